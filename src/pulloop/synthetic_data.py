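"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the shapes of the spring-bloom datasets without any
sequencing: annotated flavobacterium-like genomes with planted PULs
(looped-variant α-glucan loci with several GH13s plus SusE, open-variant
loci with a sole GH13, laminarin-type β-glucan loci), broken decoy loci
whose CAZyme lies beyond the chaining window, glycogen-synthesis (glg)
operons carrying pathway KOs, SusD protein fixtures of the two structural
classes, and two-bloom-event expression/proteome/ASV time series in which
laminarin-PUL, glg and α-PUL trajectories co-vary with configurable lag
and coupling.  Everything is keyed by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations_io import GeneRecord, GenomeAnnotation
from .errors import ParameterError
from .omics_quant import AsvTable, ExpressionTable, ProteomeTable
from .susd_typer import SusDReferenceProfile, default_profile

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ExpressionConfig:
    """Parameters of the two-bloom expression simulation.

    53 timepoints and two bloom peaks mirror the spring-bloom sampling
    design this generator emulates; lags encode the qualitative succession
    laminarin-degradation → glycogen synthesis → α-glucan degradation.
    """

    n_timepoints: int = 53
    bloom_peaks: int = 2
    noise_dispersion: float = 5.0  # NB size parameter; larger = less noise
    coupling_strength: float = 0.9  # 0 = alpha-PUL independent of glg
    lag_timepoints: int = 2
    mean_scale: float = 300.0  # peak mean counts for a planted gene
    unmapped_fraction: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_genomes: int = 50
    genes_per_contig: int = 120
    n_alpha_puls: int = 2  # alternating looped / open variants
    n_beta_puls: int = 1
    n_broken_puls: int = 1
    n_glg_operons: int = 1
    susd_mutation_rate: float = 0.1
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        for name in (
            "n_genomes", "genes_per_contig", "n_alpha_puls", "n_beta_puls",
            "n_broken_puls", "n_glg_operons",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.susd_mutation_rate <= 1.0:
            raise ParameterError("susd_mutation_rate must be in [0, 1]")


@dataclass
class PlantedPul:
    genome_id: str
    contig_id: str
    first_gene_index: int
    last_gene_index: int
    substrate: str  # intended label
    susd_type: str  # looped / open for alpha loci, not_typed otherwise
    susd_locus_tag: str


@dataclass
class PlantedSpan:
    genome_id: str
    contig_id: str
    first_gene_index: int
    last_gene_index: int


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed by seed."""

    seed: int
    puls: list[PlantedPul] = field(default_factory=list)
    decoys: list[PlantedSpan] = field(default_factory=list)
    operons: list[PlantedSpan] = field(default_factory=list)
    susd_sequences: dict[str, str] = field(default_factory=dict)
    susd_labels: dict[str, str] = field(default_factory=dict)
    feature_groups: dict[str, list[str]] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    expression_means: dict[str, np.ndarray] = field(default_factory=dict)

    def group(self, name: str) -> list[str]:
        return self.feature_groups.setdefault(name, [])


# ---------------------------------------------------------------------------
# SusD sequence fixtures


def _mutate(seq: list[str], rng: np.random.Generator, rate: float,
            protected: set[int]) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return out


def _protected_positions(profile: SusDReferenceProfile) -> set[int]:
    """0-based positions spared by neutral mutation: diagnostics, loop, anchors."""
    left, right = profile.loop_anchor
    prot = {p - 1 for p in profile.diagnostic_positions}
    prot.update(range(left - 1, right))
    return prot


def make_looped_sequence(
    profile: SusDReferenceProfile, rng: np.random.Generator, rate: float
) -> str:
    return "".join(_mutate(list(profile.sequence), rng, rate,
                           _protected_positions(profile)))


def make_open_sequence(
    profile: SusDReferenceProfile, rng: np.random.Generator, rate: float
) -> str:
    """Loop deleted and both diagnostic residues substituted to alanine."""
    left, right = profile.loop_anchor
    seq = _mutate(list(profile.sequence), rng, rate, _protected_positions(profile))
    for p in profile.diagnostic_positions:
        seq[p - 1] = "A"
    del seq[left : right - 1]  # residues strictly between the anchors
    return "".join(seq)


def simulate_susd_sequences(
    profile: SusDReferenceProfile,
    n_per_class: int,
    mutation_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Labeled SusD fixtures: ``n_per_class`` looped and open sequences.

    Returns (records, labels): FASTA-ready (id, sequence) tuples plus a
    truth table id -> class.
    """
    if mutation_rate > 0.2:
        raise ParameterError("mutation_rate must be <= 0.2")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for i in range(n_per_class):
        qid = f"looped_{i:03d}"
        records.append((qid, make_looped_sequence(profile, rng, mutation_rate)))
        labels[qid] = "looped"
    for i in range(n_per_class):
        qid = f"open_{i:03d}"
        records.append((qid, make_open_sequence(profile, rng, mutation_rate)))
        labels[qid] = "open"
    return records, labels


# ---------------------------------------------------------------------------
# genome simulation

_PAD = 10  # background genes between planted structures; > default window


def _alpha_looped(rng) -> list[dict]:
    n_gh13 = int(rng.integers(2, 5))
    gh13s = [{"fam": "GH13_31" if (i == 0 and rng.random() < 0.5) else "GH13"}
             for i in range(n_gh13)]
    accessory = {"fam": str(rng.choice(["GH65", "GH31", "GH97"]))}
    return [
        {"role": "susC"}, {"role": "susD", "adjacent": True}, {"role": "susE"},
        *gh13s, accessory,
    ]


def _alpha_open(rng) -> list[dict]:
    return [{"role": "susC"}, {"role": "susD", "adjacent": True}, {"fam": "GH13"}]


def _beta(rng) -> list[dict]:
    fams = ["GH16", "GH17", str(rng.choice(["GH3", "GH30", "GH5_46"]))]
    return [
        {"role": "susC"}, {"role": "susD", "adjacent": True},
        *({"fam": f} for f in fams),
    ]


def _glg(rng) -> list[dict]:
    return [
        {"ko": "K00975"},
        {"ko": "K00703", "glga": True},
        {"ko": "K00700"},
        {"ko": "K00963"},
    ]


def simulate_genomes(
    config: SimConfig,
    profile: SusDReferenceProfile | None = None,
) -> tuple[dict[str, GenomeAnnotation], SyntheticTruth]:
    """Generate annotated genomes with planted loci and full ground truth.

    Each genome is one contig of ``genes_per_contig`` genes.  Planted
    structures are separated by more background genes than the default
    chaining window, so each planted locus is recovered as exactly one
    call; broken decoys place their sole CAZyme ``window + 3`` ordinals
    after the susC/D pair and must never be called at the default window.
    """
    profile = profile or default_profile()
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(seed=config.seed)
    annotations: dict[str, GenomeAnnotation] = {}

    for gi in range(config.n_genomes):
        genome_id = f"G{gi:03d}"
        contig_id = "contig_1"
        genes: list[GeneRecord] = []
        cursor = 1

        def emit(families=(), ko=(), role="none", strand=None, product=""):
            nonlocal cursor
            idx = len(genes)
            length = int(rng.integers(300, 1800))
            strand = strand if strand is not None else str(rng.choice(["+", "-"]))
            tag = f"{genome_id}_{idx:05d}"
            genes.append(
                GeneRecord(
                    genome_id=genome_id, contig_id=contig_id, gene_index=idx,
                    start=cursor, end=cursor + length - 1, strand=strand,
                    locus_tag=tag, cazy_families=frozenset(families),
                    k_numbers=frozenset(ko), sus_role=role, product=product,
                )
            )
            cursor += length + int(rng.integers(20, 200))
            truth.gene_lengths[tag] = length
            return genes[-1]

        def emit_background(n):
            for _ in range(n):
                emit()
                truth.group("background").append(genes[-1].locus_tag)

        def plant(template, group) -> tuple[int, int, str]:
            """Plant one structure; returns (first_idx, last_idx, susD tag)."""
            pair_strand = str(rng.choice(["+", "-"]))
            first = len(genes)
            susd_tag = ""
            planted_tags = []
            for k, spec in enumerate(template):
                if k > 0 and not spec.get("adjacent"):
                    emit_background(int(rng.integers(0, 3)))
                role = spec.get("role", "none")
                g = emit(
                    families=[spec["fam"]] if "fam" in spec else (),
                    ko=[spec["ko"]] if "ko" in spec else (),
                    role=role,
                    strand=pair_strand if role in ("susC", "susD") else None,
                )
                planted_tags.append(g.locus_tag)
                if role == "susD":
                    susd_tag = g.locus_tag
                if spec.get("glga"):
                    truth.group("glgA").append(g.locus_tag)
            for tag in planted_tags:
                truth.group(group).append(tag)
            return first, len(genes) - 1, susd_tag

        emit_background(int(rng.integers(2, 5)))
        for a in range(config.n_alpha_puls):
            looped = a % 2 == 0
            template = _alpha_looped(rng) if looped else _alpha_open(rng)
            first, last, susd_tag = plant(template, "alpha_pul")
            susd_type = "looped" if looped else "open"
            maker = make_looped_sequence if looped else make_open_sequence
            truth.susd_sequences[susd_tag] = maker(
                profile, rng, config.susd_mutation_rate
            )
            truth.susd_labels[susd_tag] = susd_type
            truth.puls.append(
                PlantedPul(genome_id, contig_id, first, last,
                           "alpha_glucan", susd_type, susd_tag)
            )
            emit_background(_PAD)
        for _ in range(config.n_beta_puls):
            first, last, susd_tag = plant(_beta(rng), "laminarin_pul")
            truth.puls.append(
                PlantedPul(genome_id, contig_id, first, last,
                           "beta_glucan", "not_typed", susd_tag)
            )
            emit_background(_PAD)
        for _ in range(config.n_broken_puls):
            first = len(genes)
            pair_strand = str(rng.choice(["+", "-"]))
            emit(role="susC", strand=pair_strand)
            emit(role="susD", strand=pair_strand)
            emit_background(_PAD)  # gap > window: pair and CAZyme never chain
            emit(families=["GH13"])
            truth.group("decoy").append(genes[-1].locus_tag)
            truth.decoys.append(
                PlantedSpan(genome_id, contig_id, first, len(genes) - 1)
            )
            emit_background(_PAD)
        for _ in range(config.n_glg_operons):
            first = len(genes)
            pair_strand = str(rng.choice(["+", "-"]))
            for k, spec in enumerate(_glg(rng)):
                if k > 0:
                    emit_background(int(rng.integers(0, 2)))
                g = emit(ko=[spec["ko"]], strand=pair_strand)
                truth.group("glg").append(g.locus_tag)
                if spec.get("glga"):
                    truth.group("glgA").append(g.locus_tag)
            truth.operons.append(
                PlantedSpan(genome_id, contig_id, first, len(genes) - 1)
            )
            emit_background(_PAD)

        if len(genes) > config.genes_per_contig:
            raise ParameterError(
                f"planted structures need {len(genes)} genes but "
                f"genes_per_contig={config.genes_per_contig}"
            )
        emit_background(config.genes_per_contig - len(genes))
        annotations[genome_id] = GenomeAnnotation(
            genome_id=genome_id, contigs={contig_id: genes}
        )
    return annotations, truth


# ---------------------------------------------------------------------------
# bloom time-series simulation


def _gaussian(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-((t - peak) ** 2) / (2.0 * width**2))


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    if lag <= 0:
        return x.copy()
    return np.concatenate([np.full(lag, x[0]), x[:-lag]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def bloom_driver(n_timepoints: int, n_peaks: int = 2) -> np.ndarray:
    """Chlorophyll-like driver: Gaussian bloom peaks over the series."""
    t = np.arange(n_timepoints, dtype=float)
    width = n_timepoints / 12.0
    if n_peaks == 2:
        rel = (0.30, 0.62)
    else:
        rel = tuple(np.linspace(0.25, 0.75, max(n_peaks, 1)))
    out = np.zeros(n_timepoints)
    for r in rel:
        out += _gaussian(t, r * n_timepoints, width)
    return out


def simulate_bloom_tables(
    config: SimConfig,
    truth: SyntheticTruth,
) -> tuple[ExpressionTable, ProteomeTable, AsvTable]:
    """Two-bloom expression, proteome and ASV tables with planted co-variation.

    Laminarin-PUL gene means follow the bloom driver; glg genes follow with
    ``lag_timepoints`` lag; α-PUL genes follow the glg trajectory with a
    further lag, mixed against a genome-specific independent trajectory by
    ``coupling_strength`` (at 0 the α-PUL means never reference the glg
    trajectory).  Counts are negative-binomial around those means; the
    per-feature generative means are recorded in ``truth.expression_means``.
    """
    ec = config.expression
    rng = np.random.default_rng([config.seed, 1_000_003])
    T = ec.n_timepoints
    t = np.arange(T, dtype=float)
    width = T / 12.0
    samples = [f"T{i:02d}" for i in range(T)]

    driver = bloom_driver(T, ec.bloom_peaks)
    lam_traj = driver
    glg_traj = _shift(driver, ec.lag_timepoints)
    alpha_base = _shift(glg_traj, ec.lag_timepoints)

    genome_of = {tag: tag.split("_")[0] for tag in truth.gene_lengths}
    genome_indep: dict[str, np.ndarray] = {}
    for tag in truth.group("alpha_pul"):
        gid = genome_of[tag]
        if gid not in genome_indep:
            peak = rng.uniform(0.15, 0.85) * T
            genome_indep[gid] = _gaussian(t, peak, width)

    feature_traj: dict[str, np.ndarray] = {}
    flat = np.ones(T)
    for tag in truth.group("laminarin_pul"):
        feature_traj[tag] = lam_traj
    for tag in truth.group("glg"):
        feature_traj[tag] = glg_traj
    for tag in truth.group("alpha_pul"):
        indep = genome_indep[genome_of[tag]]
        feature_traj[tag] = (
            ec.coupling_strength * alpha_base
            + (1.0 - ec.coupling_strength) * indep
        )

    tags = sorted(truth.gene_lengths)
    means = np.empty((len(tags), T))
    for i, tag in enumerate(tags):
        traj = feature_traj.get(tag, flat)
        if tag in feature_traj:
            base = ec.mean_scale * rng.lognormal(0.0, 0.5)
            means[i] = 2.0 + base * traj
        else:
            means[i] = 5.0 * rng.lognormal(0.0, 0.3)
        truth.expression_means[tag] = means[i].copy()

    counts = _nb_draw(rng, means, ec.noise_dispersion)
    counts_df = pd.DataFrame(counts, index=tags, columns=samples, dtype=float)
    col_sums = counts_df.sum(axis=0)
    unmapped = rng.poisson(col_sums.to_numpy() * ec.unmapped_fraction)
    totals = pd.Series(
        col_sums.to_numpy() + unmapped, index=samples, dtype=float
    ).clip(lower=1.0)
    expr = ExpressionTable(
        counts=counts_df,
        feature_length_bp=pd.Series(truth.gene_lengths).loc[tags].astype(float),
        sample_total_reads=totals,
    )

    # proteome: a few protein groups per functional class + eukaryotic bulk
    prot_specs = [
        ("lamPUL_susC", "Bacteria", lam_traj), ("lamPUL_gh16", "Bacteria", lam_traj),
        ("glgA_protein", "Bacteria", glg_traj), ("glgB_protein", "Bacteria", glg_traj),
        ("alphaPUL_susC", "Bacteria", alpha_base), ("alphaPUL_gh13", "Bacteria", alpha_base),
        ("fucoxanthin_cp", "Eukaryota", driver), ("rubisco_lg", "Eukaryota", driver),
        ("capsid_p", "Virus", _shift(driver, 2 * ec.lag_timepoints)),
        ("keratin_contam", "other", flat),
    ]
    quant = pd.DataFrame(
        {
            name: _nb_draw(rng, 5.0 + 200.0 * traj, ec.noise_dispersion)
            for name, _, traj in prot_specs
        },
        index=samples,
    ).T.astype(float)
    quant.columns = samples
    proteome = ProteomeTable(
        quant=quant,
        taxonomy_domain={name: dom for name, dom, _ in prot_specs},
    )

    # 18S ASVs across two size fractions, including Metazoa to filter out
    asv_specs = [
        ("asv_diatom_1", ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Ditylum"),
         _gaussian(t, 0.30 * T, width)),
        ("asv_diatom_2", ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Ceratulina"),
         _gaussian(t, 0.62 * T, width)),
        ("asv_dino_auto", ("Eukaryota", "Alveolata", "Dinophyceae", "Karenia"),
         0.3 + 0.5 * _gaussian(t, 0.30 * T, width)),
        ("asv_dino_het", ("Eukaryota", "Alveolata", "Dinophyceae", "Gyrodinium"),
         0.3 + 0.5 * _gaussian(t, 0.62 * T, width)),
        ("asv_choano", ("Eukaryota", "Opisthokonta", "Choanoflagellata", "Sphaeroeca"),
         0.1 + 0.6 * _shift(driver, ec.lag_timepoints)),
        ("asv_copepod", ("Eukaryota", "Opisthokonta", "Metazoa", "Temora"), flat),
    ]
    frac_scale = {"gt10um": 1.0, "3to10um": 0.6}
    asv_counts = {}
    sample_fraction = {}
    sample_timepoint = {}
    for frac in ("gt10um", "3to10um"):
        for i in range(T):
            s = f"T{i:02d}_{frac}"
            sample_fraction[s] = frac
            sample_timepoint[s] = f"T{i:02d}"
            asv_counts[s] = [
                float(_nb_draw(rng, np.array([20.0 + 400.0 * traj[i] * frac_scale[frac]]),
                               ec.noise_dispersion)[0])
                for _, _, traj in asv_specs
            ]
    asv = AsvTable(
        counts=pd.DataFrame(asv_counts, index=[n for n, _, _ in asv_specs]),
        taxonomy={n: tax for n, tax, _ in asv_specs},
        sample_fraction=sample_fraction,
        sample_timepoint=sample_timepoint,
    )
    return expr, proteome, asv
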