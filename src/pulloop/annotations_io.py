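"""Read and validate annotated gene tables; write PUL reports.

Genes come in as GFF3 (1-based, inclusive coordinates) plus flat annotation
layers keyed by locus_tag: a dbCAN-style CAZy-family layer, a KofamScan-style
KO layer and a sus-role layer.  Everything downstream (the PUL caller, the
pathway scanner) works on the resulting :class:`GenomeAnnotation`.

Outputs are a TSV report (one row per PUL), a BED file of PUL spans
(converted to 0-based half-open) and a JSON file with full member detail.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .errors import AnnotationValidationError, GFFParseError

FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|CBM|AA)[0-9]+(_[0-9]+)?$")
SUS_ROLES = ("none", "susC", "susD", "susE")
STRANDS = ("+", "-")


@dataclass
class GeneRecord:
    """One annotated gene: coordinates plus its annotation layers.

    Coordinates are GFF3 convention: 1-based, inclusive on both ends.
    ``gene_index`` is the 0-based ordinal of the gene within its contig in
    coordinate order; the PUL caller's window rule operates on this ordinal.
    """

    genome_id: str
    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    locus_tag: str
    cazy_families: frozenset[str] = frozenset()
    k_numbers: frozenset[str] = frozenset()
    sus_role: str = "none"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationValidationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise AnnotationValidationError(
                f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.sus_role not in SUS_ROLES:
            raise AnnotationValidationError(
                f"{self.locus_tag}: sus_role must be one of {SUS_ROLES}, "
                f"got {self.sus_role!r}"
            )
        for fam in self.cazy_families:
            if not FAMILY_RE.match(fam):
                raise AnnotationValidationError(
                    f"{self.locus_tag}: malformed CAZy family token {fam!r}"
                )

    @property
    def is_cazyme(self) -> bool:
        return bool(self.cazy_families)

    @property
    def degradative_families(self) -> frozenset[str]:
        """GH/PL/CE tokens only — the families that count as enzymes."""
        return frozenset(
            f for f in self.cazy_families if f[:2] in ("GH", "PL", "CE")
        )


@dataclass
class GenomeAnnotation:
    """All genes of one genome, grouped per contig and sorted by gene_index."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    layer_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig_id, genes in self.contigs.items():
            for i, g in enumerate(genes):
                if g.genome_id != self.genome_id or g.contig_id != contig_id:
                    raise AnnotationValidationError(
                        f"{g.locus_tag}: container mismatch "
                        f"({g.genome_id}/{g.contig_id} in {self.genome_id}/{contig_id})"
                    )
                if g.gene_index != i:
                    raise AnnotationValidationError(
                        f"{contig_id}: gene_index not consecutive at {g.locus_tag}"
                    )
                if g.locus_tag in seen:
                    raise AnnotationValidationError(
                        f"duplicate locus_tag {g.locus_tag}"
                    )
                seen.add(g.locus_tag)

    def all_genes(self) -> Iterable[GeneRecord]:
        for genes in self.contigs.values():
            yield from genes

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.all_genes():
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)


def _prescan_gff(gff_path: Path) -> None:
    """Validate GFF3 syntax line-by-line so errors carry line numbers."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(lineno, f"expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GFFParseError(lineno, "start/end not integers") from None
            if start > end:
                raise GFFParseError(lineno, f"start {start} > end {end}")
            if cols[6] not in ("+", "-", ".", "?"):
                raise GFFParseError(lineno, f"bad strand {cols[6]!r}")


def _read_layer(path: Path) -> list[tuple[str, str]]:
    """Two-column TSV (locus_tag<TAB>value), repeatable rows, '#' comments."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            rows.append((parts[0], parts[1]))
    return rows


def read_annotation(
    gff_path: str | Path,
    layer_paths: Mapping[str, str | Path] | None = None,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from a GFF3 file plus layer TSVs.

    Parameters
    ----------
    gff_path
        GFF3 with ``gene`` or ``CDS`` features; locus tags are taken from the
        ``locus_tag`` attribute, falling back to ``ID``.
    layer_paths
        Optional map with keys ``"cazy"``, ``"ko"`` and/or ``"sus"``, each a
        two-column TSV keyed by locus_tag.  Layer rows naming a locus_tag that
        is absent from the GFF are collected as warnings on the returned
        object, never silently dropped.
    genome_id
        Defaults to the GFF file stem.

    Raises
    ------
    GFFParseError
        On a malformed GFF line (with its line number).
    AnnotationValidationError
        On duplicate locus tags or malformed layer values.
    """
    gff_path = Path(gff_path)
    layer_paths = dict(layer_paths or {})
    gid = genome_id if genome_id is not None else gff_path.stem

    _prescan_gff(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    raw: dict[str, list] = {}
    tags_seen: set[str] = set()
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            tag = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
            if tag in tags_seen:
                raise AnnotationValidationError(f"duplicate locus_tag {tag}")
            tags_seen.add(tag)
            product = feat.attributes.get("product", [""])[0]
            raw.setdefault(feat.seqid, []).append(
                (feat.start, feat.end, tag, feat.strand, product)
            )

    cazy: dict[str, set[str]] = {}
    kos: dict[str, set[str]] = {}
    roles: dict[str, str] = {}
    warnings: list[str] = []
    for layer_name, store in (("cazy", cazy), ("ko", kos)):
        if layer_name in layer_paths:
            for tag, value in _read_layer(Path(layer_paths[layer_name])):
                if tag not in tags_seen:
                    warnings.append(
                        f"{layer_name} layer references absent locus_tag {tag!r}"
                    )
                    continue
                store.setdefault(tag, set()).add(value)
    if "sus" in layer_paths:
        for tag, value in _read_layer(Path(layer_paths["sus"])):
            if tag not in tags_seen:
                warnings.append(f"sus layer references absent locus_tag {tag!r}")
                continue
            roles[tag] = value

    contigs: dict[str, list[GeneRecord]] = {}
    for contig_id in sorted(raw):
        rows = sorted(raw[contig_id], key=lambda r: (r[0], r[1], r[2]))
        genes = [
            GeneRecord(
                genome_id=gid,
                contig_id=contig_id,
                gene_index=i,
                start=start,
                end=end,
                strand=strand if strand in STRANDS else "+",
                locus_tag=tag,
                cazy_families=frozenset(cazy.get(tag, ())),
                k_numbers=frozenset(kos.get(tag, ())),
                sus_role=roles.get(tag, "none"),
                product=product,
            )
            for i, (start, end, tag, strand, product) in enumerate(rows)
        ]
        contigs[contig_id] = genes
    return GenomeAnnotation(genome_id=gid, contigs=contigs, layer_warnings=warnings)


# ---------------------------------------------------------------------------
# writers


def write_annotation(annotation: GenomeAnnotation, out_dir: str | Path) -> dict[str, Path]:
    """Write a GenomeAnnotation back out as GFF3 + the three layer TSVs.

    Used by the simulator and for round-trip testing; returns the paths
    keyed as accepted by :func:`read_annotation`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff = out_dir / f"{annotation.genome_id}.gff3"
    paths = {
        "cazy": out_dir / f"{annotation.genome_id}.cazy.tsv",
        "ko": out_dir / f"{annotation.genome_id}.ko.tsv",
        "sus": out_dir / f"{annotation.genome_id}.sus.tsv",
    }
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.all_genes():
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tpulloop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    with open(paths["cazy"], "w") as fh:
        for g in annotation.all_genes():
            for fam in sorted(g.cazy_families):
                fh.write(f"{g.locus_tag}\t{fam}\n")
    with open(paths["ko"], "w") as fh:
        for g in annotation.all_genes():
            for ko in sorted(g.k_numbers):
                fh.write(f"{g.locus_tag}\t{ko}\n")
    with open(paths["sus"], "w") as fh:
        for g in annotation.all_genes():
            if g.sus_role != "none":
                fh.write(f"{g.locus_tag}\t{g.sus_role}\n")
    return {"gff": gff, **paths}


PUL_TSV_COLUMNS = [
    "pul_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "first_gene_index",
    "last_gene_index",
    "n_genes",
    "n_suscd_pairs",
    "cazyme_inventory",
    "substrate",
    "susd_type",
    "curated",
    "curation_note",
    "member_locus_tags",
]


def _pul_sort_key(pul) -> tuple:
    return (pul.genome_id, pul.contig_id, pul.first_gene_index)


def write_pul_outputs(puls: list, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV report, BED spans and JSON member detail for PUL calls.

    BED spans are 0-based half-open (``bed_start = gff_start - 1``,
    ``bed_end = gff_end``); rows are ordered deterministically by
    (genome_id, contig_id, first_gene_index).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(puls, key=_pul_sort_key)
    tsv = out_dir / "puls.tsv"
    bed = out_dir / "puls.bed"
    js = out_dir / "puls.json"

    with open(tsv, "w") as fh:
        fh.write("\t".join(PUL_TSV_COLUMNS) + "\n")
        for p in ordered:
            fh.write(
                "\t".join(
                    [
                        p.pul_id,
                        p.genome_id,
                        p.contig_id,
                        str(p.start),
                        str(p.end),
                        str(p.first_gene_index),
                        str(p.last_gene_index),
                        str(len(p.member_locus_tags)),
                        str(len(p.suscd_pairs)),
                        ";".join(p.cazyme_inventory),
                        p.substrate,
                        p.susd_type,
                        "yes" if p.curated else "no",
                        p.curation_note,
                        ";".join(p.member_locus_tags),
                    ]
                )
                + "\n"
            )
    with open(bed, "w") as fh:
        for p in ordered:
            fh.write(f"{p.contig_id}\t{p.start - 1}\t{p.end}\t{p.pul_id}\n")
    with open(js, "w") as fh:
        json.dump([_pul_to_json(p) for p in ordered], fh, indent=2)
        fh.write("\n")
    return {"tsv": tsv, "bed": bed, "json": js}


def _pul_to_json(pul) -> dict:
    d = dataclasses.asdict(pul)
    d["cazyme_inventory"] = list(pul.cazyme_inventory)
    d["suscd_pairs"] = [list(p) for p in pul.suscd_pairs]
    d["member_families"] = {
        tag: sorted(fams) for tag, fams in pul.member_families.items()
    }
    return d
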