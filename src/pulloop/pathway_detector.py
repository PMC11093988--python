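"""Detect glycogen (α-glucan) synthesis capability from KO annotations.

Bacterial glycogen synthesis runs either through the classical GlgC/GlgA
route (ADP-glucose pyrophosphorylase + glycogen synthase) or the GlgE route
(maltose-1-phosphate maltosyltransferase); in both, branches are added by
the branching enzyme GlgB.  Capability is scored from the KO numbers of a
genome's genes against a configurable pathway definition; co-located glg
genes are additionally reported as operon spans using the same gene-ordinal
window semantics as the PUL caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations_io import GenomeAnnotation
from .errors import ParameterError

#: KOs retained as the α-glucan synthesis pathway.
DEFAULT_GLG_KOS = frozenset(
    {
        "K00963", "K00975", "K00693", "K00750", "K16150", "K16153", "K13679",
        "K20812", "K00703", "K16148", "K16147", "K00700", "K16149",
    }
)

#: KO -> functional role. Editable; roles drive the completeness rule.
DEFAULT_ROLE_MAP: dict[str, str] = {
    "K00963": "precursor",  # galU, UTP-glucose-1-phosphate uridylyltransferase
    "K00975": "precursor",  # glgC, glucose-1-phosphate adenylyltransferase
    "K20812": "precursor",  # glgM, alpha-maltose-1-phosphate synthase
    "K00693": "synthase",   # GYS, glycogen synthase
    "K00703": "synthase",   # glgA, starch/glycogen synthase
    "K13679": "synthase",   # glgA, ADP-glucose type
    "K16148": "synthase",   # glycogen synthase (UDP-glucose)
    "K16150": "synthase",   # glycogen synthase variant
    "K16153": "synthase",   # glycogen synthase variant
    "K16147": "synthase",   # glgE, maltosyltransferase
    "K00700": "branching",  # glgB / GBE1, 1,4-alpha-glucan branching enzyme
    "K16149": "branching",  # glgB, branching enzyme
    "K00750": "primer",     # glycogenin
}

STATUS_PRESENT = "present"
STATUS_INCOMPLETE = "incomplete"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class PathwayDefinition:
    ko_set: frozenset[str] = DEFAULT_GLG_KOS
    role_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))

    def __post_init__(self) -> None:
        if not self.ko_set:
            raise ParameterError("ko_set must be non-empty")
        extra = set(self.role_map) - set(self.ko_set)
        if extra:
            raise ParameterError(f"role_map keys outside ko_set: {sorted(extra)}")

    def roles_of(self, kos: frozenset[str] | set[str]) -> set[str]:
        return {self.role_map.get(k, "other") for k in kos}


@dataclass
class OperonSpan:
    contig_id: str
    first_gene_index: int
    last_gene_index: int
    locus_tags: list[str]

    @property
    def size(self) -> int:
        return len(self.locus_tags)


@dataclass
class PathwayCall:
    genome_id: str
    ko_hits: frozenset[str]
    status: str
    operon_loci: list[OperonSpan] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.ko_hits)


DEFAULT_DEFINITION = PathwayDefinition()


def detect_glg_pathway(
    annotation: GenomeAnnotation,
    definition: PathwayDefinition = DEFAULT_DEFINITION,
    operon_window: int = 7,
) -> PathwayCall:
    """Score a genome for α-glucan synthesis capability.

    Completeness (default rule): ``present`` needs at least one synthase-role
    KO and a branching-enzyme KO; any other non-empty hit set is
    ``incomplete``; an empty intersection is ``absent``.  The result is
    invariant to gene order and to duplicated KO assignments.
    """
    hits: set[str] = set()
    for g in annotation.all_genes():
        hits |= g.k_numbers & definition.ko_set
    roles = definition.roles_of(hits)
    if not hits:
        status = STATUS_ABSENT
    elif "synthase" in roles and "branching" in roles:
        status = STATUS_PRESENT
    else:
        status = STATUS_INCOMPLETE
    return PathwayCall(
        genome_id=annotation.genome_id,
        ko_hits=frozenset(hits),
        status=status,
        operon_loci=locate_glg_operon(annotation, definition, window=operon_window),
    )


def locate_glg_operon(
    annotation: GenomeAnnotation,
    definition: PathwayDefinition = DEFAULT_DEFINITION,
    window: int = 7,
) -> list[OperonSpan]:
    """Connected spans of pathway-KO genes, singletons included.

    Same chaining rule as the PUL caller: genes carrying a pathway KO are
    linked when at most ``window`` gene ordinals apart on one contig.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    spans: list[OperonSpan] = []
    for contig_id, genes in annotation.contigs.items():
        carriers = [g for g in genes if g.k_numbers & definition.ko_set]
        if not carriers:
            continue
        runs: list[list] = [[carriers[0]]]
        for g in carriers[1:]:
            if g.gene_index - runs[-1][-1].gene_index <= window:
                runs[-1].append(g)
            else:
                runs.append([g])
        for run in runs:
            spans.append(
                OperonSpan(
                    contig_id=contig_id,
                    first_gene_index=run[0].gene_index,
                    last_gene_index=run[-1].gene_index,
                    locus_tags=[g.locus_tag for g in run],
                )
            )
    return spans
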