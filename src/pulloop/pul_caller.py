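"""Predict polysaccharide utilization loci by a seven-gene sliding window.

A PUL is a gene neighborhood co-encoding a SusC/SusD uptake pair and one or
more carbohydrate-active enzymes.  Anchor genes (CAZymes, paired susC/susD
genes, susE genes) are chained when at most ``window`` gene ordinals apart
on the same contig; a connected component of anchors is emitted as a PUL if
it contains at least one susC/susD tandem pair and at least one gene with a
degradative (GH/PL/CE) family.  Chaining is transitive, so an emitted locus
may span more than ``window`` genes in total.  Strand is ignored for
chaining and enforced only within the susC/susD pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations_io import GeneRecord, GenomeAnnotation
from .errors import ParameterError

DEFAULT_WINDOW = 7
DEFAULT_PAIR_GAP = 1


@dataclass
class PULCall:
    """A predicted locus with its member genes and annotation inventory."""

    pul_id: str
    genome_id: str
    contig_id: str
    member_locus_tags: list[str]
    first_gene_index: int
    last_gene_index: int
    start: int  # bp, 1-based inclusive, min over member genes
    end: int  # bp, 1-based inclusive, max over member genes
    suscd_pairs: list[tuple[str, str]]
    cazyme_inventory: tuple[str, ...]  # multiset, sorted; repeats kept
    member_families: dict[str, frozenset] = field(default_factory=dict)
    substrate: str = "other"
    susd_type: str = "not_typed"
    curated: bool = False
    curation_note: str = ""

    def susd_locus_tags(self) -> list[str]:
        return [d for _, d in self.suscd_pairs]


def find_suscd_pairs(
    genes: list[GeneRecord], pair_gap: int = DEFAULT_PAIR_GAP
) -> list[tuple[str, str]]:
    """Greedy left-to-right pairing of susC and susD genes.

    A pair requires the same strand and a gene_index difference of at most
    ``pair_gap`` (default 1: adjacent, the canonical tandem arrangement).
    Each gene joins at most one pair.  Returns (susC locus_tag, susD
    locus_tag) tuples in contig order.
    """
    paired: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for j, right in enumerate(genes):
        if right.sus_role not in ("susC", "susD") or right.locus_tag in paired:
            continue
        want = "susD" if right.sus_role == "susC" else "susC"
        for left in genes[max(0, j - pair_gap) : j]:
            if (
                left.sus_role == want
                and left.locus_tag not in paired
                and left.strand == right.strand
                and right.gene_index - left.gene_index <= pair_gap
            ):
                c, d = (left, right) if left.sus_role == "susC" else (right, left)
                pairs.append((c.locus_tag, d.locus_tag))
                paired.update((left.locus_tag, right.locus_tag))
                break
    return pairs


def _anchor_indices(
    genes: list[GeneRecord], pairs: list[tuple[str, str]]
) -> list[int]:
    in_pair = {tag for pair in pairs for tag in pair}
    return [
        g.gene_index
        for g in genes
        if g.is_cazyme or g.locus_tag in in_pair or g.sus_role == "susE"
    ]


def call_puls(
    annotation: GenomeAnnotation,
    window: int = DEFAULT_WINDOW,
    pair_gap: int = DEFAULT_PAIR_GAP,
) -> list[PULCall]:
    """Emit PUL calls for every contig of a genome.

    Parameters
    ----------
    annotation
        Genes with CAZy/sus layers loaded.
    window
        Maximum gene_index difference for two anchors to be chained into the
        same locus.  The default 7 reproduces the seven-gene sliding window
        used for flavobacterial PUL prediction.
    pair_gap
        Maximum gene_index difference within a susC/susD pair.

    Notes
    -----
    Emission requires at least one gene carrying a GH, PL or CE family; a
    component whose only CAZy tokens are binding modules (CBM) or
    glycosyltransferases (GT) is not a degradative locus and is dropped.
    Non-anchor genes falling inside the anchor span are recorded as members
    but never affect emission.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if pair_gap < 1:
        raise ParameterError(f"pair_gap must be >= 1, got {pair_gap}")

    calls: list[PULCall] = []
    counter = 0
    for contig_id, genes in annotation.contigs.items():
        pairs = find_suscd_pairs(genes, pair_gap=pair_gap)
        anchors = _anchor_indices(genes, pairs)
        if not anchors:
            continue
        by_index = {g.gene_index: g for g in genes}
        tag_index = {g.locus_tag: g.gene_index for g in genes}

        # anchors are sorted; transitive linkage on a line = runs of gaps <= window
        components: list[list[int]] = [[anchors[0]]]
        for idx in anchors[1:]:
            if idx - components[-1][-1] <= window:
                components[-1].append(idx)
            else:
                components.append([idx])

        for comp in components:
            comp_set = set(comp)
            comp_pairs = [
                (c, d)
                for c, d in pairs
                if tag_index[c] in comp_set and tag_index[d] in comp_set
            ]
            members = [by_index[i] for i in range(comp[0], comp[-1] + 1)]
            has_enzyme = any(m.degradative_families for m in members if m.gene_index in comp_set)
            if not comp_pairs or not has_enzyme:
                continue
            counter += 1
            inventory = sorted(
                fam for m in members for fam in sorted(m.cazy_families)
            )
            calls.append(
                PULCall(
                    pul_id=f"{annotation.genome_id}_PUL{counter:03d}",
                    genome_id=annotation.genome_id,
                    contig_id=contig_id,
                    member_locus_tags=[m.locus_tag for m in members],
                    first_gene_index=comp[0],
                    last_gene_index=comp[-1],
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    suscd_pairs=comp_pairs,
                    cazyme_inventory=tuple(inventory),
                    member_families={
                        m.locus_tag: m.cazy_families for m in members if m.is_cazyme
                    },
                )
            )
    return calls
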