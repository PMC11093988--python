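"""Independent reference implementations used as test oracles.

Everything here is deliberately naive and self-contained: closure by
repeated expansion for locus chaining, recursion on the alignment-score
definition (plus literal enumeration of every gapped alignment at tiny
lengths), and a substrate predicate written directly from the rule
statement.  None of it shares code with the package paths it checks.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

from pulloop.annotations_io import GeneRecord, GenomeAnnotation

# ---------------------------------------------------------------------------
# random annotated contigs


def make_random_contig(
    rng: np.random.Generator,
    n_genes: int,
    genome_id: str = "R",
    p_sus: float = 0.30,
    p_cazy: float = 0.30,
) -> GenomeAnnotation:
    fams = ["GH13", "GH13_31", "GH16", "GH17", "GH3", "GH65", "CBM48", "GT2"]
    genes = []
    cursor = 1
    for i in range(n_genes):
        length = int(rng.integers(300, 1500))
        role = "none"
        if rng.random() < p_sus:
            role = ["susC", "susD", "susE"][rng.integers(3)]
        families = []
        if role == "none" and rng.random() < p_cazy:
            families = [fams[rng.integers(len(fams))]]
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id="c1",
                gene_index=i,
                start=cursor,
                end=cursor + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                locus_tag=f"{genome_id}_{i:04d}",
                cazy_families=frozenset(families),
                k_numbers=frozenset(),
                sus_role=role,
            )
        )
        cursor += length + 50
    return GenomeAnnotation(genome_id=genome_id, contigs={"c1": genes})


# ---------------------------------------------------------------------------
# brute-force PUL calling


def brute_pairs(genes, pair_gap=1):
    """Greedy left-to-right susC/susD pairing, written independently."""
    used = set()
    pairs = []
    for j in range(len(genes)):
        gj = genes[j]
        if gj.sus_role not in ("susC", "susD") or j in used:
            continue
        for i in range(max(0, j - pair_gap), j):
            gi = genes[i]
            if i in used:
                continue
            if (
                {gi.sus_role, gj.sus_role} == {"susC", "susD"}
                and gi.strand == gj.strand
            ):
                c, d = (gi, gj) if gi.sus_role == "susC" else (gj, gi)
                pairs.append((c.locus_tag, d.locus_tag))
                used.update((i, j))
                break
    return pairs


def brute_force_pul_calls(genes, window=7, pair_gap=1):
    """All-pairs linkage + repeated-closure components; returns emitted
    loci as (first_idx, last_idx, member tags, pairs) tuples."""
    pairs = brute_pairs(genes, pair_gap)
    in_pair = {t for pr in pairs for t in pr}
    anchors = [
        g.gene_index
        for g in genes
        if g.cazy_families or g.locus_tag in in_pair or g.sus_role == "susE"
    ]
    remaining = set(anchors)
    components = []
    while remaining:
        comp = {remaining.pop()}
        changed = True
        while changed:
            changed = False
            for a in list(remaining):
                if any(abs(a - b) <= window for b in comp):
                    comp.add(a)
                    remaining.discard(a)
                    changed = True
        components.append(sorted(comp))
    by_index = {g.gene_index: g for g in genes}
    tag_index = {g.locus_tag: g.gene_index for g in genes}
    out = []
    for comp in sorted(components):
        comp_set = set(comp)
        comp_pairs = tuple(
            (c, d) for c, d in pairs
            if tag_index[c] in comp_set and tag_index[d] in comp_set
        )
        has_enzyme = any(
            f[:2] in ("GH", "PL", "CE")
            for i in comp
            for f in by_index[i].cazy_families
        )
        if comp_pairs and has_enzyme:
            members = tuple(
                by_index[i].locus_tag for i in range(comp[0], comp[-1] + 1)
            )
            out.append((comp[0], comp[-1], members, comp_pairs))
    return out


def as_tuples(puls):
    """Normalize PULCall objects for comparison against the brute force."""
    return sorted(
        (
            p.first_gene_index,
            p.last_gene_index,
            tuple(p.member_locus_tags),
            tuple(p.suscd_pairs),
        )
        for p in puls
    )


# ---------------------------------------------------------------------------
# alignment oracles

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def nw_affine_optimum(q: str, r: str, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by memoized recursion on the score
    definition (gap of length L costs open + (L-1)*extend)."""

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int, state: int) -> float:
        # state 0: last column was a residue pair; 1: gap in ref; 2: gap in query
        if i == len(q) and j == len(r):
            return 0.0
        best = -np.inf
        if i < len(q) and j < len(r):
            best = max(best, _BLOSUM62[q[i], r[j]] + f(i + 1, j + 1, 0))
        if i < len(q):
            best = max(best, -(gap_extend if state == 1 else gap_open) + f(i + 1, j, 1))
        if j < len(r):
            best = max(best, -(gap_extend if state == 2 else gap_open) + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


def enumerate_all_alignment_scores(q: str, r: str, gap_open: float = 11.0,
                                   gap_extend: float = 1.0):
    """Literal enumeration of every gapped global alignment (tiny inputs
    only: the count grows like the Delannoy numbers)."""

    def rec(i, j, cols):
        if i == len(q) and j == len(r):
            yield cols
            return
        if i < len(q) and j < len(r):
            yield from rec(i + 1, j + 1, cols + [(q[i], r[j])])
        if i < len(q):
            yield from rec(i + 1, j, cols + [(q[i], "-")])
        if j < len(r):
            yield from rec(i, j + 1, cols + [("-", r[j])])

    def score(cols):
        total, prev_gap = 0.0, None  # prev_gap: which sequence was gapped
        for a, b in cols:
            if a != "-" and b != "-":
                total += _BLOSUM62[a, b]
                prev_gap = None
            else:
                gap_in = 0 if a == "-" else 1
                total -= gap_extend if prev_gap == gap_in else gap_open
                prev_gap = gap_in
        return total

    return (score(c) for c in rec(0, 0, []))


# ---------------------------------------------------------------------------
# substrate truth table


def substrate_expected(families: set[str]) -> str:
    """Expected label, written directly from the classification rule:
    GH13 -> alpha; >=2 of {GH3,GH16,GH17,GH30,GH5} incl GH16 or GH17 -> beta."""
    parents = {f.split("_")[0] for f in families}
    alpha = "GH13" in parents
    beta_set = parents & {"GH3", "GH16", "GH17", "GH30", "GH5"}
    beta = len(beta_set) >= 2 and bool(beta_set & {"GH16", "GH17"})
    if alpha and beta:
        return "ambiguous"
    if alpha:
        return "alpha_glucan"
    if beta:
        return "beta_glucan"
    return "other"
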