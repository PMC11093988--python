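# Methods

This note documents the models, rules and numerical choices implemented in
`pulloop`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
procedure left room.

## PUL prediction

Genes are represented with GFF3 coordinates (1-based, inclusive) and a
0-based per-contig ordinal (`gene_index`) assigned by sorting on
(start, end, locus_tag); all neighborhood logic runs on ordinals, not base
pairs, so assembly-dependent intergenic distances never affect calls.

**susC/susD pairing.** A pair requires the same strand and an ordinal
difference ≤ `pair_gap` (default 1: the canonical adjacent tandem). Pairing
is greedy left-to-right and each gene joins at most one pair. Lone susC or
susD genes never anchor a locus: observed α-glucan PULs always carry the
tandem pair, and requiring it is what keeps precision at 1.0 against decoys.

**Chaining.** Anchors are CAZyme-bearing genes, genes in susC/D pairs, and
susE-role genes. Two anchors are linked when ≤ `window` (default 7) ordinals
apart on one contig; loci are connected components under transitive linkage,
so a locus can exceed `window` genes in total — consistent with loci that
string together up to four GH13s plus accessory genes. "Seven genes apart"
is read as ordinal difference ≤ 7 (up to six intervening genes); the reading
with ≤ 7 *intervening* genes is available as `--window 8`. Strand is ignored
for chaining (mixed-strand accessory genes are common inside loci) and
enforced only within the pair.

**Emission.** A component is emitted iff it contains ≥ 1 complete pair and
≥ 1 gene with a GH/PL/CE family. CBM/GT/AA tokens make a gene an anchor but
never satisfy the enzyme requirement — a transporter pair next to a lone
binding module is not a degradative locus. Non-anchor genes inside the
anchor span are reported as members (they appear in locus diagrams) but
never affect emission. On a line, transitive closure over anchors reduces to
runs of consecutive anchors with gaps ≤ `window`; the test suite holds this
implementation equal to a literal all-pairs repeated-closure oracle on 1000
random contigs, and checks window monotonicity and mirror symmetry as
properties.

## Substrate classification

Classification sees the locus's CAZyme inventory as a set of parent
families (subfamily tokens such as `GH13_31` map to `GH13` by prefix — the
subfamily is still reported in the inventory). `alpha_glucan` requires a
family from `alpha_families` (default {GH13}). `beta_glucan` requires
≥ `beta_min_distinct` (default 2) distinct families from
{GH3, GH16, GH17, GH30, GH5} *including* one of the core endo-β-1,3
families {GH16, GH17}. The ≥ 2-with-core reading of "combinations" is a
deliberate choice: a lone GH3 is a generic β-glucosidase and should not
mark a laminarin locus, and a β-glucan call without any endo-acting
laminarinase family would be hollow. All four knobs are configurable; with
`beta_min_distinct = 1` a single core family suffices. Loci matching both
rule sets are `ambiguous` — there is no silent priority; re-labelling goes
through the curation table (pul_id → substrate + note), which flags the
locus `curated` and rejects unknown ids loudly.

## SusD typing

α-glucan-PUL SusD proteins split into a *looped* group (an ~17-residue
loop near the binding site plus two conserved ligand-binding residues) and
an *open* group lacking both. Typing aligns the query to a reference
profile by global pairwise alignment — BLOSUM62, gap open 11, extend 1
(conventional protein defaults; a gap of length L costs 11 + (L−1)), end
gaps penalized — and maps the profile's positions through the alignment.

* `looped`: every diagnostic position carries an allowed residue AND the
  number of query residues aligned between the loop anchors is
  ≥ `loop_min_len` (default 12 = 17 − 5; the 5-residue slack covers the
  "approximately" in the loop length).
* `open`: every diagnostic position substituted or deleted AND the loop
  region below `loop_min_len`.
* anything mixed → `unknown`; identity below `identity_floor` (default
  15 %, safely below the ~30 % identity typical between genuine homologs in
  this family) → `unknown` regardless.

`loop_insert_len` reports query-minus-reference residues between the
anchors (0 for the reference itself, −17 for a full loop deletion); the
call threshold is applied to the absolute query loop length, which is the
only reading under which the reference itself types as looped. Percent
identity is identical pairs over all alignment columns. Ties in the
alignment are broken deterministically (first optimal traceback).

The two diagnostic residues and the reference numbering are **not**
hard-coded: they are profile data (TOML), because no published list of the
residues exists to cite as code. The package ships
`default_profile()` — an explicitly synthetic 170-residue reference with a
17-residue loop (positions 90–106) and diagnostics W52/R120 — for testing
and simulation only; real analyses should build a profile from a
structurally characterized SusD.

The aligner itself is Biopython's `PairwiseAligner`; the test suite checks
its score against an independent recursion on the affine-gap score
definition (1000 random pairs, length ≤ 8), and validates that recursion
against literal enumeration of every gapped alignment at lengths ≤ 4.

## Glycogen-synthesis detection

The pathway definition is the 13-KO α-glucan synthesis set
(K00963, K00975, K00693, K00750, K16150, K16153, K13679, K20812, K00703,
K16148, K16147, K00700, K16149). The KO → role map (synthase / branching /
precursor / primer) is editable package data, assigned from the standard
KEGG orthology descriptions. The default completeness rule — `present`
needs ≥ 1 synthase-role KO (GlgA/GlgE/GYS variants) *and* a branching KO
(GlgB) — reflects the mechanism: glucose or maltose units are added by a
synthase and branches by GlgB, and a genome lacking either cannot make the
branched α-1,4/α-1,6 polymer. Any other non-empty hit set is `incomplete`.
Whether a weaker criterion (any single hit) was used historically is not
determinable; the rule is therefore explicit configuration, not a claim.
Co-located pathway genes are reported as operon spans using the same
ordinal window as the PUL caller (a convenience report; singletons are
included and flagged by size).

## Quantification

**TPM.** `reads × 10⁶ / (length_bp × total_sample_reads)`, with the MAG's
summed contig length or the gene's length as `length_bp`. This is
implemented exactly as stated and is a mapped-read *density* (RPKM-like):
there is **no** renormalization of each sample to one million, so TPM
columns do not sum to 10⁶ and the name diverges from the textbook TPM
definition. Per-gene TPM substitutes gene length into the same formula, and
locus aggregates are **sums** over member genes carrying a CAZy family
(means are available via `how="mean"`), grouped by substrate label, with
GlgA summed separately as the synthesis proxy. Members absent from the
counts table go to a gap report and are excluded, never silently zeroed.
Under uniform coverage every member gene's TPM equals the MAG TPM, so the
sum is n_members × MAG TPM — the test suite pins this identity.

**%NWS / %BacNWS.** Each protein group's quantitative value over its
per-sample column sum, × 100; %BacNWS restricts to Bacteria-labelled groups
and renormalizes to 100. Zero-sum or bacteria-free samples raise errors
naming the sample. **riBAQ**: each iBAQ over the per-sample iBAQ sum
(sums to 1). Column-sum invariants are enforced to 1e-9 (percent scales)
and 1e-12 (riBAQ) in property tests over randomized tables.

**18S relative abundance.** ASVs whose taxonomy path contains the excluded
taxon (default `Metazoa`, matched case-insensitively at any rank, since
amplicon taxonomies place ranks inconsistently) are dropped; the > 10 µm
and 3–10 µm fraction counts of each timepoint are summed; each timepoint is
normalized to 1. A timepoint missing one fraction proceeds on the single
fraction with a warning; a timepoint with nothing left after filtering is
an error.

## The synthetic-data generator

The generator produces the *shapes* of the real datasets with planted
truth; it does not simulate sequences, reads or spectra.

Genomes are single contigs of `genes_per_contig` (default 120) genes with
random lengths (300–1800 bp) and strands. Per genome (defaults): two
α-glucan PULs — a looped variant (susC/D pair, susE, 2–4 GH13s incl.
occasional GH13_31, one of GH65/GH31/GH97) and an open variant (pair plus a
sole GH13), mirroring the observed architecture split; one β-glucan PUL
(pair + GH16/GH17 + one of GH3/GH30/GH5); one broken decoy whose lone GH13
sits 11 ordinals from its pair (> window, must never be called); one glg
operon (glgC/glgA/glgB/galU KOs). Intra-locus gaps are 0–2 background
genes (≤ window); planted structures are separated by 10 background genes
(> window) so loci never merge. Each α-PUL's susD gene receives a protein
sequence of its class, generated from the profile: looped = neutral
substitutions at `susd_mutation_rate` sparing diagnostics and loop; open =
the same plus diagnostics → alanine and the loop deleted.

The expression series covers 53 timepoints with a two-peak Gaussian
"chlorophyll" driver (peaks at 30 % and 62 % of the series, width T/12).
Laminarin-PUL gene means follow the driver; glg means follow with a 2-point
lag; α-PUL means follow glg with a further 2-point lag, mixed with a
genome-specific independent Gaussian trajectory by `coupling_strength`
(default 0.9). At coupling 0 the α-PUL means are constructed without any
contribution from the glg trajectory — independence holds by construction,
not just in expectation. Counts are negative-binomial around the means
(dispersion parameter `noise_dispersion` = 5, moderate overdispersion; the
real data specify no noise model, so the model is declared rather than
inferred), per-gene baseline levels are log-normal, and per-sample totals
are column sums plus Poisson "unmapped" reads (~30 %). Proteome tables
(ten groups across Bacteria/Eukaryota/Virus/other with matching
trajectories) and ASV tables (diatoms peaking with the blooms,
dinoflagellates, a choanoflagellate, and a Metazoa ASV to exercise the
filter, across both size fractions) share the structure. All outputs are
bit-identical under a fixed seed.

What passing tests on these data show: the window rule, the classification
and typing rules, and the normalization arithmetic behave exactly as
specified on inputs whose truth is known. What they do not show: robustness
to fragmented assemblies (multi-contig loci), mis-annotation (missing or
spurious CAZy/sus/KO labels), horizontal architecture variants (unpaired
susC), or real biological noise structure — real annotations and counts are
messier than any planted cohort.

## Problem sizes and tolerances

Randomized checks use 1000 contigs (≤ 30 genes) for caller–oracle
equivalence, 200 contigs for window monotonicity, 1000 length-≤ 8 pairs for
alignment optimality, 200 fixtures per SusD class at 10 % off-site
mutation, 500 random tables for normalization invariants, and 20 replicate
seeds × 50 genomes for the coupling checks — sizes at which every property
is exercised densely while the whole suite stays fast. Floating-point
tolerances: 1e-9 on alignment-score equality and percent-scale sums, 1e-12
on riBAQ sums and TPM arithmetic.

## Known limitations

* Single-contig loci only: a PUL split across contigs is called as
  fragments (or not at all if the pair and enzymes separate).
* Typing depends on a profile; with no structurally grounded profile the
  default synthetic one is only suitable for simulation and testing.
* The greedy left-to-right susC/D pairing is order-dependent for
  `pair_gap` > 1 in pathological arrangements (multiple interleaved
  candidates); at the default adjacent pairing it is unambiguous.
* The pathway completeness rule ignores gene context (a synthase and a
  branching enzyme on opposite replicons still count) — by design, since
  capability, not operon structure, is scored; operon spans are reported
  separately.
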