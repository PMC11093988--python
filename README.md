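# pulloop

Detection, classification and quantification of **polysaccharide
utilization loci (PULs)** in marine *Flavobacteriia*, with the companion
procedures needed to follow α-glucan (glycogen-like storage polysaccharide)
cycling through phytoplankton-bloom time series: SusD binding-site typing,
glycogen-synthesis pathway scanning, and the TPM / %NWS / riBAQ / 18S
normalization formulas used for bloom metatranscriptomes, metaproteomes and
amplicon data.

Bloom-associated flavobacteria take up glycans through PULs — gene clusters
co-encoding a TonB-dependent transporter (SusC), a surface glycan-binding
lipoprotein (SusD) and carbohydrate-active enzymes (CAZymes). `pulloop`
starts from ordinary annotation products (GFF3 gene coordinates plus
dbCAN-style CAZy, KofamScan-style KO and sus-role layers) and answers: where
are the PULs, what glycan do they target, which structural SusD variant do
α-glucan loci carry, can the genome also *synthesize* α-glucan, and how do
degradation and synthesis co-vary over a bloom.

## The rules at the core

* **PUL calling** — anchor genes (CAZymes, paired *susC/susD* genes, *susE*
  genes) are chained when at most *w* = 7 gene ordinals apart on a contig
  (the seven-gene sliding window); a connected component is a PUL iff it
  contains a same-strand adjacent susC/susD tandem pair and ≥ 1 GH/PL/CE
  enzyme gene. Chaining is transitive, so loci may exceed seven genes.
* **Substrate classification** — GH13 (any subfamily) ⇒ `alpha_glucan`;
  ≥ 2 distinct families from {GH3, GH16, GH17, GH30, GH5} including an
  endo-β-1,3-glucanase core family (GH16/GH17) ⇒ `beta_glucan` (laminarin);
  both ⇒ `ambiguous`, resolved only via the explicit curation table.
* **SusD typing** — global affine-gap alignment (BLOSUM62, 11/1) to a
  reference profile; *looped* requires the two diagnostic binding residues
  plus ≥ 12 query residues across the ~17-residue binding-site loop,
  *open* requires both absent and the loop deleted; anything mixed, or
  below a 15 % identity floor, is `unknown`.
* **Glycogen synthesis** — a genome is synthesis-capable when its genes hit
  a synthase-role KO (e.g. GlgA) *and* a branching-enzyme KO (GlgB) from the
  13-KO α-glucan pathway set; co-located glg genes are reported as operon
  spans.
* **Quantification** — MAG/gene TPM is the mapped-read density
  `reads × 10⁶ / (length_bp × sample_reads)` (no per-sample renormalization
  — see `docs/methods.md`); PUL CAZyme TPM is aggregated per substrate
  class with GlgA as the synthesis proxy; proteomes are normalized to %NWS
  / %BacNWS, pure-culture proteomes to riBAQ; 18S ASV tables are
  Metazoa-filtered, fraction-combined and normalized to 1.

A fully deterministic synthetic-data generator plants all of the above —
looped/open α-glucan PULs, β-glucan PULs, window-violating decoys, glg
operons, SusD sequences of both classes, and a two-bloom expression time
series (53 timepoints) in which laminarin-PUL, glg and α-PUL trajectories
co-vary with configurable lag and coupling — so every stage is testable
against planted truth.

## Worked example

```python
import numpy as np
from pulloop import (SimConfig, simulate_genomes, simulate_bloom_tables,
                     call_puls, classify_all, default_profile,
                     aggregate_pul_expression)
from pulloop.pipeline import type_pul_susd, evaluate_recovery

config = SimConfig(seed=42, n_genomes=5)
annotations, truth = simulate_genomes(config)
puls = [p for ann in annotations.values() for p in call_puls(ann, window=7)]
puls = type_pul_susd(classify_all(puls), truth.susd_sequences, default_profile())

print(len(puls))                      # 15  (3 planted loci per genome)
p = puls[0]
print(p.pul_id, p.substrate, p.susd_type)
# G000_PUL001 alpha_glucan looped
print(p.cazyme_inventory)             # ('GH13', 'GH13', 'GH13', 'GH13_31', 'GH31')

report = evaluate_recovery(puls, truth)
print(report.recall, report.precision)   # 1.0 1.0

expr, proteome, asv = simulate_bloom_tables(config, truth)
agg = aggregate_pul_expression(expr, puls, truth.feature_groups["glgA"])
a = agg.table.loc["alpha_glucan"].to_numpy()   # summed α-PUL CAZyme TPM per sample
g = agg.table.loc["glgA"].to_numpy()           # starch-synthase TPM (synthesis proxy)
print(round(float(np.corrcoef(a, g)[0, 1]), 3))   # 0.577
```

Every planted locus is recovered span-exactly with its substrate and SusD
type (recall = precision = 1.0), and the α-glucan degradation aggregate
tracks the GlgA synthesis proxy (r ≈ 0.58 for this five-genome cohort),
reflecting the planted succession laminarin use → glycogen synthesis →
α-glucan use.

The same stages are available from the shell:

```bash
pulloop run --seed 42 --out run/          # simulate → call → classify → type → scan → quantify
pulloop call-puls --gff g.gff3 --cazy-layer g.cazy.tsv --sus-layer g.sus.tsv --out calls/
pulloop susd-type --fasta susd.faa --out typing.tsv
```

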