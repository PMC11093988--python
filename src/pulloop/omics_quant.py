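"""Quantification formulas for bloom multi-omics time series.

Implements, exactly as defined for the spring-bloom survey datasets:

* per-MAG / per-gene TPM: ``reads × 10^6 / (length_bp × sample_reads)``.
  Note this is a mapped-read density (RPKM-like); there is **no** per-sample
  renormalization to one million, so TPM columns do not sum to 10^6.
* PUL-aggregated CAZyme expression per substrate class, with the starch
  synthase GlgA reported separately as the synthesis proxy.
* metaproteomic %NWS (percent normalized weighted spectra) and %BacNWS
  (bacteria renormalized to 100%).
* riBAQ (relative iBAQ) for pure-culture proteomes.
* 18S amplicon relative abundance with Metazoa removal and size-fraction
  combining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, QuantError
from .pul_caller import PULCall

FRACTIONS = ("gt10um", "3to10um")


@dataclass
class ExpressionTable:
    """Feature × sample read counts with lengths and per-sample totals.

    ``counts`` rows are features (genes or MAGs), columns samples.
    ``sample_total_reads`` is the total sequenced reads per sample (the TPM
    denominator), which must be at least the mapped column sum.
    """

    counts: pd.DataFrame
    feature_length_bp: pd.Series
    sample_total_reads: pd.Series
    feature_to_mag: dict[str, str] = field(default_factory=dict)
    feature_to_pul: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be non-negative")
        missing = self.counts.index.difference(self.feature_length_bp.index)
        if len(missing):
            raise ParameterError(f"features lacking lengths: {list(missing)[:5]}")
        if (self.feature_length_bp.loc[self.counts.index] <= 0).any():
            raise ParameterError("feature lengths must be positive")
        missing_s = self.counts.columns.difference(self.sample_total_reads.index)
        if len(missing_s):
            raise ParameterError(f"samples lacking totals: {list(missing_s)[:5]}")
        if (self.sample_total_reads.loc[self.counts.columns] <= 0).any():
            raise ParameterError("sample totals must be positive")

    def tpm(self) -> pd.DataFrame:
        """Per-feature TPM: counts × 10^6 / (length × sample total)."""
        lengths = self.feature_length_bp.loc[self.counts.index].to_numpy()
        totals = self.sample_total_reads.loc[self.counts.columns].to_numpy()
        vals = (
            self.counts.to_numpy() * 1e6 / (lengths[:, None] * totals[None, :])
        )
        return pd.DataFrame(vals, index=self.counts.index, columns=self.counts.columns)


def mag_tpm(reads_to_mag: float, mag_length_bp: float, sample_total: float) -> float:
    """TPM of one MAG in one sample, exactly as the printed formula."""
    if mag_length_bp <= 0:
        raise ParameterError(f"mag_length_bp must be > 0, got {mag_length_bp}")
    if sample_total <= 0:
        raise ParameterError(f"sample_total must be > 0, got {sample_total}")
    return reads_to_mag * 1e6 / (mag_length_bp * sample_total)


@dataclass
class PulAggregate:
    """Per-sample aggregated CAZyme TPM per substrate class, plus GlgA."""

    table: pd.DataFrame  # rows: substrate classes + "glgA"; cols: samples
    missing_features: list[str]  # PUL members absent from the counts table


def aggregate_pul_expression(
    table: ExpressionTable,
    puls: Sequence[PULCall],
    glgA_features: Iterable[str],
    how: str = "sum",
) -> PulAggregate:
    """Aggregate CAZyme-gene TPM over PULs, grouped by substrate label.

    Per-gene TPM uses the gene length in place of the MAG length.  Only PUL
    member genes that carry a CAZy family contribute; GlgA features are
    summed separately as the α-glucan synthesis proxy.  Members absent from
    the counts table are listed in the gap report and excluded from sums.
    """
    if how not in ("sum", "mean"):
        raise ParameterError(f"how must be 'sum' or 'mean', got {how!r}")
    tpm = table.tpm()
    classes = ["alpha_glucan", "beta_glucan", "other", "ambiguous"]
    groups: dict[str, list[str]] = {c: [] for c in classes}
    missing: list[str] = []
    for pul in puls:
        cazy_members = [t for t in pul.member_locus_tags if t in pul.member_families]
        for tag in cazy_members:
            if tag in tpm.index:
                groups.setdefault(pul.substrate, []).append(tag)
            else:
                missing.append(tag)
    glga = [t for t in glgA_features if t in tpm.index]
    missing.extend(t for t in glgA_features if t not in tpm.index)

    rows = {}
    for cls in [*classes, *(k for k in groups if k not in classes)]:
        tags = groups.get(cls, [])
        rows[cls] = (
            tpm.loc[tags].agg(how, axis=0)
            if tags
            else pd.Series(0.0, index=tpm.columns)
        )
    rows["glgA"] = (
        tpm.loc[glga].agg(how, axis=0) if glga else pd.Series(0.0, index=tpm.columns)
    )
    out = pd.DataFrame(rows).T
    out.columns = tpm.columns
    return PulAggregate(table=out, missing_features=missing)


# ---------------------------------------------------------------------------
# metaproteomics


@dataclass
class ProteomeTable:
    """Protein group × sample quantification with a domain-level taxonomy."""

    quant: pd.DataFrame
    taxonomy_domain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.quant.to_numpy() < 0).any():
            raise ParameterError("quant values must be non-negative")


def pct_nws(proteome: ProteomeTable) -> pd.DataFrame:
    """Percent normalized weighted spectra: each value over its column sum, ×100."""
    sums = proteome.quant.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise QuantError(f"zero-sum sample(s): {list(zero.index)}")
    return proteome.quant.div(sums, axis=1) * 100.0


def bac_nws(pct: pd.DataFrame, taxonomy_domain: Mapping[str, str]) -> pd.DataFrame:
    """Restrict a %NWS matrix to Bacteria and renormalize columns to 100%."""
    bac = [g for g in pct.index if taxonomy_domain.get(g) == "Bacteria"]
    sub = pct.loc[bac]
    sums = sub.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise QuantError(f"no bacterial signal in sample(s): {list(zero.index)}")
    return sub.div(sums, axis=1) * 100.0


def ribaq(ibaq_values) -> np.ndarray:
    """Relative iBAQ: each protein's iBAQ over the per-sample iBAQ sum."""
    values = np.asarray(ibaq_values, dtype=float)
    if (values < 0).any():
        raise ParameterError("iBAQ values must be non-negative")
    total = values.sum()
    if total <= 0:
        raise QuantError("iBAQ column sums to zero")
    return values / total


# ---------------------------------------------------------------------------
# 18S amplicons


@dataclass
class AsvTable:
    """ASV counts with per-ASV taxonomy paths and per-sample fraction labels."""

    counts: pd.DataFrame  # ASV x sample
    taxonomy: dict[str, tuple[str, ...]]
    sample_fraction: dict[str, str]
    sample_timepoint: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("ASV counts must be non-negative")
        for s in self.counts.columns:
            frac = self.sample_fraction.get(s)
            if frac not in FRACTIONS:
                raise ParameterError(
                    f"sample {s!r} needs a fraction label in {FRACTIONS}, got {frac!r}"
                )
            if s not in self.sample_timepoint:
                raise ParameterError(f"sample {s!r} lacks a timepoint label")


@dataclass
class RelativeAbundance:
    table: pd.DataFrame  # ASV x timepoint, columns sum to 1
    warnings: list[str]


def relative_abundance_18s(
    asv: AsvTable,
    exclude_taxon: str = "Metazoa",
    combine_fractions: bool = True,
) -> RelativeAbundance:
    """Relative eukaryotic community composition per timepoint.

    ASVs whose taxonomy path contains ``exclude_taxon`` at any rank
    (case-insensitive) are dropped first; then, if requested, the two
    size-fraction samples of each timepoint are summed; finally each
    timepoint column is normalized to 1.  A timepoint missing one fraction
    is used as-is with a warning.
    """
    excl = exclude_taxon.lower()
    keep = [
        a
        for a in asv.counts.index
        if all(rank.lower() != excl for rank in asv.taxonomy.get(a, ()))
    ]
    counts = asv.counts.loc[keep]
    warnings: list[str] = []

    if combine_fractions:
        timepoints = sorted(set(asv.sample_timepoint[s] for s in counts.columns))
        cols = {}
        for tp in timepoints:
            samples = [s for s in counts.columns if asv.sample_timepoint[s] == tp]
            fracs = {asv.sample_fraction[s] for s in samples}
            if fracs != set(FRACTIONS):
                warnings.append(
                    f"timepoint {tp}: unpaired fraction(s) {sorted(fracs)}, "
                    "single fraction used"
                )
            cols[tp] = counts[samples].sum(axis=1)
        combined = pd.DataFrame(cols)
    else:
        combined = counts.copy()

    totals = combined.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise QuantError(
            f"no reads left after filtering in: {list(zero.index)}"
        )
    return RelativeAbundance(table=combined.div(totals, axis=1), warnings=warnings)
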