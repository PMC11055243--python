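"""Count filtering, log2-CPM normalization and per-pair log2-ratio profiles.

The analysis unit downstream is a :class:`PairProfile`: one matched
pair's per-gene log2 expression ratio (intracranial minus extracranial),
sorted into chromosomal order and partitioned into one sequence per
chromosome.  Positive ratios mean higher expression in the intracranial
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_io import ExpressionMatrix, PairSet, ValidationError, order_genes


@dataclass
class PairProfile:
    """One matched pair's chromosome-ordered log2-ratio profile."""

    pair_id: str
    gene_ids: pd.Index
    ratios: np.ndarray
    chromosomes: np.ndarray  # chromosome label per gene, same order as ratios

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes)
        if not (len(self.gene_ids) == len(self.ratios) == len(self.chromosomes)):
            raise ValidationError("profile fields have mismatched lengths")
        if np.isnan(self.ratios).any():
            raise ValidationError("missing values in ratio profile")

    def __len__(self) -> int:
        return len(self.ratios)

    @property
    def chromosome_breaks(self) -> list[tuple[str, int, int]]:
        """Half-open index ranges ``(chrom, start, stop)`` per chromosome."""
        breaks = []
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                breaks.append((str(self.chromosomes[start]), start, i))
                start = i
        return breaks

    def segments(self) -> list[tuple[str, np.ndarray]]:
        """Per-chromosome ratio sequences, in chromosomal order."""
        return [(c, self.ratios[a:b]) for c, a, b in self.chromosome_breaks]


def cpm(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million per sample (column library-size normalized)."""
    if counts.scale != "counts":
        raise ValidationError("cpm requires a counts-scale matrix")
    lib = counts.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for sample(s): {zero}")
    return counts.values / lib * 1e6


def cpm_filter(
    counts: ExpressionMatrix,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.25,
    strict: bool = True,
) -> pd.Index:
    """Genes expressed above *cpm_threshold* in enough samples.

    With ``strict=True`` (the default) a gene is kept iff
    CPM > threshold in strictly more than ``sample_fraction`` of the
    samples; ``strict=False`` uses >= on the fraction (the "at least
    50% of patients" style of filter used for external validation
    cohorts).
    """
    if cpm_threshold <= 0 or sample_fraction <= 0:
        raise ValidationError("thresholds must be positive")
    frac = (cpm(counts) > cpm_threshold).mean(axis=1)
    keep = frac > sample_fraction if strict else frac >= sample_fraction
    return counts.gene_ids[keep]


def _ma_loess_offsets(x: np.ndarray, span: float) -> np.ndarray:
    """Loess fit of M = x_i - x_j on A = (x_i + x_j)/2, per-gene fitted M."""
    # x: (genes, 2)
    m = x[:, 0] - x[:, 1]
    a = x.mean(axis=1)
    fit = lowess(m, a, frac=span, return_sorted=False)
    return fit


def normalize_log2cpm(
    counts: ExpressionMatrix,
    loess: bool = False,
    span: float = 0.7,
    tol: float = 0.01,
    max_cycles: int = 3,
) -> ExpressionMatrix:
    """log2(CPM + 0.5), optionally followed by pairwise cyclic-loess.

    The cyclic-loess step visits every unordered sample pair, fits a
    loess curve to the pair's M (difference) versus A (average)
    values, and moves half of the fitted trend out of each sample;
    cycles repeat until the largest per-sample mean offset change drops
    below *tol* or *max_cycles* full cycles have run.  The 0.5
    pseudo-count only affects near-zero counts, which the CPM filter
    removes anyway.
    """
    log2cpm = np.log2(cpm(counts) + 0.5)
    if loess:
        if log2cpm.shape[1] < 2:
            raise ValidationError("cyclic loess requires at least 2 samples")
        x = log2cpm.to_numpy().copy()
        n = x.shape[1]
        for _ in range(max_cycles):
            max_change = 0.0
            for i in range(n - 1):
                for j in range(i + 1, n):
                    fit = _ma_loess_offsets(x[:, [i, j]], span)
                    x[:, i] -= fit / 2
                    x[:, j] += fit / 2
                    max_change = max(max_change, abs(np.mean(fit)))
            if max_change < tol:
                break
        log2cpm = pd.DataFrame(x, index=log2cpm.index, columns=log2cpm.columns)
    return ExpressionMatrix(log2cpm, scale="log2cpm")


def compute_pair_profiles(
    expr: ExpressionMatrix,
    pairs: PairSet,
    annotation: pd.DataFrame,
) -> list[PairProfile]:
    """log2-ratio profile (intra minus extra) per pair, in chromosomal order."""
    if expr.scale != "log2cpm":
        raise ValidationError("pair profiles require a log2cpm-scale matrix")
    from .data_io import validate_annotation

    ann = validate_annotation(annotation)
    missing = expr.gene_ids.difference(ann.index)
    if len(missing):
        raise ValidationError(f"{len(missing)} genes lack annotation")
    order = order_genes(ann.loc[expr.gene_ids])
    values = expr.values.loc[order]
    chroms = ann.loc[order, "chromosome"].astype(str).to_numpy()
    profiles = []
    for row in pairs.pairs.itertuples(index=False):
        for s in (row.intra_sample, row.extra_sample):
            if s not in values.columns:
                raise ValidationError(f"pair {row.pair_id} references missing sample {s}")
        ratios = values[row.intra_sample].to_numpy() - values[row.extra_sample].to_numpy()
        profiles.append(PairProfile(row.pair_id, order, ratios, chroms))
    return profiles


def profiles_to_frame(profiles: list[PairProfile]) -> pd.DataFrame:
    """Tidy genes x pairs table of log2 ratios (genes in chromosomal order)."""
    if not profiles:
        raise ValidationError("no profiles")
    base = profiles[0]
    df = pd.DataFrame(index=base.gene_ids)
    df["chromosome"] = base.chromosomes
    for p in profiles:
        if not p.gene_ids.equals(base.gene_ids):
            raise ValidationError("profiles have mismatched gene universes")
        df[p.pair_id] = p.ratios
    df.index.name = "gene_id"
    return df
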