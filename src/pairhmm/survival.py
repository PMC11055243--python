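"""Quartile-split Kaplan-Meier survival screen over candidate genes.

For each gene, patients of an external cohort are split into a low
(expression <= first quartile) and a high (expression >= third
quartile) group; the two groups' survival curves are compared with a
two-group log-rank test, and p-values are Benjamini-Hochberg adjusted
across all screened genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import ExpressionMatrix, ValidationError
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)


def validate_survival_table(survival: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with non-negative ``time`` and 0/1 ``event``."""
    surv = survival.copy()
    if "patient_id" in surv.columns:
        surv = surv.set_index("patient_id")
    if surv.index.has_duplicates:
        raise ValidationError("duplicate patients in survival table")
    missing = {"time", "event"} - set(surv.columns)
    if missing:
        raise ValidationError(f"survival table missing columns: {sorted(missing)}")
    if (surv["time"] < 0).any():
        raise ValidationError("negative survival times")
    if not surv["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (death)")
    return surv


def quartile_groups(expr: pd.Series) -> tuple[pd.Index, pd.Index]:
    """(low, high) patient groups for one gene's expression.

    Low = patients with expression <= Q1, high = expression >= Q3
    (linear-interpolation quantiles); patients strictly between are
    excluded.  Ties at a boundary fall into the group (<=, >= rules).
    """
    x = expr.dropna()
    if len(x) < 8:
        raise ValidationError("need at least 8 patients for a quartile split")
    q1, q3 = np.quantile(x.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        raise ValidationError("degenerate (near-constant) expression")
    return x.index[x <= q1], x.index[x >= q3]


def logrank_test(
    low: pd.Index, high: pd.Index, survival: pd.DataFrame
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    Ties are handled with the standard hypergeometric variance formula.
    Returns (0, 1) with a warning when no event occurred.
    """
    surv = validate_survival_table(survival)
    a, b = surv.loc[low], surv.loc[high]
    if a.empty or b.empty:
        raise ValidationError("both groups must be non-empty")
    if a["event"].sum() + b["event"].sum() == 0:
        logger.warning("no events in either group; log-rank undefined")
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(group: pd.Index, survival: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Kaplan-Meier survival curve for one patient group (for plotting)."""
    surv = validate_survival_table(survival).loc[group]
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"], label=label or "group")
    out = kmf.survival_function_
    out.columns = ["survival"]
    return out


@dataclass
class SurvivalScreen:
    table: pd.DataFrame  # gene_id, n_low, n_high, statistic, p, q, significant
    alpha_q: float

    @property
    def significant(self) -> pd.Index:
        return pd.Index(self.table.loc[self.table["significant"], "gene_id"])


def survival_screen(
    expr: ExpressionMatrix,
    genes,
    survival: pd.DataFrame,
    alpha_q: float = 0.1,
) -> SurvivalScreen:
    """Quartile-split log-rank screen over *genes*, BH-adjusted.

    ``expr`` holds genes x patients expression; quartiles are computed
    over the patients present in both the matrix and the survival
    table.  Genes absent from the matrix are skipped with a warning.
    """
    surv = validate_survival_table(survival)
    patients = expr.sample_ids.intersection(surv.index)
    if len(patients) < 8:
        raise ValidationError("fewer than 8 patients with both expression and survival")
    rows = []
    for gene in genes:
        if gene not in expr.gene_ids:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        low, high = quartile_groups(expr.values.loc[gene, patients])
        stat, p = logrank_test(low, high, surv)
        rows.append(
            {"gene_id": gene, "n_low": len(low), "n_high": len(high),
             "statistic": stat, "p": p}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValidationError("no screened genes present in the expression matrix")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha_q
    return SurvivalScreen(table, alpha_q)


def cohort_prefilter(
    counts: ExpressionMatrix,
    tumor_content: pd.Series | None = None,
    min_tumor_content: float = 0.8,
    cpm_threshold: float = 1.0,
    min_sample_fraction: float = 0.5,
) -> ExpressionMatrix:
    """External-cohort pre-filters: tumor content and inclusive CPM filter.

    Keeps samples with tumor content >= *min_tumor_content* (when a
    content series is given) and genes with CPM > *cpm_threshold* in at
    least *min_sample_fraction* of the remaining samples.
    """
    from .preprocess import cpm_filter

    values = counts.values
    if tumor_content is not None:
        keep = tumor_content.index[tumor_content >= min_tumor_content]
        values = values[values.columns.intersection(keep)]
    filtered = ExpressionMatrix(values, scale=counts.scale)
    genes = cpm_filter(filtered, cpm_threshold, min_sample_fraction, strict=False)
    return ExpressionMatrix(values.loc[genes], scale=counts.scale)
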