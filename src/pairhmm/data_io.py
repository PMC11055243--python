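"""Loading, validation and pairing of matched-cohort expression data.

The cohort layout this package expects mirrors a patient-matched tumor
study: each patient contributes at least one intracranial and one
extracranial sample, and every (intracranial, extracranial) combination
within a patient forms one analysis pair.  Expression is carried as a
genes x samples matrix (raw counts or log2-CPM) together with a gene
annotation giving each gene's chromosome and start coordinate, which
defines the chromosomal gene order the downstream HMM relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed chromosome labels, in genomic sort order (autosomes, then X, Y).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Compartment labels a sample sheet may use.
COMPARTMENTS = ("intracranial", "extracranial")

#: Short tissue codes used to build human-readable pair ids.
TISSUE_CODES = {
    "brain": "B",
    "lung": "Lun",
    "lymph node": "Lym",
    "skin": "Ski",
    "liver": "Liv",
    "small intestine": "Smi",
    "soft tissue": "Sof",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table.

    Parameters
    ----------
    annotation
        DataFrame indexed by gene id (or with a ``gene_id`` column) with
        columns ``chromosome`` (label in 1..22, X, Y) and ``start``
        (1-based bp position used only for ordering).

    Returns
    -------
    The validated annotation, indexed by gene id with ``chromosome`` as
    string labels.
    """
    ann = annotation.copy()
    if "gene_id" in ann.columns:
        ann = ann.set_index("gene_id")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate gene ids in annotation: {dups}")
    missing = {"chromosome", "start"} - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    ann["chromosome"] = ann["chromosome"].astype(str)
    bad = set(ann["chromosome"]) - set(CHROMOSOMES)
    if bad:
        raise ValidationError(
            f"unknown chromosome labels {sorted(bad)!r}; allowed: 1..22, X, Y"
        )
    ann["start"] = ann["start"].astype(np.int64)
    if (ann["start"] < 1).any():
        raise ValidationError("gene start positions must be >= 1 (1-based)")
    return ann


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale.

    ``scale`` is ``"counts"`` (raw non-negative read counts) or
    ``"log2cpm"`` (already normalized log2 counts-per-million).
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2cpm"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric cells in expression matrix")
        if np.isnan(arr).any():
            raise ValidationError("missing values in expression matrix")
        if self.scale == "counts" and (arr < 0).any():
            raise ValidationError("negative values in a counts-scale matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PairSet:
    """All patient-matched (intracranial, extracranial) sample pairs."""

    pairs: pd.DataFrame  # columns: pair_id, patient_id, intra_sample, extra_sample

    def __post_init__(self) -> None:
        if self.pairs["pair_id"].duplicated().any():
            raise ValidationError("duplicate pair ids")

    def __len__(self) -> int:
        return len(self.pairs)

    def patient_of(self, pair_id: str) -> str:
        row = self.pairs.loc[self.pairs["pair_id"] == pair_id]
        if row.empty:
            raise KeyError(pair_id)
        return row["patient_id"].iloc[0]

    def pair_to_patient(self) -> dict[str, str]:
        return dict(zip(self.pairs["pair_id"], self.pairs["patient_id"]))


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet invariants (unique sample ids, known compartments)."""
    required = {"sample_id", "patient_id", "compartment"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    bad = set(sheet["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValidationError(f"unknown compartment labels: {sorted(bad)}")
    return sheet.reset_index(drop=True)


def load_expression(
    path, annotation_path=None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read an expression TSV and its gene annotation.

    The TSV layout is ``gene_id``, ``chromosome``, ``start`` followed by
    one column per sample (the annotation may also live in a separate
    three-column file passed as *annotation_path*).  Genes present in
    the matrix but absent from a separate annotation are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError("expression TSV must have a gene_id column")
    df = df.set_index("gene_id")
    if annotation_path is None:
        if not {"chromosome", "start"} <= set(df.columns):
            raise ValidationError(
                "expression TSV lacks chromosome/start columns and no "
                "annotation file was given"
            )
        ann = validate_annotation(df[["chromosome", "start"]])
        values = df.drop(columns=["chromosome", "start"])
    else:
        ann = validate_annotation(pd.read_csv(annotation_path, sep="\t"))
        values = df.drop(columns=[c for c in ("chromosome", "start") if c in df])
        unknown = values.index.difference(ann.index)
        if len(unknown):
            raise ValidationError(
                f"{len(unknown)} genes missing from annotation, e.g. "
                f"{unknown[:3].tolist()}"
            )
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression cells: {exc}") from exc
    scale = "counts" if (values.to_numpy() % 1 == 0).all() and (
        values.to_numpy() >= 0
    ).all() else "log2cpm"
    return ExpressionMatrix(values, scale=scale), ann.loc[values.index]


def write_expression(expr: ExpressionMatrix, annotation: pd.DataFrame, path) -> None:
    """Write matrix + annotation back to the canonical TSV layout."""
    ann = annotation.loc[expr.gene_ids, ["chromosome", "start"]]
    out = pd.concat([ann, expr.values], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def load_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def order_genes(annotation: pd.DataFrame) -> pd.Index:
    """Chromosomal gene order: chromosome 1..22, X, Y, then ascending start.

    The sort is stable, so genes tied on (chromosome, start) keep their
    input order.
    """
    ann = validate_annotation(annotation)
    rank = ann["chromosome"].map(_CHROM_RANK)
    order = np.lexsort((np.arange(len(ann)), ann["start"].to_numpy(), rank.to_numpy()))
    return ann.index[order]


def _pair_id(patient: str, intra_tissue: str, extra_tissue: str,
             intra_ord: int | None, extra_ord: int | None) -> str:
    intra_code = TISSUE_CODES.get(intra_tissue, "B")
    extra_code = TISSUE_CODES.get(extra_tissue, (extra_tissue or "X")[:3].title())
    pid = f"{patient}_{intra_code}"
    if intra_ord is not None:
        pid += str(intra_ord)
    pid += extra_code
    if extra_ord is not None:
        pid += f"-{extra_ord}"
    return pid


def build_pairs(sheet: pd.DataFrame) -> PairSet:
    """Form every patient-matched intracranial/extracranial sample pair.

    One pair per (intracranial sample, extracranial sample) combination
    within each patient, so the total pair count is the sum over
    patients of ``n_intra * n_extra``.  Patients lacking one compartment
    are skipped with a warning.  Pair ids follow the tissue-code
    convention (e.g. ``P42_BLym-2`` for the second lymph-node sample of
    patient P42 paired with their brain sample).
    """
    sheet = validate_sample_sheet(sheet)
    if "tissue" not in sheet.columns:
        sheet = sheet.assign(
            tissue=np.where(sheet["compartment"] == "intracranial", "brain", "other")
        )
    rows = []
    for patient, grp in sheet.groupby("patient_id", sort=False):
        intra = grp[grp["compartment"] == "intracranial"]
        extra = grp[grp["compartment"] == "extracranial"]
        if intra.empty or extra.empty:
            logger.warning(
                "patient %s lacks one compartment (%d intra, %d extra); skipped",
                patient, len(intra), len(extra),
            )
            continue
        multi_intra = len(intra) > 1
        multi_extra = len(extra) > 1
        for i, (_, irow) in enumerate(intra.iterrows(), start=1):
            for j, (_, erow) in enumerate(extra.iterrows(), start=1):
                rows.append(
                    {
                        "pair_id": _pair_id(
                            patient, irow["tissue"], erow["tissue"],
                            i if multi_intra else None,
                            j if multi_extra else None,
                        ),
                        "patient_id": patient,
                        "intra_sample": irow["sample_id"],
                        "extra_sample": erow["sample_id"],
                    }
                )
    return PairSet(pd.DataFrame(rows, columns=["pair_id", "patient_id",
                                               "intra_sample", "extra_sample"]))
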