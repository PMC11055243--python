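"""Synthetic matched-pair cohorts with the structure the pipeline assumes.

The generator emulates the statistical features the analysis relies on,
at desk scale: per-pair log2-ratio profiles produced by the three-state
HMM itself (segmental runs of shifted means along chromosomes with
Gaussian noise), several pairs per patient with tunable within-patient
state agreement, pathway gene sets with planted enrichment, and
survival times whose hazard depends on chosen genes' expression.  It
deliberately does not model count-level RNA-seq noise (library sizes,
overdispersion); expression is emitted directly on the log2-CPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    PairSet,
    ValidationError,
    build_pairs,
    validate_annotation,
)
from .enrichment import PathwayCollection
from .hmm import STATES, HmmParameters
from .preprocess import PairProfile

#: Extracranial sample counts per patient in a 16-patient matched cohort
#: (one intracranial sample each; 21 pairs, 37 samples in total).
STUDY_EXTRA_COUNTS = (1, 2, 3, 1, 1, 2, 1, 2, 1, 1, 1, 1, 1, 1, 1, 1)

STUDY_EXTRA_TISSUES = (
    "lung", "skin", "soft tissue", "lymph node", "lung", "lung", "lung",
    "lymph node", "lymph node", "lymph node", "small intestine", "liver",
    "lymph node", "lung", "lymph node", "lymph node",
)

STUDY_PATIENTS = (
    "P03", "P04", "P08", "P13", "P16", "P18", "P39", "P42",
    "P74", "P77", "P78", "P101", "P106", "P107", "P108", "P111",
)


def study_design_sheet() -> pd.DataFrame:
    """Sample sheet replicating the published 16-patient cohort layout."""
    rows = []
    for pid, n_extra, tissue in zip(STUDY_PATIENTS, STUDY_EXTRA_COUNTS, STUDY_EXTRA_TISSUES):
        rows.append(
            {"sample_id": f"{pid}_B", "patient_id": pid,
             "compartment": "intracranial", "tissue": "brain"}
        )
        for j in range(1, n_extra + 1):
            sid = f"{pid}_E{j}" if n_extra > 1 else f"{pid}_E"
            rows.append(
                {"sample_id": sid, "patient_id": pid,
                 "compartment": "extracranial", "tissue": tissue}
            )
    return pd.DataFrame(rows)


def default_generative_parameters() -> HmmParameters:
    """Ground-truth HMM used to simulate ratio profiles.

    Same emission layout as :func:`pairhmm.hmm.initial_parameters`
    (means -3/0/3, SDs 0.5/1/0.5) but with a stickier unchanged state so
    that roughly 17% of genes are differential in runs of ~5 genes,
    matching the scale seen in real matched tumor pairs.
    """
    return HmmParameters(
        start=np.array([0.1, 0.8, 0.1]),
        transitions=np.array(
            [[0.80, 0.19, 0.01],
             [0.02, 0.96, 0.02],
             [0.01, 0.19, 0.80]]
        ),
        means=np.array([-3.0, 0.0, 3.0]),
        sds=np.array([0.5, 1.0, 0.5]),
    )


def make_annotation(chromosome_lengths: dict[str, int]) -> pd.DataFrame:
    """Gene annotation for synthetic genomes (10 kb gene spacing)."""
    rows = []
    g = 0
    for chrom, n in chromosome_lengths.items():
        for i in range(n):
            g += 1
            rows.append({"gene_id": f"g{g:05d}", "chromosome": chrom,
                         "start": 1 + i * 10_000})
    return validate_annotation(pd.DataFrame(rows))


@dataclass
class SimulationConfig:
    """Cohort-generator settings (defaults are desk-scale but keep the
    published cohort's patient/pair composition)."""

    n_patients: int = 16
    pairs_per_patient: tuple[int, ...] = STUDY_EXTRA_COUNTS
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 700, "2": 650, "3": 600, "4": 550, "5": 500}
    )
    params: HmmParameters = field(default_factory=default_generative_parameters)
    rho: float = 0.9                      # within-patient state agreement
    baseline_mean: float = 6.0            # extracranial log2-CPM location
    baseline_sd: float = 2.0
    #: pathway_id -> (direction, force_prob): each pathway gene's latent
    #: state is forced to `direction` with this probability, per patient.
    pathway_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValidationError("rho must lie in [0, 1]")
        if len(self.pairs_per_patient) != self.n_patients:
            raise ValidationError("pairs_per_patient length must equal n_patients")

    @property
    def n_genes(self) -> int:
        return sum(self.chromosome_lengths.values())


def _simulate_states(
    params: HmmParameters, chromosome_lengths: dict[str, int], rng: np.random.Generator
) -> np.ndarray:
    """Latent state indices along all chromosomes (independent chains)."""
    out = []
    for n in chromosome_lengths.values():
        s = np.empty(n, dtype=np.int64)
        s[0] = rng.choice(3, p=params.start)
        for t in range(1, n):
            s[t] = rng.choice(3, p=params.transitions[s[t - 1]])
        out.append(s)
    return np.concatenate(out)


def _emit(params: HmmParameters, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(params.means[states], params.sds[states])


def simulate_hmm_profile(
    params: HmmParameters,
    chromosome_lengths: dict[str, int],
    seed: int | np.random.Generator | None = None,
    pair_id: str = "sim",
    annotation: pd.DataFrame | None = None,
) -> tuple[PairProfile, np.ndarray]:
    """One ratio profile drawn from the HMM; returns (profile, true states).

    Each chromosome is an independent chain: initial state from the
    start distribution, Markov transitions, observation from the
    state's Gaussian.  True states are returned as symbols.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ann = annotation if annotation is not None else make_annotation(chromosome_lengths)
    states = _simulate_states(params, chromosome_lengths, rng)
    ratios = _emit(params, states, rng)
    profile = PairProfile(pair_id, ann.index, ratios, ann["chromosome"].to_numpy())
    return profile, np.asarray(STATES)[states]


def stationary_distribution(params: HmmParameters) -> np.ndarray:
    """Stationary state distribution of the transition chain."""
    w, v = np.linalg.eig(params.transitions.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    return pi / pi.sum()


def planted_force_prob(odds: float, params: HmmParameters, state: str = "-") -> float:
    """Forcing probability that gives pathway genes the requested
    enrichment odds (odds ratio of the latent state assignment inside
    versus outside the pathway)."""
    if odds <= 0:
        raise ValidationError("enrichment odds must be positive")
    p_bg = float(stationary_distribution(params)[STATES.index(state)])
    r = odds * p_bg / (1 - p_bg)
    p_pw = r / (1 + r)
    return max(0.0, (p_pw - p_bg) / (1 - p_bg))


def make_pathways(
    gene_ids,
    n_pathways: int = 10,
    size: int = 40,
    seed: int | np.random.Generator | None = None,
) -> PathwayCollection:
    """Random non-exclusive gene sets over the synthetic genome."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = np.asarray(gene_ids)
    pathways = {}
    for i in range(1, n_pathways + 1):
        genes = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        pathways[f"pw{i:02d}"] = (f"synthetic pathway {i}", frozenset(genes))
    return PathwayCollection(pathways)


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the ground truth."""

    expression: ExpressionMatrix           # log2-CPM, genes x samples
    annotation: pd.DataFrame
    sample_sheet: pd.DataFrame
    pairs: PairSet
    true_states: pd.DataFrame              # genes x pairs, symbols
    pathways: PathwayCollection | None
    config: SimulationConfig


def simulate_cohort(
    config: SimulationConfig,
    pathways: PathwayCollection | None = None,
) -> SyntheticCohort:
    """Full cohort: expression matrix, sample sheet, annotation, truth.

    Per patient a shared latent state vector is drawn from the HMM;
    each of the patient's pairs copies it, resampling every gene's
    state independently with probability 1 - rho (from the start
    distribution), which makes rho the tunable same-patient agreement.
    Planted pathway effects bias the patient's latent states inside the
    chosen gene sets.  The intracranial log2-CPM profile is drawn once
    per patient and each extracranial sample is intracranial minus the
    pair's ratio, so recomputed pair profiles equal the simulated ones.
    """
    rng = np.random.default_rng(config.seed)
    ann = make_annotation(config.chromosome_lengths)
    genes = ann.index

    sheet_rows = []
    for p in range(config.n_patients):
        pid = f"S{p + 1:02d}"
        n_extra = config.pairs_per_patient[p]
        sheet_rows.append({"sample_id": f"{pid}_B", "patient_id": pid,
                           "compartment": "intracranial", "tissue": "brain"})
        tissue = STUDY_EXTRA_TISSUES[p % len(STUDY_EXTRA_TISSUES)]
        for j in range(1, n_extra + 1):
            sid = f"{pid}_E{j}" if n_extra > 1 else f"{pid}_E"
            sheet_rows.append({"sample_id": sid, "patient_id": pid,
                               "compartment": "extracranial", "tissue": tissue})
    sheet = pd.DataFrame(sheet_rows)
    pairs = build_pairs(sheet)

    planted: list[tuple[np.ndarray, float]] = []
    if pathways is not None:
        for pid, (direction, prob) in config.pathway_effects.items():
            if pid not in pathways.pathways:
                raise ValidationError(f"planted pathway {pid} not in collection")
            mask = np.isin(np.asarray(genes), list(pathways.pathways[pid][1]))
            planted.append((mask, prob, STATES.index(direction)))

    expr = pd.DataFrame(index=genes, dtype=float)
    truth = {}
    for pid, grp in pairs.pairs.groupby("patient_id", sort=False):
        latent = _simulate_states(config.params, config.chromosome_lengths, rng)
        for mask, prob, state_idx in planted:
            force = mask & (rng.random(len(genes)) < prob)
            latent[force] = state_idx
        intra = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
        intra_sample = grp["intra_sample"].iloc[0]
        expr[intra_sample] = intra
        for row in grp.itertuples(index=False):
            states = latent.copy()
            resample = rng.random(len(genes)) >= config.rho
            states[resample] = rng.choice(3, p=config.params.start, size=resample.sum())
            ratios = _emit(config.params, states, rng)
            expr[row.extra_sample] = intra - ratios
            truth[row.pair_id] = np.asarray(STATES)[states]

    true_states = pd.DataFrame(truth, index=genes)
    return SyntheticCohort(
        ExpressionMatrix(expr, scale="log2cpm"), ann, sheet, pairs,
        true_states, pathways, config,
    )


def simulate_survival(
    n_patients: int = 300,
    genes: tuple[str, ...] = tuple(f"sg{i:02d}" for i in range(1, 21)),
    betas: dict[str, float] | None = None,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 5e-4,
    expr_mean: float = 6.0,
    expr_sd: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Survival table + expression matrix with gene-driven hazards.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_g beta_g z_g)`` (z = standardized
    expression); censoring is an independent exponential at
    *censor_rate*.  ``betas`` defaults to the global null (all zero).
    """
    rng = np.random.default_rng(seed)
    patients = pd.Index([f"T{i:03d}" for i in range(1, n_patients + 1)])
    expr = pd.DataFrame(
        rng.normal(expr_mean, expr_sd, size=(len(genes), n_patients)),
        index=pd.Index(genes, name="gene_id"), columns=patients,
    )
    z = (expr - expr.mean(axis=1).to_numpy()[:, None]) / expr.std(axis=1).to_numpy()[:, None]
    log_hr = np.zeros(n_patients)
    for g, beta in (betas or {}).items():
        if not np.isfinite(beta):
            raise ValidationError("hazard coefficients must be finite")
        log_hr += beta * z.loc[g].to_numpy()
    hazard = baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1 / censor_rate, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    surv = pd.DataFrame(
        {
            "patient_id": patients,
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )
    return surv, ExpressionMatrix(expr, scale="log2cpm")
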