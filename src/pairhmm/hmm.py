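"""Three-state Gaussian HMM with Bayesian (MAP) Baum-Welch training.

The model classifies each gene of a chromosome-ordered log2-ratio
profile into one of three expression states — ``-`` (decreased), ``=``
(unchanged), ``+`` (increased in the intracranial sample) — with
state-specific Gaussian emission densities over the log2 ratio.  A
first-order Markov chain along the chromosomal gene order captures the
positional persistence of expression shifts (neighboring genes tend to
share a state).

Training is expectation-maximization over all chromosome sequences of
all pairs pooled into one parameter set, with MAP (rather than ML)
M-step updates for the emission parameters:

    mu_i    <- (sum_t g_t(i) x_t + kappa_i m_i) / (sum_t g_t(i) + kappa_i)
    sigma_i^2 <- (sum_t g_t(i)(x_t - mu_i)^2 + kappa_i (mu_i - m_i)^2
                  + nu_i s_i^2) / (sum_t g_t(i) + nu_i)

where (m_i, s_i) are prior means/SDs and (kappa_i, nu_i) pseudo-count
hyperparameters ("scaleMeans" / "shapeSds").  These are the exact joint
maximizers of the EM Q-function plus the log-penalty

    -kappa_i (mu_i - m_i)^2 / (2 sigma_i^2)
    - nu_i/2 log sigma_i^2 - nu_i s_i^2 / (2 sigma_i^2)

so the penalized log-likelihood is monotone non-decreasing over EM
iterations.  kappa = nu = 0 gives classical ML Baum-Welch; kappa, nu ->
infinity pins the emissions to the prior.  Start and transition
probabilities use the ordinary ML Baum-Welch ratios.

State identity is anchored by the ordered-means invariant
mu_- < mu_= < mu_+; an update that violates it raises instead of
silently relabeling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ValidationError
from .preprocess import PairProfile

logger = logging.getLogger(__name__)

#: State symbols in fixed index order (decreased, unchanged, increased).
STATES = ("-", "=", "+")

_LOG2PI = float(np.log(2 * np.pi))


class LabelSwitchError(RuntimeError):
    """Emission means lost their '-' < '=' < '+' ordering during training."""


@dataclass
class HmmParameters:
    """Start, transition and Gaussian emission parameters."""

    start: np.ndarray
    transitions: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.start.shape != (3,) or self.transitions.shape != (3, 3):
            raise ValidationError("expected 3 states")
        if abs(self.start.sum() - 1) > 1e-10:
            raise ValidationError("start probabilities must sum to 1")
        if np.abs(self.transitions.sum(axis=1) - 1).max() > 1e-10:
            raise ValidationError("transition rows must sum to 1")
        if (self.sds <= 0).any():
            raise ValidationError("emission SDs must be positive")
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise LabelSwitchError(
                f"means not ordered '-' < '=' < '+': {self.means.tolist()}"
            )

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        return cls(**{k: np.asarray(d[k]) for k in ("start", "transitions", "means", "sds")})


@dataclass
class HmmPriors:
    """Conjugate-style prior hyperparameters for the emission densities.

    ``prior_means``/``prior_sds`` are the anchor values; ``scale_means``
    (kappa) and ``shape_sds`` (nu) are pseudo-counts controlling how
    strongly the data may pull the means / SDs away from them.
    """

    prior_means: np.ndarray
    prior_sds: np.ndarray
    scale_means: np.ndarray
    shape_sds: np.ndarray

    def __post_init__(self) -> None:
        for name in ("prior_means", "prior_sds", "scale_means", "shape_sds"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.scale_means < 0).any() or (self.shape_sds < 0).any():
            raise ValidationError("pseudo-counts must be non-negative")
        if (self.prior_sds <= 0).any():
            raise ValidationError("prior SDs must be positive")


def initial_parameters() -> HmmParameters:
    """Default initialization for log2-ratio profiles.

    Emission means (-3, 0, 3) with SDs (0.5, 1, 0.5) put the unchanged
    state at ratio zero with clearly separated shifted states; start
    probabilities (0.1, 0.8, 0.1) encode that most genes are unchanged.
    Self-transitions start at 0.8 (positional persistence) with the
    remaining mass split proportionally to the other states' start
    probabilities.
    """
    start = np.array([0.1, 0.8, 0.1])
    A = np.empty((3, 3))
    for i in range(3):
        others = [j for j in range(3) if j != i]
        w = start[others] / start[others].sum()
        A[i, i] = 0.8
        A[i, others] = 0.2 * w
    return HmmParameters(start, A, np.array([-3.0, 0.0, 3.0]), np.array([0.5, 1.0, 0.5]))


def default_priors(
    scale_means=(2500.0, 1000.0, 2500.0),
    shape_sds=(5000.0, 10.0, 5000.0),
    initial: HmmParameters | None = None,
) -> HmmPriors:
    """Priors anchored at the initial emission parameters.

    The default pseudo-counts are the grid-search winners for matched
    tumor-pair profiles: strong anchors on the shifted states, a weak
    one on the unchanged state.
    """
    init = initial or initial_parameters()
    return HmmPriors(init.means.copy(), init.sds.copy(),
                     np.asarray(scale_means, float), np.asarray(shape_sds, float))


def _scaled_emissions(params: HmmParameters, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-t emission densities scaled by their row max; returns (b, log-shift)."""
    z = (x[:, None] - params.means[None, :]) / params.sds[None, :]
    logb = -0.5 * z * z - np.log(params.sds)[None, :] - 0.5 * _LOG2PI
    shift = logb.max(axis=1)
    return np.exp(logb - shift[:, None]), shift


def forward_backward(
    params: HmmParameters, sequence: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward over one chromosome sequence.

    Returns ``(log_likelihood, gamma, xi_sum)`` where ``gamma`` is the
    T x 3 matrix of state posteriors (rows sum to 1) and ``xi_sum`` the
    3 x 3 matrix of transition-pair posteriors summed over t
    (so ``xi_sum.sum(axis=1)[i] == gamma[:-1, i].sum()``).
    """
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValidationError("sequence must be a non-empty 1-D vector")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite observation in sequence")
    T = len(x)
    b, shift = _scaled_emissions(params, x)
    A = params.transitions
    alpha = np.empty((T, 3))
    c = np.empty(T)
    a = params.start * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, 3))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    if T > 1:
        xi_sum = A * (alpha[:-1].T @ (b[1:] * beta[1:] / c[1:, None]))
    else:
        xi_sum = np.zeros((3, 3))
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma, xi_sum


def log_prior(params: HmmParameters, priors: HmmPriors) -> float:
    """Unnormalized log-penalty on the emission parameters (see module doc)."""
    var = params.sds**2
    mu_pen = -priors.scale_means * (params.means - priors.prior_means) ** 2 / (2 * var)
    sd_pen = -0.5 * priors.shape_sds * np.log(var) \
        - priors.shape_sds * priors.prior_sds**2 / (2 * var)
    return float(mu_pen.sum() + sd_pen.sum())


@dataclass
class _SufficientStats:
    """Accumulated E-step statistics over all sequences."""

    n_seq: int = 0
    gamma0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    xi: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    gw: np.ndarray = field(default_factory=lambda: np.zeros(3))    # sum gamma
    gx: np.ndarray = field(default_factory=lambda: np.zeros(3))    # sum gamma*x
    gxx: np.ndarray = field(default_factory=lambda: np.zeros(3))   # sum gamma*x^2
    loglik: float = 0.0

    def add(self, x: np.ndarray, loglik: float, gamma: np.ndarray, xi_sum: np.ndarray) -> None:
        self.n_seq += 1
        self.gamma0 += gamma[0]
        self.xi += xi_sum
        self.gw += gamma.sum(axis=0)
        self.gx += gamma.T @ x
        self.gxx += gamma.T @ (x * x)
        self.loglik += loglik


def map_update(params: HmmParameters, priors: HmmPriors, stats: _SufficientStats) -> HmmParameters:
    """One MAP M-step from accumulated sufficient statistics."""
    start = stats.gamma0 / stats.n_seq
    row = stats.xi.sum(axis=1)
    A = params.transitions.copy()
    usable = row > 0
    A[usable] = stats.xi[usable] / row[usable, None]  # rows w/o transitions keep old values
    kappa, nu = priors.scale_means, priors.shape_sds
    dead = (stats.gw == 0) & (kappa == 0) & (nu == 0)
    if dead.any():
        raise ValidationError(
            f"state(s) {[STATES[i] for i in np.where(dead)[0]]} have zero "
            "responsibility and no prior pseudo-counts"
        )
    mu = (stats.gx + kappa * priors.prior_means) / (stats.gw + kappa)
    sse = stats.gxx - 2 * mu * stats.gx + mu * mu * stats.gw
    var = (sse + kappa * (mu - priors.prior_means) ** 2 + nu * priors.prior_sds**2) \
        / (stats.gw + nu)
    return HmmParameters(start, A, mu, np.sqrt(var))


@dataclass
class TrainingResult:
    params: HmmParameters
    history: np.ndarray  # penalized log-likelihood per iteration
    n_iter: int
    converged: bool


def baum_welch_map(
    initial: HmmParameters,
    priors: HmmPriors,
    sequences: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> TrainingResult:
    """MAP Baum-Welch over multiple independent chromosome sequences.

    Every sequence restarts from the start distribution (one chain per
    chromosome per pair); all sequences share one parameter set.  Stops
    when the relative improvement of the penalized log-likelihood drops
    below *tol* or after *max_iter* iterations (returned with
    ``converged=False`` and a warning).
    """
    if not sequences:
        raise ValidationError("no training sequences")
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    params = initial
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        stats = _SufficientStats()
        for x in seqs:
            ll, gamma, xi = forward_backward(params, x)
            stats.add(x, ll, gamma, xi)
        penalized = stats.loglik + log_prior(params, priors)
        history.append(penalized)
        if len(history) > 1:
            prev = history[-2]
            if penalized < prev - 1e-8 * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"penalized log-likelihood decreased: {prev} -> {penalized}"
                )
            if abs(penalized - prev) < tol * max(1.0, abs(prev)):
                converged = True
                break
        params = map_update(params, priors, stats)
    if not converged:
        logger.warning("Baum-Welch did not converge within %d iterations", max_iter)
    return TrainingResult(params, np.asarray(history), len(history), converged)


@dataclass
class StateDecoding:
    """Posterior decoding of one pair profile."""

    pair_id: str
    gene_ids: object
    states: np.ndarray           # symbols '-', '=', '+'
    gamma: np.ndarray            # per-gene 3-vector state posteriors
    log_likelihood: float

    def state_counts(self) -> dict[str, int]:
        return {s: int((self.states == s).sum()) for s in STATES}


def decode_states(params: HmmParameters, profile: PairProfile) -> StateDecoding:
    """Posterior (gamma-argmax) state per gene, chromosome by chromosome.

    Exact posterior ties are broken toward '=' — conservatively fewer
    differential calls.
    """
    gammas, loglik = [], 0.0
    for _, seg in profile.segments():
        ll, gamma, _ = forward_backward(params, seg)
        gammas.append(gamma)
        loglik += ll
    gamma = np.vstack(gammas)
    states = np.asarray(STATES)[gamma.argmax(axis=1)]
    tied_eq = gamma[:, 1] == gamma.max(axis=1)
    states[tied_eq] = "="
    return StateDecoding(profile.pair_id, profile.gene_ids, states, gamma, loglik)


def profiles_to_sequences(profiles: list[PairProfile]) -> list[np.ndarray]:
    """All chromosome sequences of all pairs, pooled for training."""
    return [seg for p in profiles for _, seg in p.segments()]


def count_misclassified(profile: PairProfile, decoding: StateDecoding) -> tuple[int, int]:
    """(misclassified, differential) counts for one decoded profile.

    A gene is misclassified when its observed ratio sign contradicts its
    decoded state (negative ratio decoded '+', positive decoded '-');
    ratios exactly 0 are never misclassified.  Differential = decoded
    '+' or '-'.
    """
    x, s = profile.ratios, decoding.states
    mis = int(((x < 0) & (s == "+")).sum() + ((x > 0) & (s == "-")).sum())
    diff = int((s != "=").sum())
    return mis, diff


def grid_search(
    initial: HmmParameters,
    profiles: list[PairProfile],
    grid: list[tuple[tuple[float, float, float], tuple[float, float, float]]],
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Choose (scaleMeans, shapeSds) minimizing sign-contradicting calls.

    For every grid setting the model is trained on all profiles pooled
    and every profile decoded; settings are ranked lexicographically by
    (fewest misclassified genes, most differential genes).  Returns the
    winning :class:`HmmPriors` and a diagnostics table.
    """
    import pandas as pd

    if not grid:
        raise ValidationError("empty hyperparameter grid")
    sequences = profiles_to_sequences(profiles)
    records = []
    for scale_means, shape_sds in grid:
        priors = default_priors(scale_means, shape_sds, initial)
        result = baum_welch_map(initial, priors, sequences, tol=tol, max_iter=max_iter)
        mis = diff = 0
        for p in profiles:
            m, d = count_misclassified(p, decode_states(result.params, p))
            mis += m
            diff += d
        records.append(
            {
                "scale_means": tuple(scale_means),
                "shape_sds": tuple(shape_sds),
                "misclassified": mis,
                "differential": diff,
                "n_iter": result.n_iter,
                "converged": result.converged,
            }
        )
    table = pd.DataFrame(records).sort_values(
        ["misclassified", "differential"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    best = table.iloc[0]
    return default_priors(best["scale_means"], best["shape_sds"], initial), table


def save_model(result: TrainingResult, priors: HmmPriors, path) -> None:
    """Serialize trained parameters + priors + history to JSON."""
    payload = {
        "params": result.params.to_dict(),
        "priors": {k: np.asarray(v).tolist() for k, v in asdict(priors).items()},
        "history": result.history.tolist(),
        "n_iter": result.n_iter,
        "converged": result.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> tuple[HmmParameters, HmmPriors]:
    with open(path) as fh:
        payload = json.load(fh)
    return (
        HmmParameters.from_dict(payload["params"]),
        HmmPriors(**{k: np.asarray(v) for k, v in payload["priors"].items()}),
    )
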