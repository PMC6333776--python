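"""Maximum-likelihood estimation of latent node activities.

The temporal fitness null model endows each node i with an activity
a_i in (0, 1]; in every time interval the pair (i, j) interacts
independently with probability u = a_i * a_j.  Over tau intervals the
pair count m_ij is Binomial(tau, a_i a_j), so the log-likelihood of the
observed counts is (up to the binomial-coefficient constant)

    L(a) = sum_{i != j} [ m_ij log(a_i a_j) + (tau - m_ij) log(1 - a_i a_j) ]

with the sum over ordered pairs (each unordered pair counted twice, which
rescales L without moving its maximum).  The stationarity conditions are

    H_i(a) = sum_{j != i} (m_ij - tau a_i a_j) / (1 - a_i a_j) = 0 ,

one per node.  The system is solved by a projected damped Newton iteration
with the analytic Jacobian, keeping iterates inside (eps, 1]; activities
pinned at the a_i = 1 boundary with an outward-pointing score (H_i > 0)
are boundary optima and count as converged.

Activities are latent: they are estimated jointly from all pair counts, not
read off any single node's strength, although on null data the estimates
are strongly correlated with node strengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .temporal import AggregateCounts, SnapshotSequence, aggregate_counts

__all__ = [
    "ActivityVector",
    "EstimationConfig",
    "IdentifiabilityError",
    "TemporalActivityModel",
    "init_configuration_model",
    "log_likelihood",
    "estimate_activities",
]

_U_MAX = 1.0 - 1e-12  # cap on a_i*a_j inside H to keep denominators finite


class IdentifiabilityError(ValueError):
    """The likelihood does not identify individual activities (e.g. N = 2)."""


@dataclass(frozen=True)
class ActivityVector:
    """Estimated activities with solver diagnostics.

    ``residual_norm`` is the max KKT residual: |H_i| for interior activities,
    max(0, -H_i) for activities at the upper boundary a_i = 1.
    """

    activities: Mapping
    converged: bool = True
    residual_norm: float = 0.0
    iterations: int = 0
    projected: tuple = ()
    excluded: tuple = ()

    def __getitem__(self, node):
        return self.activities[node]

    def as_array(self, order: Sequence) -> np.ndarray:
        return np.array([self.activities[n] for n in order], dtype=float)

    @property
    def nodes(self) -> tuple:
        return tuple(self.activities)


@dataclass(frozen=True)
class EstimationConfig:
    """Solver knobs: residual tolerance, iteration cap, boundary clip, init mode."""

    tol: float = 1e-8
    max_iter: int = 500
    eps: float = 1e-12
    init_mode: str = "configuration"

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0 < self.eps < 1):
            raise ValueError("eps must be in (0, 1)")


def _as_counts(X) -> AggregateCounts:
    if isinstance(X, SnapshotSequence):
        return aggregate_counts(X)
    if isinstance(X, AggregateCounts):
        return X
    raise TypeError(f"expected AggregateCounts or SnapshotSequence, got {type(X).__name__}")


def _coerce_activities(activities) -> Mapping:
    if isinstance(activities, ActivityVector):
        return activities.activities
    return activities


def init_configuration_model(counts: AggregateCounts, eps: float = 1e-12) -> ActivityVector:
    """Configuration-model starting point for the ML solve.

    a_i = sum_j (m_ij / tau) / sqrt(2 * sum_{i<j} m_ij / tau): the mean
    temporal degree of i over the square root of twice the mean number of
    temporal edges.  Values are clipped into (eps, 1].
    """
    if counts.tau <= 0:
        raise ValueError("tau must be positive")
    total = counts.total_weight
    if total == 0:
        raise ValueError("all pair counts are zero; activities are unidentifiable")
    denom = math.sqrt(2.0 * total / counts.tau)
    strengths = counts.strengths
    a = {
        n: min(1.0, max(eps, (strengths[n] / counts.tau) / denom))
        for n in counts.node_universe
    }
    return ActivityVector(activities=a, converged=False, residual_norm=math.nan, iterations=0)


def log_likelihood(activities, counts: AggregateCounts) -> float:
    """Log-likelihood of the observed counts, ordered-pair (doubled) form.

    Includes the binomial-coefficient constant.  Returns -inf when some pair
    has a_i a_j = 1 but m_ij < tau (zero-probability observation).
    """
    act = _coerce_activities(activities)
    tau = counts.tau
    nodes = list(counts.node_universe)
    a = np.array([act[n] for n in nodes], dtype=float)
    M = counts.to_matrix(nodes)
    U = np.outer(a, a)
    iu = np.triu_indices(len(nodes), k=1)
    m, u = M[iu], U[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_u = np.where(m > 0, np.log(u), 0.0)
        one_minus = 1.0 - u
        bad = (one_minus <= 0) & (tau - m > 0)
        if np.any(bad):
            return -math.inf
        log_1mu = np.where(tau - m > 0, np.log(np.where(one_minus > 0, one_minus, 1.0)), 0.0)
    const = gammaln(tau + 1) - gammaln(m + 1) - gammaln(tau - m + 1)
    # ordered-pair sum: every unordered pair appears twice
    return float(2.0 * np.sum(m * log_u + (tau - m) * log_1mu + const))


def _score_and_jacobian(a: np.ndarray, M: np.ndarray, tau: int):
    """H_i(a) and its Jacobian, with u capped just below 1 for stability."""
    U = np.minimum(np.outer(a, a), _U_MAX)
    np.fill_diagonal(U, 0.0)
    D = 1.0 - U
    R = (M - tau * U) / D
    np.fill_diagonal(R, 0.0)
    H = R.sum(axis=1)
    W = (M - tau) / (D * D)
    np.fill_diagonal(W, 0.0)
    J = a[:, None] * W
    np.fill_diagonal(J, W @ a)
    return H, J


def _kkt_residual(a: np.ndarray, H: np.ndarray, eps: float) -> float:
    """Max violation of the first-order conditions on the box (eps, 1]."""
    r = np.abs(H)
    at_upper = a >= 1.0 - 1e-12
    r[at_upper & (H > 0)] = 0.0  # boundary optimum: score points outward
    at_lower = a <= eps * (1 + 1e-9)
    r[at_lower & (H < 0)] = 0.0
    return float(r.max()) if r.size else 0.0


def _newton_solve(M: np.ndarray, tau: int, a0: np.ndarray, config: EstimationConfig):
    """Projected damped Newton on H(a) = 0 inside the box [eps, 1].

    Activities pinned at the a = 1 boundary with an outward score (H_i > 0)
    are boundary optima; they are frozen out of the Newton system each
    iteration so the remaining components solve their reduced system.
    """
    a = np.clip(a0, config.eps, 1.0)
    H, J = _score_and_jacobian(a, M, tau)
    res = _kkt_residual(a, H, config.eps)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        if res <= config.tol:
            break
        free = ~((a >= 1.0 - 1e-12) & (H > 0))
        step = np.zeros_like(a)
        if free.any():
            Jf = J[np.ix_(free, free)]
            try:
                step[free] = np.linalg.solve(Jf, -H[free])
            except np.linalg.LinAlgError:
                step[free] = np.linalg.lstsq(Jf, -H[free], rcond=None)[0]
        if not np.all(np.isfinite(step)) or not step.any():
            step = np.where(free, -H, 0.0)  # gradient-flavoured fallback
        t = 1.0
        accepted = False
        while t > 1e-14:
            cand = np.clip(a + t * step, config.eps, 1.0)
            H_c, J_c = _score_and_jacobian(cand, M, tau)
            res_c = _kkt_residual(cand, H_c, config.eps)
            if res_c < res:
                a, H, J, res = cand, H_c, J_c, res_c
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
    projected = np.flatnonzero(a >= 1.0 - 1e-12)
    return a, res <= config.tol, res, n_iter, projected


def estimate_activities(
    counts,
    config: EstimationConfig | None = None,
    init: Mapping | None = None,
) -> ActivityVector:
    """ML activities a* solving H(a*) = 0 under the temporal fitness model.

    Nodes with zero total interactions are excluded from the solve (their
    likelihood is maximized at the boundary; they can never host significant
    ties) and reported with a_i = eps.  N = 2 is rejected: a single equation
    only pins down the product a_1 a_2.
    """
    counts = _as_counts(counts)
    config = config or EstimationConfig()
    strengths = counts.strengths
    active = [n for n in counts.node_universe if strengths[n] > 0]
    silent = [n for n in counts.node_universe if strengths[n] == 0]
    if silent:
        warnings.warn(
            f"{len(silent)} node(s) with zero interactions excluded from estimation; "
            f"assigned a_i = {config.eps}",
            stacklevel=2,
        )
    if len(active) == 2:
        raise IdentifiabilityError(
            "two interacting nodes only identify the product a_1*a_2, not each activity"
        )
    if len(active) < 2:
        raise ValueError("need at least 3 interacting nodes to estimate activities")
    if counts.tau <= 0:
        raise ValueError("tau must be positive")

    M = counts.to_matrix(active)
    if init is not None:
        a0 = np.array([_coerce_activities(init)[n] for n in active], dtype=float)
    elif config.init_mode == "configuration":
        cm = init_configuration_model(counts, eps=config.eps)
        a0 = cm.as_array(active)
    else:
        raise ValueError(f"unknown init_mode {config.init_mode!r}")

    a, converged, res, n_iter, projected_idx = _newton_solve(M, counts.tau, a0, config)
    if not converged:
        warnings.warn(
            f"activity estimation did not reach tol={config.tol} within "
            f"{config.max_iter} iterations (residual {res:.3e})",
            stacklevel=2,
        )
    activities = {n: float(v) for n, v in zip(active, a)}
    for n in silent:
        activities[n] = config.eps
    return ActivityVector(
        activities=activities,
        converged=bool(converged),
        residual_norm=float(res),
        iterations=int(n_iter),
        projected=tuple(active[k] for k in projected_idx),
        excluded=tuple(silent),
    )


class TemporalActivityModel(BaseEstimator):
    """Temporal fitness model with ML-estimated node activities.

    scikit-learn style estimator: ``fit`` takes an :class:`AggregateCounts`
    or :class:`SnapshotSequence` and estimates one activity per node.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the max KKT residual of the score H.
    max_iter : int
        Newton iteration cap.
    eps : float
        Lower clip for activities (open lower boundary of (0, 1]).
    init_mode : str
        ``"configuration"`` starts from the configuration-model formula.

    Attributes
    ----------
    activities_ : dict
        Node -> estimated activity a*_i.
    result_ : ActivityVector
        Full result with diagnostics.
    converged_ : bool
    residual_norm_ : float
    n_iter_ : int
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500,
                 eps: float = 1e-12, init_mode: str = "configuration"):
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps
        self.init_mode = init_mode

    def _config(self) -> EstimationConfig:
        return EstimationConfig(tol=self.tol, max_iter=self.max_iter,
                                eps=self.eps, init_mode=self.init_mode)

    def fit(self, X, y=None):
        counts = _as_counts(X)
        result = estimate_activities(counts, config=self._config())
        self.result_ = result
        self.activities_ = dict(result.activities)
        self.converged_ = result.converged
        self.residual_norm_ = result.residual_norm
        self.n_iter_ = result.iterations
        self.tau_ = counts.tau
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of counts X under the fitted activities."""
        return log_likelihood(self.result_, _as_counts(X))

    def interaction_probability(self, i, j) -> float:
        """Null per-interval interaction probability u = a*_i a*_j."""
        return float(self.activities_[i] * self.activities_[j])
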