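"""Three-state HMM for site-level expression change calling.

States are 0 = decreased, 1 = stable, 2 = increased expression. At each
genomic site the observable is the natural-log fold change L = ln(x/mu)
between a sample strain's normalized coverage x and the reference-replicate
mean mu. Under no expression change L is taken as normal with mean 0 and
variance s^2 = 2*sigma^2/mu^2 (delta-method approximation from the
reference mean/variance). The up and down states place the true mean at the
upper/lower critical value +/- c = z_{1-alpha/2} * s of that null
distribution.

Emissions are tail-probability *scores*, not densities: at each site
  stable = 2 * (1 - Phi(|L| / s))        two-sided p-value under no change
  up     = Phi((L - c) / s)              mass below L under the up state
  down   = 1 - Phi((L + c) / s)          mass above L under the down state
so the up score is nondecreasing and the down score nonincreasing in L.
Scores are used unnormalized; only within-site relative magnitude matters.

Sites where the reference is essentially silent (mu < 0.5 normalized reads)
bypass the fold-change model: sample coverage >= 5 reads is assigned up
probability 0.95, otherwise stable probability 0.95, with the residual mass
split equally between the other two states.

Decoding is posterior (forward-backward) rather than Viterbi: the argmax of
per-site posteriors maximizes the expected number of correctly called
sites, which is the right loss for site-specific differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # fast vectorized standard normal CDF
from scipy.stats import norm

from .coverage_io import ReferenceSummary

__all__ = [
    "DOWN",
    "STABLE",
    "UP",
    "HmmParams",
    "EmissionParams",
    "delta_lfc_sd",
    "emission_probs",
    "forward_backward",
    "decode_states",
    "baum_welch_transitions",
    "StateTrack",
]

DOWN, STABLE, UP = 0, 1, 2

_DEFAULT_PI0 = np.array([0.05, 0.9, 0.05])
_DEFAULT_T = np.array(
    [
        [0.8, 0.1, 0.1],
        [0.1, 0.8, 0.1],
        [0.1, 0.1, 0.8],
    ]
)


class LowCoverageSite(ValueError):
    """Reference mean below threshold: the delta-method s is not usable."""


@dataclass
class HmmParams:
    """Initial distribution and transition matrix over (down, stable, up)."""

    pi0: np.ndarray = field(default_factory=lambda: _DEFAULT_PI0.copy())
    T: np.ndarray = field(default_factory=lambda: _DEFAULT_T.copy())

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.pi0.shape != (3,) or self.T.shape != (3, 3):
            raise ValueError("expected pi0 of length 3 and 3x3 T")
        if not np.isclose(self.pi0.sum(), 1.0):
            raise ValueError("pi0 must sum to 1")
        if not np.allclose(self.T.sum(axis=1), 1.0):
            raise ValueError("rows of T must sum to 1")
        if (self.pi0 < 0).any() or (self.T < 0).any():
            raise ValueError("probabilities must be non-negative")


@dataclass
class EmissionParams:
    """Tunables of the per-site emission model.

    alpha is the two-sided significance level defining the critical shift
    c = z_{1-alpha/2} * s. ``epsilon`` replaces zero sample coverage inside
    the log (half a normalized read, symmetric with the low-coverage
    threshold). ``sigma2_floor`` keeps s finite on constant reference
    tracks. ``orientation`` selects the monotone emission parameterization
    ("monotone", default) or the literal symmetric-tail reading
    ("literal": up = 1 - Phi((L - c)/s)) retained for comparison.
    """

    alpha: float = 0.05
    low_mu_threshold: float = 0.5
    low_mu_sample_min: float = 5.0
    low_mu_prob: float = 0.95
    epsilon: float = 0.5
    sigma2_floor: float = 1e-6
    orientation: str = "monotone"

    @property
    def z(self) -> float:
        return float(norm.ppf(1 - self.alpha / 2))


def delta_lfc_sd(mu, sigma2, params: EmissionParams | None = None):
    """Delta-method standard deviation of the log fold change.

    var(ln(x/mu)) ~= 2*sigma^2 / mu^2, treating sample and reference as
    exchangeable under no change. Raises :class:`LowCoverageSite` for
    scalar mu below the low-coverage threshold, where the approximation
    breaks down and the caller must use the silent-site rule instead.
    """
    params = params or EmissionParams()
    mu_arr = np.asarray(mu, dtype=float)
    sigma2_arr = np.maximum(np.asarray(sigma2, dtype=float), params.sigma2_floor)
    if mu_arr.ndim == 0:
        if float(mu_arr) < params.low_mu_threshold:
            raise LowCoverageSite(
                f"mu={float(mu_arr)} below threshold {params.low_mu_threshold}"
            )
        return float(np.sqrt(2.0 * sigma2_arr / mu_arr**2))
    with np.errstate(divide="ignore"):
        return np.sqrt(2.0 * sigma2_arr / mu_arr**2)


def emission_probs(
    sample_cov,
    ref: ReferenceSummary,
    params: EmissionParams | None = None,
):
    """Per-site emission score triples (down, stable, up).

    ``sample_cov`` is the sample strain's normalized coverage, aligned
    site-for-site with ``ref``. Returns an (n, 3) array. Scalars accepted.
    """
    params = params or EmissionParams()
    x = np.atleast_1d(np.asarray(sample_cov, dtype=float))
    mu = np.atleast_1d(ref.mu)
    sigma2 = np.atleast_1d(ref.sigma2)
    if x.shape != mu.shape:
        raise ValueError("sample coverage and reference summary misaligned")

    e = np.empty((len(x), 3))
    low = mu < params.low_mu_threshold
    rest = (1.0 - params.low_mu_prob) / 2.0
    up_low = low & (x >= params.low_mu_sample_min)
    e[up_low] = (rest, rest, params.low_mu_prob)
    e[low & ~(x >= params.low_mu_sample_min)] = (rest, params.low_mu_prob, rest)

    hi = ~low
    if hi.any():
        s = delta_lfc_sd(mu[hi], sigma2[hi], params)
        c = params.z * s
        L = np.log(np.maximum(x[hi], params.epsilon) / mu[hi])
        stable = 2.0 * (1.0 - ndtr(np.abs(L) / s))
        if params.orientation == "literal":
            up = 1.0 - ndtr((L - c) / s)
            down = ndtr((L + c) / s)
        else:
            up = ndtr((L - c) / s)
            down = 1.0 - ndtr((L + c) / s)
        e[hi, DOWN] = down
        e[hi, STABLE] = stable
        e[hi, UP] = up
    if np.isscalar(sample_cov) or np.asarray(sample_cov).ndim == 0:
        return e[0]
    return e


@dataclass
class StateTrack:
    """Decoded posteriors: site coordinates, n x 3 posterior, argmax state."""

    positions: np.ndarray
    posterior: np.ndarray
    state: np.ndarray

    @property
    def log_likelihood(self) -> float:
        return self._loglik

    _loglik: float = 0.0


def _check_emissions(emissions: np.ndarray) -> np.ndarray:
    e = np.asarray(emissions, dtype=float)
    if e.ndim != 2 or e.shape[1] != 3 or e.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (n, 3) array")
    if not np.isfinite(e).all():
        raise ValueError("non-finite emission score")
    zero_rows = np.flatnonzero(e.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"all-zero emission row at site index {int(zero_rows[0])}: "
            "posterior undefined"
        )
    return e


def _forward_backward_scaled(e: np.ndarray, pi0: np.ndarray, T: np.ndarray):
    """Scaled forward-backward. Returns (gamma, xi_sum, loglik).

    Per-site scaling keeps chains of 1e7+ sites in the dynamic range;
    the log-likelihood is the sum of log scale factors.
    """
    n = e.shape[0]
    alpha = np.empty_like(e)
    scale = np.empty(n)
    a = pi0 * e[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise ValueError("zero forward mass at site index 0")
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * e[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise ValueError(f"zero forward mass at site index {t}")
        alpha[t] = a / scale[t]

    beta = np.empty_like(e)
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    if n > 1:
        b = e[1:] * beta[1:] / scale[1:, None]
        xi_sum = T * (alpha[:-1].T @ b)
    else:
        xi_sum = np.zeros((3, 3))
    return gamma, xi_sum, float(np.log(scale).sum())


def forward_backward(
    emissions,
    params: HmmParams | None = None,
    positions=None,
) -> StateTrack:
    """Posterior state probabilities by the forward-backward algorithm.

    ``emissions`` is an (n, 3) array of per-site emission scores. Posterior
    rows sum to 1; decoding (argmax, ties to stable) is included.
    """
    params = params or HmmParams()
    e = _check_emissions(emissions)
    gamma, _, loglik = _forward_backward_scaled(e, params.pi0, params.T)
    if positions is None:
        positions = np.arange(1, len(e) + 1, dtype=np.int64)
    track = StateTrack(
        positions=np.asarray(positions, dtype=np.int64),
        posterior=gamma,
        state=decode_states(gamma),
    )
    track._loglik = loglik
    return track


def decode_states(posterior) -> np.ndarray:
    """Argmax decoding of posteriors; exact ties resolve to stable.

    Accepts an (n, 3) array or a StateTrack.
    """
    if isinstance(posterior, StateTrack):
        posterior = posterior.posterior
    p = np.asarray(posterior, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    state = p.argmax(axis=1)
    # conservative tie-break: any row where stable attains the max is stable
    state[p[:, STABLE] >= p.max(axis=1)] = STABLE
    return state.astype(np.int8)


def baum_welch_transitions(
    emissions,
    start: HmmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[HmmParams, list[float]]:
    """Re-estimate pi0 and T by EM with the emission scores held fixed.

    Returns the re-estimated parameters and the per-iteration
    log-likelihood trace (nondecreasing, an EM guarantee). A single-site
    chain carries no transition evidence and returns ``start`` unchanged.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    start = start or HmmParams()
    e = _check_emissions(emissions)
    if e.shape[0] < 2:
        return HmmParams(start.pi0.copy(), start.T.copy()), []

    pi0, T = start.pi0.copy(), start.T.copy()
    trace: list[float] = []
    for _ in range(max_iter):
        gamma, xi_sum, loglik = _forward_backward_scaled(e, pi0, T)
        trace.append(loglik)
        pi0 = gamma[0] / gamma[0].sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        T = np.where(denom > 0, xi_sum / np.where(denom > 0, denom, 1.0), T)
        T /= T.sum(axis=1, keepdims=True)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return HmmParams(pi0, T), trace
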