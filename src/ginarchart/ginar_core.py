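"""Core definitions of the geometric INAR(1) count process.

The GINAR(1) process is a stationary integer-valued autoregression

    X_t = rho ∘ X_{t-1} + B_t * G_t,

where ``rho ∘ X`` is binomial thinning (the sum of X independent
Bernoulli(rho) variables), B_t ~ Bernoulli(1 - rho) and G_t ~ geometric(p)
are independent, so the innovation eps_t = B_t * G_t has mass
p(1-rho) + rho at zero and (1-rho)(1-p)^j p at j >= 1.  Started from a
geometric(p) state, the process is stationary with geometric(p) marginal
(support {0, 1, 2, ...}, mean (1-p)/p) and autocorrelation rho**k at lag k.

The process is a discrete-time Markov chain; this module builds its exact
transition probabilities and (truncated) transition matrix, simulates
sample paths, and provides moment-based parameter estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GINARParams",
    "TransitionMatrix",
    "CountSeries",
    "innovation_pmf",
    "transition_prob",
    "build_tpm",
    "default_truncation",
    "theoretical_acf",
    "binomial_thinning",
    "simulate",
    "estimate_params",
]

#: marginal-tail threshold used by the default truncation rule
_TAIL_TOL = 1e-12


@dataclass(frozen=True)
class GINARParams:
    """Parameter pair (p, rho) of a GINAR(1) process.

    Parameters
    ----------
    p : float
        Geometric marginal parameter, strictly inside (0, 1).  The
        stationary marginal is P(X = j) = (1-p)^j p on {0, 1, ...} with
        mean (1-p)/p, so smaller p means larger counts.
    rho : float
        Thinning parameter in [0, 1); equals the lag-1 autocorrelation.
        rho = 0 is admitted as the iid limit; rho = 1 (a non-ergodic
        chain) is rejected.
    """

    p: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")

    def marginal_mean(self) -> float:
        """Mean (1-p)/p of the stationary geometric(p) marginal."""
        return (1.0 - self.p) / self.p

    def marginal_var(self) -> float:
        """Variance (1-p)/p**2 of the stationary marginal."""
        return (1.0 - self.p) / self.p**2

    def marginal_pmf(self, j) -> np.ndarray | float:
        """Stationary marginal mass (1-p)^j p at j (vectorised)."""
        j = np.asarray(j)
        if np.any(j < 0):
            raise ValueError("state index must be non-negative")
        return (1.0 - self.p) ** j * self.p

    def kalmykov_domain(self) -> bool:
        """Whether rho/(rho+1) < p, i.e. marginal mean < 1/rho.

        This is the admissibility condition under which transition
        matrices of two processes sharing this rho can be compared in
        the Kalmykov (usual stochastic) order.
        """
        return self.rho / (self.rho + 1.0) < self.p


@dataclass(frozen=True)
class TransitionMatrix:
    """Truncated transition probability matrix of a GINAR(1) chain.

    ``entries[i, j]`` is the exact transition probability from state i
    to state j for 0 <= i, j <= n; rows are *not* renormalised.  The
    mass each row places beyond state n is kept in ``tail_mass`` so the
    truncation error stays auditable.
    """

    params: GINARParams
    n: int
    entries: np.ndarray = field(repr=False)
    tail_mass: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ent = np.asarray(self.entries, dtype=float)
        if ent.shape != (self.n + 1, self.n + 1):
            raise ValueError("entries must be (n+1) x (n+1)")

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.n + 1)


@dataclass(frozen=True)
class CountSeries:
    """A univariate non-negative integer series, optionally with provenance."""

    values: np.ndarray
    params: GINARParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a non-empty 1-d sequence")
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "values", vals.astype(np.int64))

    def __len__(self) -> int:
        return self.values.size


def innovation_pmf(j, params: GINARParams):
    """Innovation probability mass P(eps = j) of the GINAR(1) process.

    The innovation is the product of a Bernoulli(1-rho) and a
    geometric(p) variable:  mass p(1-rho) + rho at j = 0 and
    (1-rho)(1-p)^j p at j >= 1.  Vectorised over ``j``.
    """
    j_arr = np.asarray(j)
    if np.any(j_arr < 0):
        raise ValueError("innovation support is {0, 1, 2, ...}")
    p, rho = params.p, params.rho
    out = (1.0 - rho) * (1.0 - p) ** j_arr * p
    out = np.where(j_arr == 0, p * (1.0 - rho) + rho, out)
    return float(out) if np.isscalar(j) else out


def _log_binom(n, k):
    """log of the binomial coefficient C(n, k), via log-gamma."""
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def transition_prob(i: int, j: int, params: GINARParams) -> float:
    """Exact one-step transition probability P(X_t = j | X_{t-1} = i).

    Closed form: the thinned survivors contribute a binomial(i, rho)
    count m <= min(i, j) and the innovation supplies the remaining
    j - m, giving

        sum_{m=0}^{min(i,j)} C(i,m) rho^m (1-rho)^(i-m) (1-rho)(1-p)^(j-m) p
        + C(i,j) rho^j (1-rho)^(i-j) rho   [only when i >= j],

    the second term being the j-survivor / zero-innovation-through-B
    path that the truncated geometric factor of the first term omits.
    Binomial coefficients are evaluated in log space so states up to a
    few hundred are overflow-safe.
    """
    if i < 0 or j < 0:
        raise ValueError("states must be non-negative")
    p, rho = params.p, params.rho
    if rho == 0.0:
        # iid limit: next state is pure innovation = geometric(p)
        return float((1.0 - p) ** j * p)
    m = np.arange(min(i, j) + 1)
    log_terms = (
        _log_binom(i, m)
        + m * math.log(rho)
        + (i - m) * math.log1p(-rho)
        + math.log1p(-rho)
        + (j - m) * math.log1p(-p)
        + math.log(p)
    )
    total = float(np.exp(log_terms).sum())
    if i >= j:
        total += math.exp(
            _log_binom(i, j) + j * math.log(rho) + (i - j) * math.log1p(-rho)
        ) * rho
    return total


def default_truncation(params: GINARParams, tol: float = _TAIL_TOL) -> int:
    """Smallest n with marginal tail (1-p)^(n+1) below ``tol``."""
    return max(0, math.ceil(math.log(tol) / math.log1p(-params.p)) - 1)


def build_tpm(params: GINARParams, n: int | None = None) -> TransitionMatrix:
    """Build the exact transition matrix on states {0, ..., n}.

    ``n`` defaults to the marginal-tail truncation rule.  Entries are
    the exact transition probabilities (never renormalised); the
    per-row deficit 1 - sum_j entries[i, j] is returned as tail mass.
    """
    if n is None:
        n = default_truncation(params)
    if n < 0:
        raise ValueError("truncation order must be non-negative")
    ent = np.empty((n + 1, n + 1))
    for i in range(n + 1):
        for j in range(n + 1):
            ent[i, j] = transition_prob(i, j, params)
    tail = 1.0 - ent.sum(axis=1)
    # rounding can leave a tiny negative deficit; clamp at exactly 0
    tail[np.abs(tail) < 1e-14] = np.maximum(tail[np.abs(tail) < 1e-14], 0.0)
    return TransitionMatrix(params=params, n=n, entries=ent, tail_mass=tail)


def theoretical_acf(k: int, params: GINARParams) -> float:
    """Autocorrelation rho**k of the stationary process at lag k."""
    if k < 0:
        raise ValueError("lag must be non-negative")
    return float(params.rho**k)


def binomial_thinning(x: int, rho: float, rng: np.random.Generator) -> int:
    """One draw of rho ∘ x: a binomial(x, rho) count of survivors.

    By convention 0 ∘ x = 0 and 1 ∘ x = x.
    """
    if x < 0:
        raise ValueError("x must be a non-negative integer")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    if x == 0:
        return 0
    if rho == 1.0:
        return int(x)
    return int(rng.binomial(x, rho))


def _draw_geometric0(rng: np.random.Generator, p: float, size=None):
    """Geometric(p) on {0, 1, ...} (numpy's geometric counts trials)."""
    return rng.geometric(p, size=size) - 1


def simulate(
    params: GINARParams,
    T: int,
    init: int | str = "stationary",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CountSeries:
    """Simulate a GINAR(1) path X_1, ..., X_T.

    The initial state X_0 is drawn from the stationary geometric(p)
    marginal when ``init='stationary'``, or fixed at the given integer.
    Each step thins the previous count and adds an innovation drawn as
    the product of a Bernoulli(1-rho) and a geometric(p) variable —
    i.e. the defining recursion itself, not an inverse-CDF shortcut.
    """
    if T < 1:
        raise ValueError("series length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p, rho = params.p, params.rho
    if init == "stationary":
        x = int(_draw_geometric0(rng, p))
    else:
        x = int(init)
        if x < 0:
            raise ValueError("initial state must be non-negative")
    # pre-draw the innovation components; thinning stays sequential
    b = rng.random(T) < (1.0 - rho)
    g = _draw_geometric0(rng, p, size=T)
    eps = np.where(b, g, 0)
    out = np.empty(T, dtype=np.int64)
    for t in range(T):
        x = binomial_thinning(x, rho, rng) + int(eps[t])
        out[t] = x
    return CountSeries(values=out, params=params, seed=seed)


def estimate_params(series: CountSeries | np.ndarray) -> GINARParams:
    """Moment estimates (p_hat, rho_hat) from an observed count series.

    p_hat = 1 / (1 + sample mean) inverts the marginal mean (1-p)/p;
    rho_hat is the lag-1 sample autocorrelation clipped to [0, 1).
    Deliberately minimal — no likelihood fitting.
    """
    values = series.values if isinstance(series, CountSeries) else np.asarray(series)
    if values.size < 10:
        raise ValueError("need at least 10 observations")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("degenerate series: sample mean must be positive")
    var = values.var()
    if var == 0:
        raise ValueError("degenerate series: constant values, rho is unidentified")
    x0 = values[:-1] - mean
    x1 = values[1:] - mean
    rho_hat = float(np.dot(x0, x1) / (values.size * var))
    rho_hat = min(max(rho_hat, 0.0), np.nextafter(1.0, 0.0))
    return GINARParams(p=1.0 / (1.0 + float(mean)), rho=rho_hat)
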