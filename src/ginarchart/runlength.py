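"""Exact run-length analysis of the upper one-sided geometric chart.

The chart monitors a GINAR(1) count process {X_t} and signals at the
first t with X_t > U.  Because the process is Markov on {0, 1, ...},
the run length RL_u = min{t >= 1 : X_t > U | X_0 = u} is a discrete
phase-type variable governed by the substochastic block

    Q = [ p_ij ]  for  i, j in {0, ..., U}

of the transition matrix (the Markov-chain / Brook–Evans method):

    P(RL_u > m) = e_u' Q^m 1,      E[RL_u] = e_u' (I - Q)^{-1} 1.

Two initialisations are supported: a fixed head-start state u in
{0, ..., U}, and the *overall* run length whose initial state is the
first monitored observation X_1 ~ geometric(p) itself — so a signal is
already possible at t = 1 with probability P(X_1 > U), and

    P(RL > m) = pi' Q^{m-1} 1  (m >= 1),   E[RL] = 1 + pi' (I - Q)^{-1} 1,

with the defective vector pi_u = (1-p)^u p, u = 0..U.

The pmf tail is geometric-like with ratio xi, the Perron root of Q, so
the hazard rate of every initialisation converges to 1 - xi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ginar_core import GINARParams, transition_prob, _draw_geometric0

__all__ = [
    "ChartSpec",
    "RunLengthDistribution",
    "RunLengthSummary",
    "build_substochastic",
    "rl_distribution",
    "arl",
    "overall_arl",
    "perron_root",
    "rl_summary",
    "monte_carlo_run_lengths",
]

OVERALL = "overall"


@dataclass(frozen=True)
class ChartSpec:
    """Upper control limit U and initial-state policy of the chart.

    ``init`` is either a fixed state u in {0, ..., U} (u = U is the
    classical head start) or the token ``"overall"`` for a random
    initial state distributed as the first monitored count.
    """

    U: int
    init: int | str = 0

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("upper control limit must be a non-negative integer")
        if self.init != OVERALL:
            u = int(self.init)
            if not (0 <= u <= self.U):
                raise ValueError(f"initial state must lie in 0..{self.U}")
            object.__setattr__(self, "init", u)

    @property
    def is_overall(self) -> bool:
        return self.init == OVERALL


def build_substochastic(params: GINARParams, U: int) -> np.ndarray:
    """The (U+1) x (U+1) in-control block Q of the transition matrix.

    Q is a finite block of the infinite chain, so no truncation error
    is involved; every row sum is < 1 because every state can jump
    beyond U in one step.
    """
    if U < 0:
        raise ValueError("upper control limit must be non-negative")
    q = np.empty((U + 1, U + 1))
    for i in range(U + 1):
        for j in range(U + 1):
            q[i, j] = transition_prob(i, j, params)
    return q


def _initial_vector(params: GINARParams, chart: ChartSpec) -> np.ndarray:
    """Row vector over states 0..U selecting the chart's start.

    For the overall chart this is the defective geometric vector
    pi_u = (1-p)^u p; its deficit is the t = 1 signal probability.
    """
    if chart.is_overall:
        u = np.arange(chart.U + 1)
        return (1.0 - params.p) ** u * params.p
    e = np.zeros(chart.U + 1)
    e[chart.init] = 1.0
    return e


@dataclass(frozen=True)
class RunLengthDistribution:
    """Exact pmf / survival / hazard of the run length up to a horizon M.

    Arrays are aligned so that ``pmf[m-1] = P(RL = m)`` and
    ``hazard[m-1] = P(RL = m) / P(RL >= m)`` for m = 1..M, while
    ``survival[m] = P(RL > m)`` for m = 0..M (``survival[0] = 1``).
    ``xi`` is the Perron root of Q: the pmf tail decays like xi**m and
    the hazard tends to 1 - xi.
    """

    chart: ChartSpec
    params: GINARParams
    Q: np.ndarray = field(repr=False)
    pmf: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    hazard: np.ndarray = field(repr=False)
    xi: float = 0.0

    @property
    def horizon(self) -> int:
        return self.pmf.size

    @property
    def limiting_hazard(self) -> float:
        return 1.0 - self.xi

    def support(self) -> np.ndarray:
        """Grid m = 1..M on which ``pmf`` and ``hazard`` live."""
        return np.arange(1, self.horizon + 1)


def rl_distribution(
    params: GINARParams,
    chart: ChartSpec,
    eps: float = 1e-12,
    max_horizon: int = 10**6,
) -> RunLengthDistribution:
    """Exact run-length distribution out to the first m with P(RL > m) < eps.

    Survival probabilities are obtained by propagating the initial row
    vector through Q one step at a time; no matrix powers are formed.
    """
    if eps <= 0:
        raise ValueError("tail cutoff eps must be positive")
    q = build_substochastic(params, chart.U)
    one = np.ones(chart.U + 1)
    w = _initial_vector(params, chart)
    if chart.is_overall:
        # P(RL > 1) = pi' 1; the deficit 1 - pi'1 already signalled at t=1
        surv = [1.0, float(w @ one)]
    else:
        surv = [1.0, float(w @ q @ one)]
        w = w @ q
    while surv[-1] >= eps and len(surv) <= max_horizon:
        w = w @ q
        surv.append(float(w @ one))
    survival = np.array(surv)
    pmf = survival[:-1] - survival[1:]
    # P(RL >= m) = survival[m-1]
    hazard = pmf / survival[:-1]
    return RunLengthDistribution(
        chart=chart,
        params=params,
        Q=q,
        pmf=pmf,
        survival=survival,
        hazard=hazard,
        xi=perron_root(q),
    )


def arl(params: GINARParams, chart: ChartSpec) -> float:
    """Average run length, from the linear system (I - Q) a = 1.

    Fixed start u returns a[u]; the overall chart returns
    1 + pi' a with the defective initial vector pi.
    """
    q = build_substochastic(params, chart.U)
    a = np.linalg.solve(np.eye(chart.U + 1) - q, np.ones(chart.U + 1))
    if chart.is_overall:
        return 1.0 + float(_initial_vector(params, chart) @ a)
    return float(a[chart.init])


def overall_arl(params: GINARParams, U: int) -> float:
    """ARL of the chart whose initial state is the random count X_1."""
    return arl(params, ChartSpec(U=U, init=OVERALL))


def perron_root(Q: np.ndarray) -> float:
    """Maximum real eigenvalue xi of a non-negative substochastic matrix.

    Cross-checks a dense eigendecomposition against power iteration on
    a strictly positive shift of Q (so convergence does not depend on
    Q itself being primitive); disagreement beyond 1e-10 raises.
    """
    q = np.asarray(Q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be square")
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    eigs = np.linalg.eigvals(q)
    real = eigs[np.abs(eigs.imag) < 1e-12].real
    if real.size == 0:
        raise np.linalg.LinAlgError("no real eigenvalue found")
    xi = float(real.max())
    # power-iteration cross-check on Q + cI (same eigenvectors, shifted roots)
    shift = 1e-3
    m = q + shift * np.eye(q.shape[0])
    v = np.ones(q.shape[0]) / np.sqrt(q.shape[0])
    lam = 0.0
    for _ in range(100_000):
        w = m @ v
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0.0:
            break
        v = w / lam_new
        if abs(lam_new - lam) < 1e-14:
            lam = lam_new
            break
        lam = lam_new
    else:
        raise np.linalg.LinAlgError("power iteration failed to converge")
    xi_power = lam - shift if lam > 0 else 0.0
    if abs(xi_power - xi) > 1e-10:
        raise np.linalg.LinAlgError(
            f"eigendecomposition ({xi}) and power iteration ({xi_power}) disagree"
        )
    return xi


@dataclass(frozen=True)
class RunLengthSummary:
    """Standard phase-type performance measures of a run length."""

    arl: float
    sdrl: float
    quantiles: dict[float, int]
    limiting_hazard: float


def rl_summary(
    dist: RunLengthDistribution, percentiles: tuple[float, ...] = (0.5,)
) -> RunLengthSummary:
    """ARL, SDRL and percentiles of an exact run-length distribution.

    Moments come from linear solves against (I - Q):  for a fixed start
    E[RL^2] = e_u' (I + Q)(I - Q)^{-2} 1, and for the overall chart
    E[RL^2] = 1 + 2 pi' (I - Q)^{-2} 1 + pi' (I - Q)^{-1} 1 (the extra
    sample at t = 1 shifts the phase-type part by one).  Percentile q is
    the smallest m with P(RL <= m) >= q.
    """
    for q in percentiles:
        if not (0.0 < q < 1.0):
            raise ValueError("percentiles must lie strictly inside (0, 1)")
    Q = dist.Q
    n = Q.shape[0]
    ident = np.eye(n)
    one = np.ones(n)
    a = np.linalg.solve(ident - Q, one)  # (I-Q)^{-1} 1
    b = np.linalg.solve(ident - Q, a)  # (I-Q)^{-2} 1
    w = _initial_vector(dist.params, dist.chart)
    if dist.chart.is_overall:
        mean = 1.0 + float(w @ a)
        second = 1.0 + 2.0 * float(w @ b) + float(w @ a)
    else:
        mean = float(w @ a)
        second = float(w @ ((ident + Q) @ b))
    var = max(second - mean**2, 0.0)
    cdf = 1.0 - dist.survival[1:]  # P(RL <= m), m = 1..M
    quants: dict[float, int] = {}
    for q in percentiles:
        idx = int(np.searchsorted(cdf, q, side="left"))
        if idx >= cdf.size:
            raise ValueError(
                f"horizon too short for percentile {q}; lower eps in rl_distribution"
            )
        quants[q] = idx + 1
    return RunLengthSummary(
        arl=mean,
        sdrl=float(np.sqrt(var)),
        quantiles=quants,
        limiting_hazard=dist.limiting_hazard,
    )


def monte_carlo_run_lengths(
    params: GINARParams,
    U: int,
    n_paths: int,
    init: int | str = 0,
    seed: int | None = None,
    max_steps: int = 10**6,
) -> np.ndarray:
    """Simulate run lengths directly from the process recursion.

    Paths evolve by binomial thinning plus Bernoulli-geometric
    innovations — independent of the closed-form transition law — and
    are vectorised across paths, so this serves as a brute-force oracle
    for the exact Markov-chain engine.  For the overall chart the first
    monitored count is the stationary draw itself and may already
    signal at t = 1; a fixed start u is a pre-period state, with
    monitoring beginning at t = 1 on the next observation.
    """
    rng = np.random.default_rng(seed)
    p, rho = params.p, params.rho
    rl = np.zeros(n_paths, dtype=np.int64)
    if init == OVERALL:
        x = _draw_geometric0(rng, p, size=n_paths)
        t = 1
        signalled = x > U
        rl[signalled] = 1
        alive = ~signalled
    else:
        x = np.full(n_paths, int(init))
        t = 0
        alive = np.ones(n_paths, dtype=bool)
    idx = np.nonzero(alive)[0]
    x = x[idx]
    while idx.size:
        t += 1
        if t > max_steps:
            raise RuntimeError("maximum simulation horizon exceeded")
        thinned = rng.binomial(x, rho) if rho > 0 else np.zeros_like(x)
        keep = rng.random(idx.size) < (1.0 - rho)
        x = thinned + np.where(keep, _draw_geometric0(rng, p, size=idx.size), 0)
        signalled = x > U
        rl[idx[signalled]] = t
        idx = idx[~signalled]
        x = x[~signalled]
    return rl
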