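"""Chart-parameter selection and performance tabulation.

* ``find_ucl`` — smallest upper control limit achieving a target
  in-control ARL (the ARL is nondecreasing in U, so a scan is exact);
* ``arl_profile`` — ARL as a function of the process parameter p at a
  fixed control limit, the detection-speed profile of the chart;
* ``verify_corollaries`` — one-shot numerical verification of the
  structural run-length properties the TP2/Kalmykov results imply:
  log-concavity (IHR) of the zero-start run length, DHR of the
  head-start run length, hazard dominance, likelihood-ratio ordering in
  the initial state, stochastic ordering in p, monotone overall ARL,
  and hazard convergence to one minus the Perron root.

The chart detects *decreases* in p (increases in the process mean): an
observation above the limit signals that p has dropped.  Increases in p
push the ARL up, so they are effectively invisible to this chart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ginar_core import GINARParams
from . import ordering
from .runlength import ChartSpec, arl, rl_distribution

__all__ = ["DesignResult", "find_ucl", "arl_profile", "verify_corollaries"]


@dataclass(frozen=True)
class DesignResult:
    """Outcome of a UCL search for a target in-control ARL."""

    U: int
    achieved_arl: float
    target_arl: float
    init: int | str


def find_ucl(
    params: GINARParams,
    target_arl: float,
    init: int | str = 0,
    max_ucl: int = 10_000,
) -> DesignResult:
    """Smallest U with ARL(params, U, init) >= target_arl.

    A fixed initial state is clipped into {0, ..., U} while U is still
    below it during the scan.  Raises if the target is unreachable
    below ``max_ucl``.
    """
    if target_arl <= 1.0:
        raise ValueError("target ARL must exceed 1")
    for U in range(max_ucl + 1):
        this_init = init if init == "overall" else min(int(init), U)
        achieved = arl(params, ChartSpec(U=U, init=this_init))
        if achieved >= target_arl:
            return DesignResult(
                U=U, achieved_arl=achieved, target_arl=target_arl, init=init
            )
    raise RuntimeError(f"target ARL {target_arl} not reachable with U <= {max_ucl}")


def arl_profile(
    params0: GINARParams,
    U: int,
    p_grid,
    init: int | str = "overall",
) -> pd.DataFrame:
    """ARL of a fixed chart across process parameters p (rho held fixed).

    Returns a table with columns ``p``, ``mean`` (the marginal mean
    (1-p)/p of the shifted process) and ``arl``.  On the admissible
    interval (rho/(rho+1), 1) the overall ARL is increasing in p, i.e.
    the chart detects stronger downward shifts in p faster.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any((p_grid <= 0) | (p_grid >= 1)):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    rows = []
    for p in p_grid:
        shifted = GINARParams(p=float(p), rho=params0.rho)
        rows.append(
            {
                "p": float(p),
                "mean": shifted.marginal_mean(),
                "arl": arl(shifted, ChartSpec(U=U, init=init)),
            }
        )
    return pd.DataFrame(rows)


def verify_corollaries(
    params: GINARParams,
    U: int,
    p_prime: float,
    horizon_eps: float = 1e-9,
    max_horizon: int = 10**5,
    grid_points: int = 10,
    tol: float = ordering.DEFAULT_TOL,
) -> dict:
    """Numerically exercise the structural run-length properties at once.

    Requires the admissibility condition rho/(rho+1) < p <= p' < 1.
    Returns a JSON-ready report; ``report['all_hold']`` aggregates the
    individual verdicts.
    """
    p, rho = params.p, params.rho
    if not params.kalmykov_domain():
        raise ValueError(
            f"admissibility requires rho/(rho+1) = {rho / (rho + 1):.6f} < p = {p}"
        )
    if not (p <= p_prime < 1.0):
        raise ValueError("need p <= p_prime < 1")

    dists = {
        u: rl_distribution(
            params, ChartSpec(U=U, init=u), eps=horizon_eps, max_horizon=max_horizon
        )
        for u in range(U + 1)
    }
    grid = min(d.horizon for d in dists.values())
    report: dict = {"params": {"p": p, "rho": rho, "U": U, "p_prime": p_prime}}

    # log-concavity (=> IHR) of the zero-start run length, and its
    # reversal (=> DHR) for the head-start run length
    report["rl0_pf2"] = ordering.is_pf2_sequence(dists[0].pmf, tol=tol).to_dict()
    f = dists[U].pmf
    rev_gaps = f[:-2] * f[2:] - f[1:-1] ** 2
    report["rlU_reverse_pf2"] = {
        "check": "reverse_pf2",
        "holds": bool(rev_gaps.min() >= -tol),
        "margin": float(rev_gaps.min()),
        "tolerance": tol,
    }
    haz0 = dists[0].hazard
    hazU = dists[U].hazard
    report["rl0_ihr"] = {
        "check": "hazard_nondecreasing",
        "holds": bool(np.all(np.diff(haz0) >= -tol)),
        "margin": float(np.diff(haz0).min()) if haz0.size > 1 else 0.0,
        "tolerance": tol,
    }
    report["rlU_dhr"] = {
        "check": "hazard_nonincreasing",
        "holds": bool(np.all(np.diff(hazU) <= tol)),
        "margin": float(-np.diff(hazU).max()) if hazU.size > 1 else 0.0,
        "tolerance": tol,
    }
    m = min(haz0.size, hazU.size)
    report["hazard_dominance"] = {
        "check": "hazard_rlU_ge_rl0",
        "holds": bool(np.all(hazU[:m] - haz0[:m] >= -tol)),
        "margin": float((hazU[:m] - haz0[:m]).min()),
        "tolerance": tol,
    }

    # likelihood-ratio ordering in the initial state: RL_{u'} <=lr RL_u
    # for u <= u', checked across every pair on the common grid
    lr_ok = True
    lr_margin = np.inf
    for u in range(U + 1):
        for u_hi in range(u, U + 1):
            rep = ordering.lr_le(dists[u_hi].pmf[:grid], dists[u].pmf[:grid], tol=tol)
            lr_ok &= rep.holds
            lr_margin = min(lr_margin, rep.margin)
    report["lr_order_in_initial_state"] = {
        "check": "lr_le_all_state_pairs",
        "holds": bool(lr_ok),
        "margin": float(lr_margin),
        "tolerance": tol,
    }

    # stochastic ordering in p: survival of RL_u(p) below survival of
    # RL_{u'}(p') for u' <= u, p <= p'
    shifted = GINARParams(p=p_prime, rho=rho)
    shifted_dists = {
        u: rl_distribution(
            shifted, ChartSpec(U=U, init=u), eps=horizon_eps, max_horizon=max_horizon
        )
        for u in range(U + 1)
    }
    st_ok = True
    st_margin = np.inf
    for u_hi in range(U + 1):
        d_small = dists[u_hi]
        for u_lo in range(u_hi + 1):
            d_large = shifted_dists[u_lo]
            g = min(d_small.horizon, d_large.horizon)
            gaps = d_large.survival[:g] - d_small.survival[:g]
            st_ok &= bool(gaps.min() >= -tol)
            st_margin = min(st_margin, float(gaps.min()))
    report["st_order_in_p"] = {
        "check": "survival_dominance_in_p_and_u",
        "holds": bool(st_ok),
        "margin": float(st_margin),
        "tolerance": tol,
    }

    # monotone overall ARL on a grid spanning (rho/(rho+1), p]
    left = rho / (rho + 1.0)
    p_grid = np.linspace(left + 1e-6 if left > 0 else 1e-6, p, grid_points)
    profile = arl_profile(params, U, p_grid, init="overall")
    diffs = np.diff(profile["arl"].to_numpy())
    report["overall_arl_increasing"] = {
        "check": "overall_arl_monotone_in_p",
        "holds": bool(np.all(diffs >= -1e-9)),
        "margin": float(diffs.min()) if diffs.size else 0.0,
        "tolerance": 1e-9,
    }

    # hazard convergence to the limiting rate 1 - xi
    lim = dists[0].limiting_hazard
    conv = max(abs(haz0[-1] - lim), abs(hazU[-1] - lim))
    report["hazard_convergence"] = {
        "check": "hazard_to_one_minus_xi",
        "holds": bool(conv < 1e-6),
        "margin": float(1e-6 - conv),
        "tolerance": 1e-6,
        "limiting_hazard": lim,
    }

    report["all_hold"] = all(
        v["holds"] for k, v in report.items() if isinstance(v, dict) and "holds" in v
    )
    return report
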