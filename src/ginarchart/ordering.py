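"""Numerical verifiers for total positivity and stochastic orders.

Each check returns an :class:`OrderReport` carrying a boolean verdict,
the minimal signed quantity whose non-negativity defines the order (a
2x2 minor, a log-concavity gap, a cross-product or a tail-sum gap), and
— when the property fails — the indices of the first violation, so a
failed check can be replayed by hand.

Checks provided:

* ``is_tp2`` — total positivity of order 2 of a non-negative matrix
  (all 2x2 minors non-negative);
* ``is_pf2_sequence`` — log-concavity f(x+1)^2 >= f(x) f(x+2) of a
  probability sequence (Polya frequency of order 2);
* ``lr_le`` — likelihood-ratio order f <=lr g of two pmfs on a common
  grid, via the division-free cross-product criterion;
* ``st_le`` — usual stochastic order via survival-function dominance;
* ``kalmykov_le`` — the Kalmykov order between two transition matrices:
  row i of the smaller matrix is stochastically below row m of the
  larger one whenever i <= m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ginar_core import TransitionMatrix

__all__ = ["OrderReport", "is_tp2", "is_pf2_sequence", "lr_le", "st_le", "kalmykov_le"]

#: default slack on quantities built from probabilities; the theory
#: guarantees exact non-negativity, so only rounding can dip below zero
DEFAULT_TOL = 1e-12


@dataclass(frozen=True)
class OrderReport:
    """Verdict of an ordering check with its worst margin and witness."""

    check: str
    holds: bool
    margin: float
    tolerance: float
    witness: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        assert self.holds == (self.margin >= -self.tolerance)
        assert (self.witness is not None) == (not self.holds)

    def to_dict(self) -> dict:
        return {
            "check": self.check,
            "holds": bool(self.holds),
            "margin": float(self.margin),
            "witness": list(self.witness) if self.witness is not None else None,
            "tolerance": float(self.tolerance),
        }


def _report(check: str, margin: float, witness, tol: float) -> OrderReport:
    holds = margin >= -tol
    return OrderReport(
        check=check,
        holds=holds,
        margin=float(margin),
        tolerance=tol,
        witness=None if holds else tuple(int(w) for w in witness),
    )


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, TransitionMatrix):
        m = m.entries
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a rectangular matrix")
    return arr


def is_tp2(matrix, tol: float = DEFAULT_TOL, method: str = "exhaustive") -> OrderReport:
    """Check that every 2x2 minor of a non-negative matrix is >= -tol.

    ``method='exhaustive'`` scans all row pairs i < k and column pairs
    j < l.  ``method='adjacent'`` checks only consecutive rows/columns,
    which is sufficient for strictly positive matrices but not in the
    presence of zero entries; the exhaustive scan is the reference.
    """
    a = _as_matrix(matrix)
    if np.any(a < 0):
        raise ValueError("matrix entries must be non-negative")
    nr, nc = a.shape
    if nr < 2 or nc < 2:
        return _report("tp2", 0.0, None, tol)

    if method == "adjacent":
        minors = a[:-1, :-1] * a[1:, 1:] - a[:-1, 1:] * a[1:, :-1]
        idx = np.unravel_index(np.argmin(minors), minors.shape)
        i, j = idx
        return _report("tp2", minors[idx], (i, i + 1, j, j + 1), tol)
    if method != "exhaustive":
        raise ValueError(f"unknown method {method!r}")

    ri, rk = np.triu_indices(nr, k=1)
    cj, cl = np.triu_indices(nc, k=1)
    # minors[(i,k) pair, (j,l) pair] = a[i,j] a[k,l] - a[i,l] a[k,j]
    minors = (
        a[ri[:, None], cj[None, :]] * a[rk[:, None], cl[None, :]]
        - a[ri[:, None], cl[None, :]] * a[rk[:, None], cj[None, :]]
    )
    flat = np.argmin(minors)
    rpair, cpair = np.unravel_index(flat, minors.shape)
    witness = (ri[rpair], rk[rpair], cj[cpair], cl[cpair])
    return _report("tp2", minors[rpair, cpair], witness, tol)


def is_pf2_sequence(pmf, tol: float = DEFAULT_TOL) -> OrderReport:
    """Check log-concavity f(x+1)^2 >= f(x) f(x+2) of a sequence.

    A pmf in PF2 has an increasing hazard rate; the geometric pmf is
    the equality case (every defining expression exactly zero).
    """
    f = np.asarray(pmf, dtype=float)
    if np.any(f < 0):
        raise ValueError("sequence entries must be non-negative")
    if f.size < 3:
        return _report("pf2", 0.0, None, tol)
    gaps = f[1:-1] ** 2 - f[:-2] * f[2:]
    x = int(np.argmin(gaps))
    return _report("pf2", gaps[x], (x,), tol)


def _min_cross_product(f: np.ndarray, g: np.ndarray, block: int = 1024):
    """min over x < y of f[x] g[y] - g[x] f[y], with its arg, blockwise.

    Blocked so that long grids (run-length pmfs have thousands of
    support points) never materialise the full n x n outer product.
    """
    n = f.size
    best = np.inf
    best_idx = (0, 1)
    for x0 in range(0, n - 1, block):
        x1 = min(x0 + block, n - 1)
        xs = np.arange(x0, x1)
        # D[x - x0, y] for y > x, masked below the diagonal
        d = f[xs, None] * g[None, :] - g[xs, None] * f[None, :]
        mask = np.arange(n)[None, :] <= xs[:, None]
        d[mask] = np.inf
        k = np.argmin(d)
        bx, by = np.unravel_index(k, d.shape)
        if d[bx, by] < best:
            best = d[bx, by]
            best_idx = (int(xs[bx]), int(by))
    return best, best_idx


def lr_le(f, g, tol: float = DEFAULT_TOL) -> OrderReport:
    """Check the likelihood-ratio order f <=lr g on a common grid.

    Uses the cross-product criterion f(x) g(y) >= f(y) g(x) for all
    x < y (equivalently g/f nondecreasing where defined); avoiding the
    ratio means zero-probability cells need no special-casing.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError("f and g must be 1-d arrays on a common grid")
    if np.any(f < 0) or np.any(g < 0):
        raise ValueError("pmf entries must be non-negative")
    if f.size < 2:
        return _report("lr_le", 0.0, None, tol)
    margin, (x, y) = _min_cross_product(f, g)
    return _report("lr_le", margin, (x, y), tol)


def st_le(f, g, tol: float = DEFAULT_TOL) -> OrderReport:
    """Check the usual stochastic order f <=st g on a common grid.

    Holds when the survival function of g dominates that of f
    pointwise: sum_{y>=x} f(y) <= sum_{y>=x} g(y) + tol for every x.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError("f and g must be 1-d arrays on a common grid")
    surv_f = np.cumsum(f[::-1])[::-1]
    surv_g = np.cumsum(g[::-1])[::-1]
    gaps = surv_g - surv_f
    x = int(np.argmin(gaps))
    return _report("st_le", gaps[x], (x,), tol)


def _tail_sums(matrix, mode: str) -> np.ndarray:
    """tails[i, l] = sum_{j >= l} of row i.

    ``mode='window'`` sums the stored columns l..n literally.
    ``mode='complement'`` uses 1 - sum_{j < l}, which for a truncated
    row of a genuinely stochastic chain is the *exact* infinite tail
    sum (the mass beyond the truncation belongs to the tail); without
    it, tail mass leaking past the truncation edge shows up as spurious
    violations of order 1e-10 at low levels l.
    """
    a = _as_matrix(matrix)
    if mode == "window":
        return np.cumsum(a[:, ::-1], axis=1)[:, ::-1]
    if mode == "complement":
        prefix = np.cumsum(a, axis=1)[:, :-1]
        return 1.0 - np.hstack([np.zeros((a.shape[0], 1)), prefix])
    raise ValueError(f"unknown tail mode {mode!r}")


def kalmykov_le(P_small, P_large, tol: float = DEFAULT_TOL, tails: str | None = None) -> OrderReport:
    """Check the Kalmykov order P_small <=st P_large between two TPMs.

    Requires, for every pair of rows i <= m and every level l, that the
    tail sum of row i of P_small is at most the tail sum of row m of
    P_large:  sum_{j>=l} P_small[i, j] <= sum_{j>=l} P_large[m, j] + tol.
    With P_small = P_large this reduces to ordinary stochastic
    monotonicity of the matrix.

    ``tails`` selects how tail sums are formed (see ``_tail_sums``);
    by default :class:`TransitionMatrix` inputs use the exact
    complement rule and raw arrays the literal window sums.
    """
    if tails is None:
        tails = (
            "complement"
            if isinstance(P_small, TransitionMatrix)
            and isinstance(P_large, TransitionMatrix)
            else "window"
        )
    a = _as_matrix(P_small)
    b = _as_matrix(P_large)
    if a.shape != b.shape:
        raise ValueError("matrices must share dimensions and truncation")
    tails_a = _tail_sums(P_small, tails)
    tails_b = _tail_sums(P_large, tails)
    # running max over i <= m of the small-matrix tails
    run_max = np.maximum.accumulate(tails_a, axis=0)
    gaps = tails_b - run_max
    m, level = np.unravel_index(np.argmin(gaps), gaps.shape)
    # recover the offending row i <= m of P_small for the witness
    i = int(np.argmax(tails_a[: m + 1, level]))
    return _report("kalmykov_le", gaps[m, level], (i, m, level), tol)
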