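"""Bifurcation analysis of the 5-species PI3K/AKT/mTOR sub-network.

The sub-network isolates the positive feedback loop responsible for the
bistable switch seen in the full smooth-muscle-cell model: PI3K (treated
as the bifurcation parameter) activates PDK1; AKT is activated by PDK1
OR mTORC2; AKT activates mTOR, which activates mTORC2, closing the loop.
With weights, maximal activations and time constants all equal to 1 the
governing equations are

    dPDK1/dt   = f(PI3K) − PDK1
    dAKT/dt    = f(PDK1) + f(mTORC2) − f(PDK1)·f(mTORC2) − AKT
    dmTOR/dt   = f(AKT) − mTOR
    dmTORC2/dt = f(mTOR) − mTORC2

with ``f`` the normalized Hill transfer (default n = 1.4, EC50 = 0.52).

Because only AKT carries the feedback, equilibria reduce to a scalar
fixed-point problem in AKT; a dense scan with bisection refinement
enumerates every root in [0, 1], and a pseudo-arclength continuation
traces the branches.  The fold (limit point) of the lower/unstable
branch pair marks the switching threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .network import HillParams, transfer_act, transfer_inhib

__all__ = [
    "SUBNET_SPECIES",
    "EquilibriumPoint",
    "EquilibriumBranch",
    "LimitPoint",
    "subnet_rhs",
    "equilibria_at",
    "trace_branches",
    "find_limit_point",
    "limit_point",
    "lp_locus",
    "input_surface",
    "ramp_hysteresis",
]

SUBNET_SPECIES = ("PDK1", "AKT", "mTOR", "mTORC2")

DEFAULT_HILL = HillParams()

STABILITY_EPS = 1e-9
RESIDUAL_TOL = 1e-10


def subnet_rhs(state, pi3k: float, hill: HillParams = DEFAULT_HILL):
    """Right-hand side of the 4 sub-network ODEs (state order PDK1, AKT,
    mTOR, mTORC2); PI3K is the bifurcation parameter."""
    pdk1, akt, mtor, mtorc2 = state
    f = lambda x: transfer_act(x, hill)
    fp, fm = f(pdk1), f(mtorc2)
    return np.array([
        f(pi3k) - pdk1,
        fp + fm - fp * fm - akt,
        f(akt) - mtor,
        f(mtor) - mtorc2,
    ])


def _akt_residual(akt: float, pdk1: float, hill: HillParams) -> float:
    """Scalar reduction: at equilibrium mTOR = f(AKT), mTORC2 = f(mTOR),
    so AKT must satisfy AKT = OR(f(PDK1), f(f(f(AKT))))."""
    f = lambda x: transfer_act(x, hill)
    fp = f(pdk1)
    fm = f(f(f(akt)))
    return fp + fm - fp * fm - akt


def _jacobian(state, pi3k: float, hill: HillParams, h: float = 1e-7):
    J = np.empty((4, 4))
    base = subnet_rhs(state, pi3k, hill)
    for j in range(4):
        pert = np.array(state, dtype=float)
        pert[j] += h
        J[:, j] = (subnet_rhs(pert, pi3k, hill) - base) / h
    return J


@dataclass(frozen=True)
class EquilibriumPoint:
    """One equilibrium of the sub-network at a given PI3K level."""

    pi3k: float
    state: tuple[float, float, float, float]  # PDK1, AKT, mTOR, mTORC2
    stable: bool
    leading_eig: float  # largest real part of the Jacobian eigenvalues

    @property
    def akt(self) -> float:
        return self.state[1]


@dataclass
class EquilibriumBranch:
    """An ordered run of equilibria with uniform stability character."""

    branch_id: str  # "lower" | "unstable" | "upper"
    points: list[EquilibriumPoint]

    @property
    def pi3k(self) -> np.ndarray:
        return np.array([p.pi3k for p in self.points])

    @property
    def akt(self) -> np.ndarray:
        return np.array([p.akt for p in self.points])


@dataclass(frozen=True)
class LimitPoint:
    """Fold bifurcation: PI3K level where two equilibria merge."""

    pi3k: float
    state: tuple[float, float, float, float]
    bracket: float  # detection bracket width


def _classify(pi3k: float, akt: float, hill: HillParams) -> EquilibriumPoint:
    f = lambda x: transfer_act(x, hill)
    pdk1 = f(pi3k)
    mtor = f(akt)
    mtorc2 = f(mtor)
    state = (float(pdk1), float(akt), float(mtor), float(mtorc2))
    eigs = np.linalg.eigvals(_jacobian(np.array(state), pi3k, hill))
    lead = float(eigs.real.max())
    return EquilibriumPoint(pi3k=float(pi3k), state=state,
                            stable=lead < -STABILITY_EPS, leading_eig=lead)


def equilibria_at(pi3k: float, hill: HillParams = DEFAULT_HILL,
                  scan_step: float = 1e-4) -> list[EquilibriumPoint]:
    """Enumerate all equilibria in the unit box at one PI3K level.

    Uses the scalar fixed-point reduction in AKT: a dense scan at
    ``scan_step`` locates sign changes of the residual, each refined by
    bisection; exact roots on grid points are kept as-is.
    """
    if not (0.0 <= pi3k <= 1.0):
        raise ValueError("pi3k must lie in [0, 1]")
    f = lambda x: transfer_act(x, hill)
    pdk1 = float(f(pi3k))
    grid = np.arange(0.0, 1.0 + scan_step / 2, scan_step)
    res = np.array([_akt_residual(a, pdk1, hill) for a in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            roots.append(grid[i])
        elif r0 * r1 < 0.0:
            roots.append(brentq(_akt_residual, grid[i], grid[i + 1],
                                args=(pdk1, hill), xtol=1e-14))
    if res[-1] == 0.0:
        roots.append(grid[-1])
    # deduplicate near-coincident roots (tangency at a fold)
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 10 * scan_step:
            dedup.append(r)
    pts = [_classify(pi3k, a, hill) for a in dedup]
    for p in pts:
        resid = np.abs(subnet_rhs(np.array(p.state), pi3k, hill)).max()
        if resid > RESIDUAL_TOL:
            raise RuntimeError(f"equilibrium residual {resid:.2e} too large")
    return pts


def _n_equilibria(pi3k: float, hill: HillParams, scan_step: float) -> int:
    return len(equilibria_at(pi3k, hill, scan_step))


def find_limit_point(hill: HillParams = DEFAULT_HILL,
                     bracket_tol: float = 1e-5,
                     scan_step: float = 1e-4) -> LimitPoint | None:
    """Locate the fold of the lower/unstable branch pair by bisection on
    the equilibrium count (3 below the LP, 1 above).

    Returns ``None`` when the system is monostable over the whole PI3K
    range (no fold) — a valid outcome for damped Hill parameters.
    """
    lo, hi = 0.0, 1.0
    if _n_equilibria(lo, hill, scan_step) < 3:
        return None
    if _n_equilibria(hi, hill, scan_step) >= 3:
        return None  # no fold inside the range
    while hi - lo > bracket_tol:
        mid = 0.5 * (lo + hi)
        if _n_equilibria(mid, hill, scan_step) >= 3:
            lo = mid
        else:
            hi = mid
    # merging pair: at lo the lower stable and unstable roots are closest
    pts = equilibria_at(lo, hill, scan_step)
    pts_sorted = sorted(pts, key=lambda p: p.akt)
    merge = pts_sorted[0] if len(pts_sorted) < 3 else pts_sorted[1]
    pi3k_lp = 0.5 * (lo + hi)
    return LimitPoint(pi3k=pi3k_lp, state=merge.state, bracket=hi - lo)


def limit_point(hill: HillParams = DEFAULT_HILL) -> float:
    """PI3K level of the fold with default settings (raises if absent)."""
    lp = find_limit_point(hill)
    if lp is None:
        raise RuntimeError("no limit point for these Hill parameters")
    return lp.pi3k


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------

def _corrector(p: float, a: float, hill: HillParams,
               tangent: np.ndarray, max_iter: int = 30) -> tuple[float, float]:
    """Newton correction of (pi3k, akt) onto the equilibrium curve,
    constrained to the hyperplane orthogonal to the predictor tangent."""
    f = lambda x: transfer_act(x, hill)
    p0, a0 = p, a
    for _ in range(max_iter):
        pdk1 = float(f(p))
        g = _akt_residual(a, pdk1, hill)
        if abs(g) < 1e-13:
            break
        h = 1e-7
        dg_da = (_akt_residual(a + h, pdk1, hill) - g) / h
        dg_dp = (_akt_residual(a, float(f(p + h)), hill) - g) / h
        # solve [dg_dp dg_da; t_p t_a] [dp da]^T = [-g; 0]
        det = dg_dp * tangent[1] - dg_da * tangent[0]
        if abs(det) < 1e-14:
            raise RuntimeError("singular corrector")
        dp = -g * tangent[1] / det
        da = g * tangent[0] / det
        p, a = p + dp, a + da
        if not (-0.05 <= p <= 1.05):
            raise RuntimeError("corrector left the parameter range")
    else:
        raise RuntimeError(f"corrector failed from ({p0:.4f}, {a0:.4f})")
    return p, a


def _continue_branch(p0: float, a0: float, direction: float,
                     hill: HillParams, step: float,
                     p_range: tuple[float, float]) -> list[tuple[float, float]]:
    """Pseudo-arclength continuation in the (PI3K, AKT) plane."""
    f = lambda x: transfer_act(x, hill)
    points = [(p0, a0)]
    # initial tangent along the parameter axis
    tangent = np.array([direction, 0.0])
    h = 1e-6
    g0 = _akt_residual(a0, float(f(p0)), hill)
    dg_da = (_akt_residual(a0 + h, float(f(p0)), hill) - g0) / h
    dg_dp = (_akt_residual(a0, float(f(p0 + h)), hill) - g0) / h
    t = np.array([dg_da, -dg_dp])
    if np.linalg.norm(t) > 1e-12:
        t = t / np.linalg.norm(t)
        if t[0] * direction < 0:
            t = -t
        tangent = t
    p, a = p0, a0
    ds = step
    for _ in range(20000):
        moved = False
        for attempt in range(12):
            try:
                pp = p + tangent[0] * ds
                ap = a + tangent[1] * ds
                pn, an = _corrector(pp, ap, hill, tangent)
            except RuntimeError:
                ds *= 0.5
                continue
            if abs(pn - p) > 5 * step or abs(an - a) > 5 * step:
                ds *= 0.5
                continue
            moved = True
            break
        if not moved:
            break
        new_t = np.array([pn - p, an - a])
        nrm = np.linalg.norm(new_t)
        if nrm < 1e-15:
            break
        tangent = new_t / nrm
        p, a = pn, an
        points.append((p, a))
        ds = min(step, ds * 1.7)
        if not (p_range[0] - 1e-9 <= p <= p_range[1] + 1e-9):
            break
        if not (-1e-6 <= a <= 1.0 + 1e-6):
            break
    return points


def trace_branches(pi3k_range: tuple[float, float] = (0.0, 1.0),
                   step: float = 2e-3,
                   hill: HillParams = DEFAULT_HILL) -> list[EquilibriumBranch]:
    """Trace equilibrium branches over a PI3K range.

    The lower stable branch and the unstable branch are obtained by a
    forward evolution from the zero state (the continuation rounds the
    fold and comes back); the upper branch by a backward evolution from
    the saturated state, mirroring a prediction–correction continuation
    run started from the two printed analytic equilibria.
    """
    lo, hi = pi3k_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("pi3k_range must be within [0, 1]")
    branches: list[EquilibriumBranch] = []

    start_pts = equilibria_at(lo, hill)
    lower_start = min(start_pts, key=lambda p: p.akt)
    fwd = _continue_branch(lo, lower_start.akt, +1.0, hill, step, (lo, hi))
    upper_pts = equilibria_at(hi, hill)
    upper_start = max(upper_pts, key=lambda p: p.akt)
    bwd = _continue_branch(hi, upper_start.akt, -1.0, hill, step, (lo, hi))

    fwd = [(p, a) for p, a in fwd if lo <= p <= hi]
    bwd = [(p, a) for p, a in bwd if lo <= p <= hi]
    fwd_cls = [_classify(p, a, hill) for p, a in fwd]
    lower = [pt for pt in fwd_cls if pt.stable]
    unstable = [pt for pt in fwd_cls if not pt.stable]
    upper = [_classify(p, a, hill) for p, a in bwd]
    upper = [pt for pt in upper if pt.stable]
    # close the upper branch at the left boundary if the last continuation
    # step stopped just short of it
    if upper and min(p.pi3k for p in upper) > lo + 1e-12:
        end = max(equilibria_at(lo, hill), key=lambda p: p.akt)
        upper.append(end)
    if lower:
        branches.append(EquilibriumBranch("lower", lower))
    if unstable:
        branches.append(EquilibriumBranch("unstable", unstable))
    if upper:
        branches.append(EquilibriumBranch("upper", upper))
    return branches


def lp_locus(ec50_grid, n_grid) -> dict[tuple[float, float], float | None]:
    """Limit-point position over a grid of Hill parameters.

    Entries are ``None`` where the fold disappears (signal too damped to
    sustain the positive feedback) or where the Hill normalization is
    undefined (``ec50^n >= 1/2``).
    """
    out: dict[tuple[float, float], float | None] = {}
    for ec50 in ec50_grid:
        for n in n_grid:
            try:
                hill = HillParams(n=float(n), ec50=float(ec50))
            except ValueError:
                out[(float(ec50), float(n))] = None
                continue
            lp = find_limit_point(hill, bracket_tol=1e-4, scan_step=5e-4)
            out[(float(ec50), float(n))] = None if lp is None else lp.pi3k
    return out


def input_surface(activator_grid, inhibitor_grid, weight: float = 1.0,
                  hill: HillParams = DEFAULT_HILL
                  ) -> tuple[np.ndarray, float]:
    """Steady PI3K over an (activator, inhibitor) AND-gate input surface.

    PI3K relaxes linearly onto its drive, so the steady level is
    ``W · f_act(activator) · f_inhib(inhibitor)``.  Returns the surface
    (activator levels along rows) and the fold threshold that the
    surface must cross to trigger AKT saturation.
    """
    a = np.asarray(activator_grid, dtype=float)[:, None]
    i = np.asarray(inhibitor_grid, dtype=float)[None, :]
    surface = weight * transfer_act(a, hill) * transfer_inhib(i, hill)
    return surface, limit_point(hill)


def ramp_hysteresis(hill: HillParams = DEFAULT_HILL,
                    pi3k_max: float = 0.4, t_ramp: float = 400.0,
                    n_steps: int = 8000) -> dict[str, float]:
    """Slowly ramp PI3K up past the fold and back down to zero.

    Integrates the sub-network ODEs (RK4, quasi-static ramp) and reports
    the AKT level at the end of the up-ramp and after the down-ramp; a
    bistable switch leaves the system on the upper branch (AKT high) even
    after PI3K returns to zero.
    """
    y = np.zeros(4)
    dt = t_ramp / n_steps
    akt_up = None
    for k in range(2 * n_steps):
        t = k * dt
        if t < t_ramp:
            p = pi3k_max * t / t_ramp
        else:
            p = pi3k_max * max(0.0, 2.0 - t / t_ramp)
        k1 = subnet_rhs(y, p, hill)
        k2 = subnet_rhs(y + 0.5 * dt * k1, p, hill)
        k3 = subnet_rhs(y + 0.5 * dt * k2, p, hill)
        k4 = subnet_rhs(y + dt * k3, p, hill)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if akt_up is None and t >= t_ramp:
            akt_up = float(y[1])
    return {"akt_after_up": akt_up, "akt_after_down": float(y[1])}
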