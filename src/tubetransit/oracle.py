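"""Independent 1-D drift-diffusion first-passage solver.

Solves  dp/dt = D d2p/dx2 - v dp/dx  on [0, L] with a zero-flux wall at
x = 0 and an absorbing boundary at x = L, and reports the absorbed
fraction F(t) = 1 - integral(p).  In the straight-channel geometry the
x-marginal of the non-interacting particle dynamics is exactly this
process (cylinder-wall reflections have radial normals and never change
x), which makes the solver an independent oracle for the stochastic
engine.

Two implementations cross-check each other: a finite-volume
Crank-Nicolson scheme (with first-order upwinding of the advection term
when the cell Peclet number v*dx/D exceeds 2) and, for the pure-diffusion
point-source case, the eigenfunction series

    F(t) = 1 - sum_n 4*(-1)^n / ((2n+1)*pi) * exp(-D*((2n+1)*pi/(2L))^2 t).
"""

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import RefinementError, ValidationError

_DEFAULT_CELLS = 2000
_MAX_CELLS = 32000
_REFINE_TOL = 1e-4


@dataclass(frozen=True)
class OracleProblem:
    """1-D first-passage problem (SI units).

    ``source_width`` = 0 means a point mass at x = 0; otherwise the
    initial density is uniform on [0, source_width].
    """

    D: float                  # m^2/s
    v: float = 0.0            # signed drift, m/s
    L: float = 4.0e-3         # m
    source_width: float = 5e-5  # m
    t_end: float = 10800.0    # s
    record_every: float = 60.0  # s

    def __post_init__(self):
        if not self.D > 0:
            raise ValidationError(f"D must be > 0, got {self.D!r}")
        if not self.L > 0:
            raise ValidationError(f"L must be > 0, got {self.L!r}")
        if not 0 <= self.source_width < self.L:
            raise ValidationError(
                f"source_width must lie in [0, L), got {self.source_width!r}")
        if not self.t_end > 0:
            raise ValidationError(f"t_end must be > 0, got {self.t_end!r}")

    @property
    def t_grid(self) -> np.ndarray:
        grid = np.arange(0.0, self.t_end + 1e-9, self.record_every)
        if grid[-1] < self.t_end - 1e-9:
            grid = np.append(grid, self.t_end)
        return grid


def _tridiagonal_operator(problem: OracleProblem, m: int):
    """Finite-volume tridiagonal generator A with dp/dt = A p.

    Interior faces use central advection unless |Pe_cell| > 2, in which
    case first-order upwinding keeps the scheme monotone.  The left
    boundary face carries zero total flux; the right boundary is held at
    p = 0 (absorbing).
    """
    D, v, L = problem.D, problem.v, problem.L
    dx = L / m
    lower = np.zeros(m)
    diag = np.zeros(m)
    upper = np.zeros(m)
    pe = abs(v) * dx / D
    upwind = pe > 2.0

    # interior faces between cells i-1 and i: flux = v*p_face - D*(p_i-p_{i-1})/dx
    for i in range(1, m):
        if upwind:
            a_left = v if v > 0 else 0.0   # coefficient of p_{i-1} in v*p_face
            a_right = v if v < 0 else 0.0  # coefficient of p_i
        else:
            a_left = 0.5 * v
            a_right = 0.5 * v
        # cell i-1 loses flux/dx, cell i gains
        diag[i - 1] += (-a_left - D / dx) / dx
        upper[i - 1] += (-a_right + D / dx) / dx
        lower[i] += (a_left + D / dx) / dx
        diag[i] += (a_right - D / dx) / dx

    # right boundary face: absorbing, p_face = 0 for diffusion (ghost with
    # p=0 at the face) and upwinded advection out of the last cell
    adv_out = v if v > 0 else 0.0
    diag[m - 1] += (-adv_out - 2.0 * D / dx) / dx
    # left boundary face: zero total flux (nothing to add)
    return lower, diag, upper, dx


def solve_drift_diffusion_1d(problem: OracleProblem,
                             n_cells: int = _DEFAULT_CELLS,
                             refine: bool = True) -> np.ndarray:
    """Absorbed fraction F on ``problem.t_grid`` via Crank-Nicolson.

    With ``refine=True`` the spatial grid is doubled until F(t_end)
    changes by less than 1e-4; exceeding the cell budget raises
    ``RefinementError`` with guidance (this happens when the global
    Peclet number v*L/D is too large for the budget).
    """
    F = _solve_fixed_grid(problem, n_cells)
    if not refine:
        return F
    m = n_cells
    while True:
        if 2 * m > _MAX_CELLS:
            raise RefinementError(
                f"grid not converged at {m} cells (Peclet number "
                f"{abs(problem.v) * problem.L / problem.D:.3g}); reduce the "
                "drift, increase D, or relax the refinement tolerance")
        F2 = _solve_fixed_grid(problem, 2 * m)
        if abs(F2[-1] - F[-1]) < _REFINE_TOL:
            return F2
        m *= 2
        F = F2


def _solve_fixed_grid(problem: OracleProblem, m: int) -> np.ndarray:
    lower, diag, upper, dx = _tridiagonal_operator(problem, m)

    p = np.zeros(m)
    if problem.source_width == 0.0:
        p[0] = 1.0 / dx
    else:
        w = problem.source_width
        centers = (np.arange(m) + 0.5) * dx
        # overlap of each cell with [0, w]
        lo = centers - 0.5 * dx
        hi = centers + 0.5 * dx
        overlap = np.clip(np.minimum(hi, w) - np.maximum(lo, 0.0), 0.0, None)
        p = overlap / (w * dx)

    t_grid = problem.t_grid
    F = np.zeros(len(t_grid))
    # internal step: Crank-Nicolson is unconditionally stable; the step is
    # chosen for temporal accuracy
    dt_target = max(problem.t_end / 2000.0, 1e-9)

    ab_cache = {}

    def matrices(dt):
        if dt not in ab_cache:
            # (I - dt/2 A) p+ = (I + dt/2 A) p
            h = 0.5 * dt
            ab = np.zeros((3, m))
            ab[0, 1:] = -h * upper[:-1]
            ab[1, :] = 1.0 - h * diag
            ab[2, :-1] = -h * lower[1:]
            ab_cache[dt] = ab
        return ab_cache[dt]

    def rhs(p, dt):
        h = 0.5 * dt
        out = p + h * diag * p
        out[:-1] += h * upper[:-1] * p[1:]
        out[1:] += h * lower[1:] * p[:-1]
        return out

    for k in range(1, len(t_grid)):
        span = t_grid[k] - t_grid[k - 1]
        n_sub = max(1, int(np.ceil(span / dt_target)))
        dt = span / n_sub
        ab = matrices(dt)
        for _ in range(n_sub):
            p = solve_banded((1, 1), ab, rhs(p, dt))
        F[k] = 1.0 - float(np.sum(p) * dx)
    return np.clip(F, 0.0, 1.0)


def series_arrival_pure_diffusion(D: float, L: float, t) -> np.ndarray:
    """Closed-form absorbed fraction for v = 0 and a point source at 0.

    Eigenfunction series truncated when the next term drops below 1e-12.
    Accepts scalar or array t; returns the same shape.
    """
    if not D > 0 or not L > 0:
        raise ValidationError("D and L must be > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    F = np.zeros_like(t_arr)
    for i, ti in enumerate(t_arr):
        if ti <= 0:
            F[i] = 0.0
            continue
        total = 0.0
        for n in range(100000):
            coeff = 4.0 * (-1.0) ** n / ((2 * n + 1) * np.pi)
            term = coeff * np.exp(-D * ((2 * n + 1) * np.pi / (2 * L)) ** 2 * ti)
            total += term
            if abs(term) < 1e-12:
                break
        F[i] = 1.0 - total
    F = np.clip(F, 0.0, 1.0)
    return F if np.ndim(t) else float(F[0])
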