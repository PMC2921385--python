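"""The 2D minimal model: an M x N cell layout of a young root's longitudinal cut.

Rows (layers) 3..M-2 are provascular: each runs the full 1D dynamics along
its N columns (influx alpha at its basal cell, acropetal PIN1 pumping, PIN1
expression feedback) and additionally exchanges auxin with the adjacent rows
by transverse diffusion.  The two outermost rows on each side (j in
{1, 2, M-1, M}) are epidermal: they neither express PIN1 nor receive shoot
influx; auxin enters them only by transverse diffusion from the provascular
core, moves along them by diffusion, and degrades.  The outermost rows
j = 1 and j = M have one-sided transverse exchange.

Column 1 is the root end.  The tip-cut / QC-ablation experiment drops the
n_cut tipmost columns of a stationary layout and restarts the dynamics,
tracking how a new auxin maximum re-forms at a distance from the new end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as scipy_root

from .params import AuxinTransportParams
from .minimal1d import ATOL, RTOL, STEADY_TOL
from .rates import pin_degradation_rate, pin_synthesis_rate

__all__ = [
    "Layout2D",
    "AblationResult",
    "provascular_rows",
    "epidermal_rows",
    "build_rhs_2d",
    "rhs_flat_2d",
    "integrate_2d",
    "steady_state_2d",
    "ablate_and_restart",
]


def provascular_rows(M: int) -> np.ndarray:
    """1-based provascular row indices j in {3 .. M-2}."""
    return np.arange(3, M - 1)


def epidermal_rows(M: int) -> np.ndarray:
    """1-based epidermal row indices j in {1, 2, M-1, M}."""
    return np.array([1, 2, M - 1, M])


@dataclass
class Layout2D:
    """M x N grid state; a[j-1, i-1] is the auxin level of row j, column i."""

    a: np.ndarray
    PIN: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).copy()
        self.PIN = np.asarray(self.PIN, dtype=float).copy()
        if self.a.ndim != 2 or self.a.shape != self.PIN.shape:
            raise ValueError("a and PIN must be 2D arrays of equal shape")
        M, N = self.a.shape
        if M < 6:
            raise ValueError(
                f"need M >= 6 rows (two epidermal rows flanking the provascular core "
                f"on each side), got M={M}"
            )
        if N < 2:
            raise ValueError(f"need N >= 2 columns, got N={N}")
        if np.any(self.a < 0) or np.any(self.PIN < 0):
            raise ValueError("concentrations must be nonnegative")
        epi = epidermal_rows(M) - 1
        if np.any(self.PIN[epi] != 0):
            raise ValueError("epidermal rows cannot carry PIN1")

    @property
    def M(self) -> int:
        return self.a.shape[0]

    @property
    def N(self) -> int:
        return self.a.shape[1]

    @classmethod
    def zeros(cls, M: int, N: int) -> "Layout2D":
        return cls(np.zeros((M, N)), np.zeros((M, N)))

    def copy(self) -> "Layout2D":
        return Layout2D(self.a.copy(), self.PIN.copy())

    def pack(self) -> np.ndarray:
        """Flatten to the reduced state [a (all rows), PIN (provascular rows)].

        Epidermal PIN is structurally zero, so it is excluded from the
        dynamic state: keeping it would add frozen components with zero
        rows in the Jacobian that pollute the stability spectrum.
        """
        prov = provascular_rows(self.M) - 1
        return np.concatenate([self.a.ravel(), self.PIN[prov].ravel()])

    @classmethod
    def unpack(cls, y: np.ndarray, M: int, N: int) -> "Layout2D":
        half = M * N
        prov = provascular_rows(M) - 1
        lay = cls.__new__(cls)
        lay.a = np.maximum(y[:half].reshape(M, N), 0.0)
        lay.PIN = np.zeros((M, N))
        lay.PIN[prov] = np.maximum(y[half:].reshape(prov.size, N), 0.0)
        return lay

    def provascular_max_column(self, row: Optional[int] = None) -> int:
        """1-based column of the auxin maximum in a provascular row
        (default: the row with the global provascular maximum)."""
        prov = provascular_rows(self.M) - 1
        if row is None:
            sub = self.a[prov]
            return int(np.unravel_index(np.argmax(sub), sub.shape)[1]) + 1
        return int(np.argmax(self.a[row - 1])) + 1


def _masks(M: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    prov = np.zeros(M, dtype=bool)
    prov[provascular_rows(M) - 1] = True
    return prov, ~prov


def rhs_flat_2d(
    y: np.ndarray,
    p: AuxinTransportParams,
    M: int,
    N: int,
    D_trans: Optional[float] = None,
) -> np.ndarray:
    """Raw flattened RHS.  ``D_trans`` overrides the transverse diffusion
    constant (default: the same D as the longitudinal one)."""
    Dt = p.D if D_trans is None else D_trans
    half = M * N
    provrows = provascular_rows(M) - 1
    a = y[:half].reshape(M, N)
    PIN = np.zeros((M, N))
    PIN[provrows] = y[half:].reshape(provrows.size, N)
    apos = np.maximum(a, 0.0)
    pinpos = np.maximum(PIN, 0.0)
    prov, epi = _masks(M, N)

    da = -p.Kd * a
    da[prov, -1] += p.alpha
    # longitudinal diffusion, all rows
    flux = p.D * np.diff(a, axis=1)
    da[:, :-1] += flux
    da[:, 1:] -= flux
    # transverse diffusion between adjacent rows (one-sided at j=1 and j=M)
    tflux = Dt * np.diff(a, axis=0)
    da[:-1, :] += tflux
    da[1:, :] -= tflux
    # acropetal active transport, provascular rows only (PIN is zero elsewhere)
    pump = p.K0 * pinpos[:, 1:] * apos[:, 1:]
    da[:, :-1] += pump
    da[:, 1:] -= pump

    dPINp = pin_synthesis_rate(apos[provrows], p) - pin_degradation_rate(
        apos[provrows], pinpos[provrows], p
    )
    return np.concatenate([da.ravel(), dPINp.ravel()])


def build_rhs_2d(
    state: Layout2D, p: AuxinTransportParams, D_trans: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (da/dt, dPIN/dt) on the full grid (epidermal PIN
    rows are identically zero).

    All internal fluxes cancel pairwise, so
    sum_{j,i} da/dt = (#provascular rows) * alpha - Kd * sum a exactly.
    """
    M, N = state.M, state.N
    dy = rhs_flat_2d(state.pack(), p, M, N, D_trans)
    half = M * N
    dPIN = np.zeros((M, N))
    dPIN[provascular_rows(M) - 1] = dy[half:].reshape(-1, N)
    return dy[:half].reshape(M, N), dPIN


def jacobian_2d(
    y: np.ndarray, p: AuxinTransportParams, M: int, N: int, D_trans: Optional[float] = None
) -> np.ndarray:
    """Analytic Jacobian of the flattened (reduced) 2D RHS.

    Assembled on the full a/PIN index space, then restricted to the active
    states (all auxin components plus provascular PIN); the restriction is
    exact because epidermal PIN is structurally constant at zero.
    """
    Dt = p.D if D_trans is None else D_trans
    half = M * N
    provrows = provascular_rows(M) - 1
    a = np.maximum(y[:half].reshape(M, N), 0.0)
    PIN = np.zeros((M, N))
    PIN[provrows] = np.maximum(y[half:].reshape(provrows.size, N), 0.0)
    prov, _ = _masks(M, N)
    J = np.zeros((2 * half, 2 * half))

    def idx(j, i):  # flat auxin index
        return j * N + i

    ii = np.arange(half)
    J[ii, ii] -= p.Kd
    # longitudinal diffusion
    for j in range(M):
        for i in range(N - 1):
            l, r = idx(j, i), idx(j, i + 1)
            J[l, l] -= p.D
            J[l, r] += p.D
            J[r, r] -= p.D
            J[r, l] += p.D
    # transverse diffusion
    for j in range(M - 1):
        for i in range(N):
            u, d = idx(j, i), idx(j + 1, i)
            J[u, u] -= Dt
            J[u, d] += Dt
            J[d, d] -= Dt
            J[d, u] += Dt
    # active transport and PIN blocks
    A = p.q1**p.h1
    B = p.q2**p.h1
    for j in np.flatnonzero(prov):
        for i in range(1, N):
            src, dst = idx(j, i), idx(j, i - 1)
            J[dst, src] += p.K0 * PIN[j, i]
            J[src, src] -= p.K0 * PIN[j, i]
            J[dst, half + src] += p.K0 * a[j, i]
            J[src, half + src] -= p.K0 * a[j, i]
        for i in range(N):
            k = idx(j, i)
            av = a[j, i]
            x = av**p.h1
            dsyn_dx = p.k1 * x * (2 * A * B + (A + B) * x) / ((A + x) ** 2 * (B + x) ** 2)
            dx_da = p.h1 * av ** (p.h1 - 1.0) if av > 0 else (1.0 if p.h1 == 1.0 else 0.0)
            ddeg_da = p.k2 * PIN[j, i] * p.h2 * av ** (p.h2 - 1.0) / p.q3**p.h2
            J[half + k, k] = dsyn_dx * dx_da - ddeg_da
            J[half + k, half + k] = -p.k2 * (1.0 + (av / p.q3) ** p.h2)
    active = np.concatenate(
        [np.arange(half), half + (provrows[:, None] * N + np.arange(N)).ravel()]
    )
    return J[np.ix_(active, active)]


@dataclass
class Trajectory2D:
    times: np.ndarray
    states: list  # list[Layout2D]
    diagnostics: dict = field(default_factory=dict)

    @property
    def final(self) -> Layout2D:
        return self.states[-1]


def integrate_2d(
    init: Layout2D,
    p: AuxinTransportParams,
    t_end: float,
    *,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    D_trans: Optional[float] = None,
) -> Trajectory2D:
    """Stiff (BDF) integration of the full grid."""
    M, N = init.M, init.N
    sol = solve_ivp(
        lambda t, y: rhs_flat_2d(y, p, M, N, D_trans),
        (0.0, t_end),
        init.pack(),
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: jacobian_2d(y, p, M, N, D_trans),
    )
    if not sol.success:
        raise RuntimeError(f"2D integration failed at t={sol.t[-1]}: {sol.message}")
    states = [Layout2D.unpack(sol.y[:, k], M, N) for k in range(sol.t.size)]
    return Trajectory2D(sol.t, states, {"nfev": sol.nfev, "njev": sol.njev})


def steady_state_2d(
    p: AuxinTransportParams,
    M: int = 8,
    N: int = 50,
    init: Optional[Layout2D] = None,
    *,
    tol: float = STEADY_TOL,
    t_relax: float = 1500.0,
    max_relax_rounds: int = 10,
) -> Layout2D:
    """Stationary grid solution of the Cauchy problem (zero initial data by
    default): relax by stiff integration, polish with Newton."""
    if init is None:
        init = Layout2D.zeros(M, N)
    M, N = init.M, init.N
    fun = lambda v: rhs_flat_2d(v, p, M, N)
    jac = lambda v: jacobian_2d(v, p, M, N)
    cur = init
    for _ in range(max_relax_rounds):
        cur = integrate_2d(cur, p, t_relax).final
        if np.max(np.abs(fun(cur.pack()))) < 1e-3:
            sol = scipy_root(fun, cur.pack(), jac=jac, method="hybr")
            if (
                sol.success
                and np.max(np.abs(fun(sol.x))) < tol
                and np.min(sol.x) > -1e-8
                and np.max(np.abs(sol.x - cur.pack())) < 1e-2 * (1 + np.max(cur.a))
            ):
                return Layout2D.unpack(sol.x, M, N)
    raise RuntimeError("2D steady state did not converge (relaxation + Newton)")


@dataclass
class AblationResult:
    """Outcome of the tip-cut / QC-ablation restart experiment."""

    trajectory: Trajectory2D
    track_row: int
    times: np.ndarray
    max_column: np.ndarray  # 1-based argmax column of the tracked row over time
    max_value: np.ndarray
    final: Layout2D


def ablate_and_restart(
    stationary: Layout2D,
    p: AuxinTransportParams,
    n_cut: int = 5,
    *,
    track_row: int = 4,
    t_end: float = 4000.0,
    n_snapshots: int = 200,
) -> AblationResult:
    """Cut off the ``n_cut`` tipmost columns of a stationary layout and
    integrate the truncated root, tracking the auxin maximum of one
    provascular row as the reflected-flow mechanism rebuilds it at a
    distance from the new root end."""
    if not 0 <= n_cut < stationary.N:
        raise ValueError(f"n_cut must be in [0, N), got {n_cut}")
    init = Layout2D(stationary.a[:, n_cut:], stationary.PIN[:, n_cut:].copy())
    # truncation leaves epidermal PIN zero by construction
    t_eval = np.linspace(0.0, t_end, n_snapshots)
    traj = integrate_2d(init, p, t_end, t_eval=t_eval)
    cols = np.array([s.provascular_max_column(track_row) for s in traj.states])
    vals = np.array([np.max(s.a[track_row - 1]) for s in traj.states])
    return AblationResult(traj, track_row, traj.times, cols, vals, traj.final)
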