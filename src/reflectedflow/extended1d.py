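"""The 1D extended model: a growing, dividing cell file under auxin control.

The fixed-file transport dynamics are augmented with

* a third morphogen, the Division Factor, synthesized where the auxin
  profile drops steeply toward the root base, degraded in an
  auxin-dependent way, and diffusing between cells;
* per-cell size r and a two-phase cell cycle (growth phase: elongation at
  rate K_growth; idle phase: no growth) whose completions are random events
  driven by the instantaneous hazards f_GP(r) and f_IP(DivF);
* division (idle-phase completion): the mother splits into two daughters of
  half size that inherit her concentrations unchanged, so amounts
  (concentration x size) are conserved and the file is renumbered;
* sloughing of root-cap cells: under the default policy the tipmost cell is
  removed whenever more than a fixed number of cells lie distal to the
  auxin maximum;
* a time-dependent influx schedule alpha(t) = alpha0 + k*t emulating the
  increasing auxin supply from a growing shoot.

Deterministic dynamics advance with fixed-step classical Runge-Kutta (RK4);
the step is the minimum of dt_max and a local stability limit, and is halved
when a concentration would go negative.  Phase completions use the standard
accumulated-hazard construction: each cell draws a unit-exponential
threshold when it enters a phase, integrates its hazard along the
trajectory, and fires when the integral crosses the threshold; the event
time is located inside the step by bisection, the event is applied
atomically, and integration resumes.  Growth dilutes concentrations
(a growing cell's amount is spread over its increasing size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy.special import expit

from .params import CellCycleParams, DivisionFactorParams, FluxSchedule, ParameterSet
from .rates import Phase, f_GP, f_IP

__all__ = [
    "RootState",
    "Event",
    "EventLog",
    "SloughPolicy",
    "ExtendedRun",
    "init_root",
    "divf_rhs",
    "extended_rhs",
    "step_hybrid",
    "divide",
    "slough",
    "run_extended",
    "division_rate_profile",
    "classify_cells",
    "CellType",
]

EVENT_TIME_TOL = 1e-6  # tu, bisection tolerance for event localization
_MIN_DT = 1e-7

CellType = Literal[
    "columella", "root_cap_initial", "QC", "vascular_initial", "meristem", "differentiation"
]


@dataclass
class Event:
    time: float
    kind: Literal["division", "phase_change", "removal"]
    cell_id: int
    position: int  # 1-based index at event time


class EventLog:
    """Timestamped division / phase-change / removal events."""

    def __init__(self) -> None:
        self.events: list[Event] = []

    def append(self, ev: Event) -> None:
        if self.events and ev.time < self.events[-1].time - 1e-12:
            raise ValueError("event times must be nondecreasing")
        self.events.append(ev)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class RootState:
    """Dynamic cell file: parallel per-cell arrays ordered tip -> base."""

    t: float
    a: np.ndarray
    PIN: np.ndarray
    DivF: np.ndarray
    r: np.ndarray
    growing: np.ndarray  # bool; True = growth phase
    hazard_acc: np.ndarray
    hazard_thresh: np.ndarray
    ids: np.ndarray
    next_id: int

    @property
    def N(self) -> int:
        return self.a.size

    @property
    def x(self) -> np.ndarray:
        """Cell centers: origin at the outer wall of cell 1."""
        return np.cumsum(self.r) - self.r / 2

    @property
    def length(self) -> float:
        return float(self.r.sum())

    def phase(self, i: int) -> Phase:
        return Phase.GROWTH if self.growing[i] else Phase.IDLE

    def amounts(self) -> np.ndarray:
        """Per-cell auxin amounts a_i * r_i (conserved across divisions)."""
        return self.a * self.r

    def max_cell(self) -> int:
        return int(np.argmax(self.a)) + 1

    def copy(self) -> "RootState":
        return RootState(
            self.t,
            self.a.copy(),
            self.PIN.copy(),
            self.DivF.copy(),
            self.r.copy(),
            self.growing.copy(),
            self.hazard_acc.copy(),
            self.hazard_thresh.copy(),
            self.ids.copy(),
            self.next_id,
        )


@dataclass(frozen=True)
class SloughPolicy:
    """Root-cap sloughing rule: remove cell 1 when more than ``cap`` cells
    lie distal to the distal-most prominent auxin maximum, at most once per
    ``min_interval`` time units: sloughing is a slow surface process, and
    its maximal rate (1/min_interval) must stay below the meristem's
    division capacity or a transient over-supply erodes the whole tip.
    ``enabled=False`` disables removals entirely."""

    enabled: bool = True
    cap: int = 5
    min_interval: float = 20.0


def init_root(
    pset: ParameterSet,
    n_cells: int = 3,
    *,
    a_seed: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> RootState:
    """Initial root of ``n_cells`` growth-phase cells of birth size r0 with
    the auxin maximum seeded in cell 2 (the embryonic pattern); PIN and
    Division Factor start at zero."""
    if n_cells < 2:
        raise ValueError("need at least 2 initial cells")
    if rng is None:
        rng = np.random.default_rng(0)
    cc = pset.cell_cycle
    a = np.zeros(n_cells)
    a[1] = a_seed
    return RootState(
        t=0.0,
        a=a,
        PIN=np.zeros(n_cells),
        DivF=np.zeros(n_cells),
        r=np.full(n_cells, cc.r0),
        growing=np.ones(n_cells, dtype=bool),
        hazard_acc=np.zeros(n_cells),
        hazard_thresh=rng.exponential(size=n_cells),
        ids=np.arange(1, n_cells + 1),
        next_id=n_cells + 1,
    )


def divf_rhs(
    a: np.ndarray, DivF: np.ndarray, dp: DivisionFactorParams
) -> np.ndarray:
    """Division Factor derivative: gradient-driven synthesis (zero in the
    basal cell), auxin-regulated degradation, pairwise diffusion.

    Synthesis is a logistic sigmoid of the tipward auxin drop
    (a_i - a_{i+1}) on scale T, with midpoint at five scales, so it is
    active only where the profile falls steeply toward the base - the
    proximal flank of the auxin maximum.
    """
    from .rates import divf_degradation_rate, divf_synthesis_rate

    n = a.size
    apos = np.maximum(a, 0.0)
    dD = np.zeros(n)
    dD[:-1] += divf_synthesis_rate(apos[:-1], apos[1:], dp)
    dD -= divf_degradation_rate(apos, np.maximum(DivF, 0.0), dp)
    flux = dp.D_DivF * np.diff(DivF)
    dD[:-1] += flux
    dD[1:] -= flux
    return dD


def extended_rhs(
    a: np.ndarray,
    PIN: np.ndarray,
    DivF: np.ndarray,
    r: np.ndarray,
    growing: np.ndarray,
    pset: ParameterSet,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coupled derivative of the growing file at influx ``alpha``.

    Transport follows the fixed-file equations on the current cell order;
    growth adds a dilution term -(dr/dt / r) * c to every concentration c of
    an elongating cell, so that elongation spreads a fixed amount over an
    increasing size.
    """
    from .rates import pin_degradation_rate, pin_synthesis_rate

    p = pset.auxin
    apos = np.maximum(a, 0.0)
    pinpos = np.maximum(PIN, 0.0)
    da = -p.Kd * a
    da[-1] += alpha
    flux = p.D * np.diff(a)
    da[:-1] += flux
    da[1:] -= flux
    pump = p.K0 * pinpos[1:] * apos[1:]
    da[:-1] += pump
    da[1:] -= pump
    dPIN = pin_synthesis_rate(apos, p) - pin_degradation_rate(apos, pinpos, p)
    dD = divf_rhs(a, DivF, pset.division_factor)
    dr = np.where(growing, pset.cell_cycle.K_growth, 0.0)
    dil = dr / r
    return da - dil * a, dPIN - dil * PIN, dD - dil * DivF, dr


def _hazards_arrays(
    growing: np.ndarray, r: np.ndarray, DivF: np.ndarray, cc: CellCycleParams
) -> np.ndarray:
    h = np.empty(growing.size)
    g = growing
    if g.any():
        h[g] = f_GP(r[g], cc)
    if (~g).any():
        h[~g] = f_IP(np.maximum(DivF[~g], 0.0), cc)
    return h


def _hazards(root: RootState, cc: CellCycleParams) -> np.ndarray:
    return _hazards_arrays(root.growing, root.r, root.DivF, cc)


def _stability_dt(root: RootState, pset: ParameterSet) -> float:
    """Conservative explicit-step bound from the fastest local decay rate."""
    p = pset.auxin
    dp = pset.division_factor
    amax = float(np.max(root.a, initial=0.0))
    rate_pin = p.k2 * (1.0 + (max(amax, 0.0) / p.q3) ** p.h2)
    rate_a = p.Kd + 2 * p.D + p.K0 * float(np.max(root.PIN, initial=0.0))
    rate_d = dp.kdeg * (1.0 + (max(amax, 0.0) / dp.q4) ** dp.h3) + 2 * dp.D_DivF
    # classical RK4 real-axis stability limit is |lambda| dt < 2.78; keep a
    # 10% margin (negativity-triggered halving is the safety net)
    return 2.5 / max(rate_pin, rate_a, rate_d, 1e-12)


def _make_fast_rhs(
    growing: np.ndarray, pset: ParameterSet, schedule: Optional[FluxSchedule]
) -> Callable:
    """Closure computing the same derivative as :func:`extended_rhs` without
    validation overhead (the hot path of the fixed-step integrator)."""
    p = pset.auxin
    dp = pset.division_factor
    A = p.q1**p.h1
    B = p.q2**p.h1
    Kg = pset.cell_cycle.K_growth
    grow = growing.astype(float) * Kg

    def f(t, a, PIN, DivF, r):
        alpha = schedule.alpha0 + schedule.k * t if schedule is not None else p.alpha
        apos = np.maximum(a, 0.0)
        pinpos = np.maximum(PIN, 0.0)
        da = -p.Kd * a
        da[-1] += alpha
        flux = p.D * np.diff(a)
        da[:-1] += flux
        da[1:] -= flux
        pump = p.K0 * pinpos[1:] * apos[1:]
        da[:-1] += pump
        da[1:] -= pump
        x = apos if p.h1 == 1.0 else apos**p.h1
        dPIN = p.k1 * x * x / ((A + x) * (B + x)) - p.k2 * pinpos * (
            1.0 + (apos / p.q3) ** p.h2
        )
        drop = (apos[:-1] - apos[1:]) / dp.T - 5.0
        syn = dp.beta * expit(drop)
        dD = np.empty_like(DivF)
        dD[:-1] = syn
        dD[-1] = 0.0
        dD -= (
            dp.kdeg
            * np.maximum(DivF, 0.0)
            * (1.0 + (apos / dp.q4) ** dp.h3)
            / (1.0 + (apos / dp.q5) ** dp.h4)
        )
        dflux = dp.D_DivF * np.diff(DivF)
        dD[:-1] += dflux
        dD[1:] -= dflux
        dil = grow / r
        return da - dil * a, dPIN - dil * PIN, dD - dil * DivF, grow

    return f


def _rk4_advance(
    root: RootState, dt: float, pset: ParameterSet, schedule: Optional[FluxSchedule]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One classical RK4 step of the continuous state; returns new arrays."""

    f = _make_fast_rhs(root.growing, pset, schedule)

    t, a, PIN, D, r = root.t, root.a, root.PIN, root.DivF, root.r
    k1 = f(t, a, PIN, D, r)
    k2 = f(t + dt / 2, a + dt / 2 * k1[0], PIN + dt / 2 * k1[1], D + dt / 2 * k1[2], r + dt / 2 * k1[3])
    k3 = f(t + dt / 2, a + dt / 2 * k2[0], PIN + dt / 2 * k2[1], D + dt / 2 * k2[2], r + dt / 2 * k2[3])
    k4 = f(t + dt, a + dt * k3[0], PIN + dt * k3[1], D + dt * k3[2], r + dt * k3[3])
    out = []
    for comp, (c1, c2, c3, c4) in zip((a, PIN, D, r), zip(k1, k2, k3, k4)):
        out.append(comp + dt / 6 * (c1 + 2 * c2 + 2 * c3 + c4))
    return tuple(out)  # type: ignore[return-value]


def divide(root: RootState, i: int, log: EventLog, rng: np.random.Generator) -> None:
    """Split cell i (0-based) into two half-size daughters in growth phase.

    Daughters inherit the mother's concentrations unchanged (intensive
    inheritance), so the total amounts sum(c*r) are continuous across the
    event; the file is renumbered by the insertion.
    """
    half = root.r[i] / 2
    ins = lambda arr, v1, v2: np.concatenate([arr[:i], [v1, v2], arr[i + 1 :]])
    log.append(Event(root.t, "division", int(root.ids[i]), i + 1))
    d1, d2 = root.next_id, root.next_id + 1
    root.next_id += 2
    root.r = ins(root.r, half, half)
    root.a = ins(root.a, root.a[i], root.a[i])
    root.PIN = ins(root.PIN, root.PIN[i], root.PIN[i])
    root.DivF = ins(root.DivF, root.DivF[i], root.DivF[i])
    root.growing = np.concatenate(
        [root.growing[:i], [True, True], root.growing[i + 1 :]]
    ).astype(bool)
    root.hazard_acc = ins(root.hazard_acc, 0.0, 0.0)
    root.hazard_thresh = ins(root.hazard_thresh, rng.exponential(), rng.exponential())
    root.ids = np.concatenate([root.ids[:i], [d1, d2], root.ids[i + 1 :]]).astype(int)


def slough(
    root: RootState,
    policy: SloughPolicy,
    log: Optional[EventLog] = None,
    *,
    last_removal: float = -np.inf,
) -> RootState:
    """Apply the sloughing policy once: remove cell 1 if more than
    ``policy.cap`` cells lie distal to the global auxin maximum and the
    cooldown since the last removal has elapsed."""
    if not policy.enabled or root.N < 3:
        return root
    if root.t - last_removal < policy.min_interval:
        return root
    # anchor on the distal-most prominent maximum: the root cap belongs to
    # the tip-adjacent maximum, and a transient secondary maximum far up the
    # file must not trigger wholesale erosion of the tip
    if int(np.argmax(root.a)) <= policy.cap:
        return root  # even the global maximum is within the cap
    from .analysis import find_maxima

    maxima = find_maxima(root.a, epsilon=0.05 * float(np.max(root.a, initial=0.0)))
    if not maxima:
        return root
    distal = maxima[0] - 1  # cells strictly distal to that maximum
    if distal > policy.cap:
        if log is not None:
            log.append(Event(root.t, "removal", int(root.ids[0]), 1))
        for name in ("a", "PIN", "DivF", "r", "growing", "hazard_acc", "hazard_thresh", "ids"):
            setattr(root, name, getattr(root, name)[1:])
    return root


def step_hybrid(
    root: RootState,
    dt_max: float,
    rng: np.random.Generator,
    pset: ParameterSet,
    *,
    schedule: Optional[FluxSchedule] = None,
    log: Optional[EventLog] = None,
    hazards_enabled: bool = True,
    slough_policy: Optional[SloughPolicy] = None,
) -> list[Event]:
    """Advance the root by at most ``dt_max``, firing at most the earliest
    phase-completion event.

    The continuous state advances by RK4 with step min(dt_max, stability
    limit), halving on any negative concentration.  Hazards accumulate by
    the trapezoid rule along the step; if a cell's accumulator crosses its
    pre-drawn unit-exponential threshold, the crossing time is located by
    bisection (to 1e-6 tu), the step is cut there, and the event (division
    for idle-phase completion, growth->idle otherwise) is applied before
    returning.  Returns the events fired (also appended to ``log``).
    """
    if log is None:
        log = EventLog()
    cc = pset.cell_cycle
    dt = min(dt_max, _stability_dt(root, pset))

    h0 = _hazards(root, cc) if hazards_enabled else np.zeros(root.N)

    def try_step(step: float):
        a, PIN, D, r = _rk4_advance(root, step, pset, schedule)
        if min(a.min(), PIN.min(), D.min()) < 0.0:
            return None
        return a, PIN, D, r

    while True:
        res = try_step(dt)
        if res is not None:
            break
        dt /= 2
        if dt < _MIN_DT:
            raise RuntimeError(
                f"step size collapsed at t={root.t}: state drives concentrations negative"
            )

    def hazard_gain(step: float, state) -> np.ndarray:
        h1 = _hazards_arrays(root.growing, state[3], state[2], cc)
        return 0.5 * step * (h0 + h1)

    events: list[Event] = []
    if hazards_enabled:
        gain = hazard_gain(dt, res)
        acc = root.hazard_acc + gain
        if np.any(acc >= root.hazard_thresh):
            # locate the earliest crossing by bisection on the sub-step
            lo, hi = 0.0, dt
            state_hi = res
            for _ in range(60):
                if hi - lo <= EVENT_TIME_TOL:
                    break
                mid = 0.5 * (lo + hi)
                state_mid = try_step(mid)
                if state_mid is None:
                    hi = mid
                    continue
                acc_mid = root.hazard_acc + hazard_gain(mid, state_mid)
                if np.any(acc_mid >= root.hazard_thresh):
                    hi, state_hi = mid, state_mid
                else:
                    lo = mid
            dt = hi
            res = state_hi
            acc = root.hazard_acc + hazard_gain(dt, res)
        root.hazard_acc = acc

    root.a, root.PIN, root.DivF, root.r = res
    root.t += dt

    if hazards_enabled:
        crossed = np.flatnonzero(root.hazard_acc >= root.hazard_thresh)
        if crossed.size:
            # apply the most-accumulated crossing only; others fire on
            # subsequent (zero-length hazard) steps in strict order
            i = int(crossed[np.argmax(root.hazard_acc[crossed] - root.hazard_thresh[crossed])])
            if root.growing[i]:
                root.growing[i] = False
                root.hazard_acc[i] = 0.0
                root.hazard_thresh[i] = rng.exponential()
                ev = Event(root.t, "phase_change", int(root.ids[i]), i + 1)
                log.append(ev)
                events.append(ev)
            else:
                divide(root, i, log, rng)
                events.append(log.events[-1])

    if slough_policy is not None:
        before = len(log)
        removals = [e.time for e in log.events if e.kind == "removal"]
        slough(root, slough_policy, log, last_removal=removals[-1] if removals else -np.inf)
        events.extend(log.events[before:])
    return events


@dataclass
class ExtendedRun:
    """Outcome of a growing-root simulation."""

    root: RootState
    log: EventLog
    snapshot_times: list[float] = field(default_factory=list)
    snapshots: list[RootState] = field(default_factory=list)
    max_distance: list[tuple[float, int, int]] = field(default_factory=list)
    # (time, N, 1-based auxin-maximum cell index)


def run_extended(
    pset: ParameterSet,
    t_end: float,
    *,
    seed: int = 0,
    n_cells: int = 3,
    dt_max: float = 0.01,
    schedule: Optional[FluxSchedule] = None,
    slough_policy: Optional[SloughPolicy] = None,
    hazards_enabled: bool = True,
    snapshot_every: Optional[float] = None,
    record_every: float = 10.0,
    max_cells: Optional[int] = None,
    min_cells: Optional[int] = None,
    init: Optional[RootState] = None,
) -> ExtendedRun:
    """Drive the hybrid simulation from ``n_cells`` initial cells to t_end
    (or until the file reaches ``max_cells``).

    ``min_cells`` stops a run whose file, having once grown past that size,
    shrinks back below it: a root eroded that far is in the degenerate
    auxin-saturated terminal state (no pattern, no divisions) and only
    burns integrator steps."""
    rng = np.random.default_rng(seed)
    root = init if init is not None else init_root(pset, n_cells, rng=rng)
    if slough_policy is None:
        slough_policy = SloughPolicy()
    log = EventLog()
    run = ExtendedRun(root, log)
    next_snap = 0.0
    next_rec = 0.0
    peak_n = 0
    while root.t < t_end:
        if snapshot_every is not None and root.t >= next_snap:
            run.snapshot_times.append(root.t)
            run.snapshots.append(root.copy())
            next_snap += snapshot_every
        if root.t >= next_rec:
            run.max_distance.append((root.t, root.N, root.max_cell()))
            next_rec += record_every
        step_hybrid(
            root,
            min(dt_max, t_end - root.t),
            rng,
            pset,
            schedule=schedule,
            log=log,
            hazards_enabled=hazards_enabled,
            slough_policy=slough_policy,
        )
        if max_cells is not None and root.N >= max_cells:
            break
        if min_cells is not None:
            peak_n = max(peak_n, root.N)
            if peak_n >= min_cells and root.N < min_cells:
                run.max_distance.append((root.t, root.N, root.max_cell()))
                return run
    run.max_distance.append((root.t, root.N, root.max_cell()))
    return run


def division_rate_profile(
    log: EventLog, window: tuple[float, float], n_positions: int
) -> np.ndarray:
    """Divisions per cell position per unit time, binned by the 1-based
    position index at event time, over the time window."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive duration")
    rates = np.zeros(n_positions)
    for ev in log.of_kind("division"):
        if t0 <= ev.time <= t1 and 1 <= ev.position <= n_positions:
            rates[ev.position - 1] += 1.0
    return rates / (t1 - t0)


def classify_cells(
    root: RootState,
    log: EventLog,
    window: tuple[float, float],
    *,
    rare_frac: float = 0.1,
    active_frac: float = 0.4,
) -> list[str]:
    """Assign RAM cell-type labels from position (relative to the auxin
    maximum) and the empirical division-rate profile.

    Distal of the maximum: columella (nondividing, auxin-rich).  The
    maximum cell itself: root cap initial.  Its proximal neighbour: QC.
    Then vascular initials until the division rate reaches the active
    threshold, the actively dividing meristem while it stays there, and the
    nondividing differentiation zone beyond.  Rates below ``rare_frac`` (of
    the profile maximum) count as nondividing, above ``active_frac`` as
    actively dividing.
    """
    if not window[1] > window[0]:
        raise ValueError("window must have positive duration")
    n = root.N
    rates = division_rate_profile(log, window, n)
    top = rates.max()
    labels: list[str] = ["differentiation"] * n
    k = int(np.argmax(root.a))  # 0-based maximum cell
    for i in range(k):
        labels[i] = "columella"
    labels[k] = "root_cap_initial"
    if k + 1 < n:
        labels[k + 1] = "QC"
    j = k + 2
    active_thr = active_frac * top if top > 0 else np.inf
    rare_thr = rare_frac * top if top > 0 else np.inf
    while j < n and rates[j] < active_thr:
        labels[j] = "vascular_initial"
        j += 1
    while j < n and rates[j] >= rare_thr:
        labels[j] = "meristem"
        j += 1
    # remaining proximal nondividing cells stay "differentiation"
    return labels
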