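"""Parameter containers and the named-preset registry.

All concentrations are in abstract concentration units (cu) and times in
abstract time units (tu); no SI conversion is attempted.  Two named presets,
``basic`` and ``robust``, are bundled as YAML files under
``reflectedflow/presets/``.  The robust preset is characterised by sharp
auxin-dependent inhibition of PIN1 expression (h2 = 10 at threshold
q3 = 3.26), which makes the patterning behave like a fibrous-root transport
system; the basic preset has a gentler inhibition and behaves like a taproot
system.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "AuxinTransportParams",
    "DivisionFactorParams",
    "GrowthPhaseShape",
    "IdlePhaseShape",
    "CellCycleParams",
    "FluxSchedule",
    "ParameterSet",
    "load_preset",
    "available_presets",
]

# In-text anchor values that the loader asserts for the bundled presets.
# Loading fails loudly if a preset file drifts away from these.
_PRESET_ANCHORS = {
    "robust": {"auxin.h2": 10.0, "auxin.q3": 3.26, "division_factor.T": 0.1},
    "basic": {"division_factor.T": 0.1},
}


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")


@dataclass(frozen=True)
class AuxinTransportParams:
    """Rate constants of the auxin/PIN1 transport system.

    alpha : auxin influx from the shoot into the basal cell (cu/tu)
    Kd    : first-order auxin degradation rate constant (1/tu)
    D     : cell-to-cell diffusion rate constant (1/tu)
    K0    : active (PIN1-mediated) transport rate constant (1/(cu tu))
    k1    : maximal PIN1 synthesis rate (cu/tu)
    q1    : activation threshold of auxin-dependent PIN1 synthesis (cu)
    q2    : saturation threshold of auxin-dependent PIN1 synthesis (cu)
    h1    : synthesis response exponent (dimensionless, >= 1)
    k2    : basal PIN1 degradation rate constant (1/tu)
    q3    : threshold of auxin-dependent PIN1 degradation (cu)
    h2    : degradation response exponent (dimensionless, >= 1)
    """

    alpha: float
    Kd: float
    D: float
    K0: float
    k1: float
    q1: float
    q2: float
    h1: float
    k2: float
    q3: float
    h2: float

    def __post_init__(self) -> None:
        for name in ("Kd", "k1", "q1", "q2", "h1", "k2", "q3", "h2"):
            _positive(name, getattr(self, name))
        # alpha, D and K0 may be zero: influx-free, diffusion-free and
        # transport-free degenerate systems are legitimate limiting cases
        for name in ("alpha", "D", "K0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.q1 > self.q2:
            raise ValueError(
                f"activation threshold q1={self.q1} must not exceed "
                f"saturation threshold q2={self.q2}"
            )
        if self.h1 < 1 or self.h2 < 1:
            raise ValueError("response exponents h1, h2 must be >= 1")

    def replace(self, **changes: float) -> "AuxinTransportParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DivisionFactorParams:
    """Parameters of the Division Factor morphogen.

    beta   : maximal Division Factor synthesis rate (cu/tu)
    T      : steepness scale of the gradient-driven synthesis sigmoid (cu)
    kdeg   : rate coefficient of auxin-dependent degradation (1/tu)
    q4     : lower auxin threshold of the degradation response (cu)
    q5     : upper auxin threshold of the degradation response (cu)
    h3, h4 : Hill exponents of the degradation response
    D_DivF : Division Factor diffusion rate constant (1/tu)
    """

    beta: float
    kdeg: float
    q4: float
    q5: float
    h3: float
    h4: float
    D_DivF: float
    T: float = 0.1

    def __post_init__(self) -> None:
        for name in ("beta", "T", "kdeg", "q4", "q5", "h3", "h4", "D_DivF"):
            _positive(name, getattr(self, name))

    def replace(self, **changes: float) -> "DivisionFactorParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class GrowthPhaseShape:
    """Shape of the growth-phase completion hazard f_GP(r).

    k_gp is the hazard plateau (1/tu); h_gp the sharpness exponent that keeps
    the hazard negligible below the minimal division size r_min.
    """

    k_gp: float = 1.0
    h_gp: float = 20.0

    def __post_init__(self) -> None:
        _positive("k_gp", self.k_gp)
        _positive("h_gp", self.h_gp)


@dataclass(frozen=True)
class IdlePhaseShape:
    """Shape of the idle-phase completion hazard f_IP(DivF).

    The hazard is bell-shaped in the Division Factor concentration: low at
    deficiency and excess, maximal at intermediate levels.  Two exponents
    (h_lo rising flank, h_hi falling flank, with h_hi > h_lo) make the
    generalized Hill function unimodal; q_lo and q_hi are the corresponding
    concentration scales (cu) and k_ip the hazard scale (1/tu).
    """

    k_ip: float = 1.0
    q_lo: float = 0.1
    q_hi: float = 1.0
    h_lo: float = 2.0
    h_hi: float = 6.0

    def __post_init__(self) -> None:
        for name in ("k_ip", "q_lo", "q_hi", "h_lo", "h_hi"):
            _positive(name, getattr(self, name))
        if self.h_hi <= self.h_lo:
            raise ValueError(
                "bell shape requires the falling-flank exponent h_hi to "
                f"exceed the rising-flank exponent h_lo (got {self.h_hi} <= {self.h_lo})"
            )


@dataclass(frozen=True)
class CellCycleParams:
    """Cell growth and division parameters of the growing-root model.

    K_growth : elongation rate during the growth phase (length/tu)
    r_min    : minimal size allowing division (length)
    r0       : daughter birth size (length), 0 < r0 < r_min
    """

    K_growth: float
    r_min: float
    r0: float
    gp_shape: GrowthPhaseShape = field(default_factory=GrowthPhaseShape)
    ip_shape: IdlePhaseShape = field(default_factory=IdlePhaseShape)

    def __post_init__(self) -> None:
        if self.K_growth < 0:  # zero = frozen file, the fixed-model limit
            raise ValueError(f"K_growth must be nonnegative, got {self.K_growth}")
        _positive("r_min", self.r_min)
        _positive("r0", self.r0)
        if not self.r0 < self.r_min:
            raise ValueError(
                f"daughter birth size r0={self.r0} must be below the minimal "
                f"division size r_min={self.r_min}"
            )


@dataclass(frozen=True)
class FluxSchedule:
    """Linearly ramped auxin influx alpha(t) = alpha0 + k*t (cu/tu)."""

    alpha0: float
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be nonnegative, got {self.alpha0}")

    def __call__(self, t: float) -> float:
        value = self.alpha0 + self.k * t
        if value < 0:
            raise ValueError(f"flux schedule became negative at t={t}: {value}")
        return value


@dataclass(frozen=True)
class ParameterSet:
    """A complete named parameterization of all model layers."""

    name: str
    auxin: AuxinTransportParams
    division_factor: DivisionFactorParams
    cell_cycle: CellCycleParams

    @classmethod
    def from_dict(cls, data: dict[str, Any], name: str = "custom") -> "ParameterSet":
        gp = GrowthPhaseShape(**data["cell_cycle"].pop("gp_shape", {}))
        ip = IdlePhaseShape(**data["cell_cycle"].pop("ip_shape", {}))
        return cls(
            name=data.get("name", name),
            auxin=AuxinTransportParams(**data["auxin"]),
            division_factor=DivisionFactorParams(**data["division_factor"]),
            cell_cycle=CellCycleParams(gp_shape=gp, ip_shape=ip, **data["cell_cycle"]),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _lookup(data: dict[str, Any], dotted: str) -> float:
    section, key = dotted.split(".")
    return float(data[section][key])


def available_presets() -> list[str]:
    files = resources.files("reflectedflow") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in files.iterdir() if p.name.endswith(".yaml"))


def load_reference_profile(name: str = "dr5_profile_synthetic") -> "np.ndarray":
    """Load a bundled digitized staining profile as an (n, 2) array of
    (position, intensity).  The bundled default is a synthetic densitometry
    emulation (see its header), not measured data."""
    import numpy as np

    path = resources.files("reflectedflow") / "presets" / f"{name}.csv"
    rows = [
        tuple(float(v) for v in line.split(","))
        for line in path.read_text().splitlines()
        if line and not line.startswith("#")
    ]
    return np.asarray(rows)


def load_preset(name: str) -> ParameterSet:
    """Load a bundled parameter set (``basic`` or ``robust``) or a YAML path.

    Bundled presets are checked against their anchor values at load time and
    loading fails loudly on any mismatch.
    """
    path = resources.files("reflectedflow") / "presets" / f"{name}.yaml"
    if path.is_file():
        raw = yaml.safe_load(path.read_text())
        anchors = _PRESET_ANCHORS.get(name, {})
        for dotted, expected in anchors.items():
            got = _lookup(raw, dotted)
            if got != expected:
                raise ValueError(
                    f"preset {name!r} anchor mismatch: {dotted} = {got}, expected {expected}"
                )
        return ParameterSet.from_dict(raw, name=name)
    # fall back to treating the argument as a filesystem path
    with open(name) as fh:
        raw = yaml.safe_load(fh)
    return ParameterSet.from_dict(raw, name=raw.get("name", name))
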