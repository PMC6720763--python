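"""Standard-gas generation math: bubbler, permeation tubes, stream mixing.

A dynamic gas-mixture generator delivers odorant vapor either by bubbling
carrier air through the liquid (saturation at the bath temperature) or from
gravimetrically calibrated permeation tubes, then mixes and dilutes streams
to hit target concentrations.  Units follow the generator conventions:
volumetric flows in mL/s, evaporated mass flow in mg/s, permeation rates in
ng/s, vapor density in ng/nL, concentrations in ppm (v/v).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .psychophysics import OdorantProfile, concentration_for_oi

__all__ = [
    "GAS_CONSTANT",
    "MOLAR_VOLUME_20C",
    "STANDARD_PRESSURE",
    "BubblerSettings",
    "PermeationSettings",
    "StreamSpec",
    "MixturePlan",
    "bubbler_mass_flow",
    "bubbler_concentration",
    "saturation_concentration",
    "permeation_concentration",
    "vapor_density",
    "mix_streams",
    "plan_mixture",
]

#: J/(mol K)
GAS_CONSTANT = 8.314

#: Molar volume of an ideal gas at 20 °C and 1 atm, L/mol — the constant
#: conventionally hard-coded in the ppm conversion.  ``strict`` modes
#: recompute R·T/p_atm instead.
MOLAR_VOLUME_20C = 24.04

#: Pa
STANDARD_PRESSURE = 101325.0


@dataclass(frozen=True)
class BubblerSettings:
    """Operating point of one bubbling vial."""

    vapor_pressure: float   # Pa at the bath temperature
    molar_mass: float       # g/mol
    flow: float             # carrier flow, mL/s
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        for name in ("vapor_pressure", "molar_mass", "flow", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PermeationSettings:
    """Operating point of one permeation tube."""

    permeation_rate: float  # ng/s
    vapor_density: float    # ng/nL at working temperature
    flow: float             # carrier flow, mL/s

    def __post_init__(self) -> None:
        for name in ("permeation_rate", "vapor_density", "flow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class StreamSpec:
    """One gas stream: flow (mL/s) and per-odorant concentrations (ppm).

    ``concentrations`` maps odorant name -> ppm; pure dilution air is a
    stream with an empty map.
    """

    flow: float
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise ValueError("flow must be >= 0")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")


def bubbler_mass_flow(s: BubblerSettings) -> float:
    """Evaporated mass flow W = P0·M·V̇ / (10³·R·T), in mg/s.

    Assumes the carrier leaves the vial saturated at the bath temperature.
    """
    return (s.vapor_pressure * s.molar_mass * s.flow
            / (1.0e3 * GAS_CONSTANT * s.temperature))


def bubbler_concentration(w: float, flow: float, molar_mass: float) -> float:
    """Concentration c = 24.04·W / (10⁻⁶·V̇·M), in ppm.

    ``w`` in mg/s, ``flow`` in mL/s, ``molar_mass`` in g/mol.  24.04 L/mol
    is the molar volume at 20 °C.
    """
    if min(w, flow, molar_mass) <= 0:
        raise ValueError("w, flow and molar_mass must be > 0")
    return MOLAR_VOLUME_20C * w / (1.0e-6 * flow * molar_mass)


def saturation_concentration(vapor_pressure: float, temperature: float = 293.15,
                             strict: bool = False) -> float:
    """Saturation concentration out of the bubbler, ppm.

    Composing the mass-flow and ppm formulas, flow and molar mass cancel:
    c = 24.04·10³·P0/(R·T).  With ``strict=True`` the hard-coded molar
    volume is replaced by R·T/p_atm, giving the saturation mole fraction
    10⁶·P0/p_atm exactly.
    """
    if vapor_pressure <= 0 or temperature <= 0:
        raise ValueError("vapor_pressure and temperature must be > 0")
    if strict:
        return 1.0e6 * vapor_pressure / STANDARD_PRESSURE
    return MOLAR_VOLUME_20C * 1.0e3 * vapor_pressure / (GAS_CONSTANT * temperature)


def permeation_concentration(s: PermeationSettings) -> float:
    """Permeation-tube concentration c = E/(ρ·V̇), in ppm.

    E in ng/s, ρ in ng/nL, V̇ in mL/s.
    """
    return s.permeation_rate / (s.vapor_density * s.flow)


def vapor_density(molar_mass: float, molar_volume: float = MOLAR_VOLUME_20C) -> float:
    """Vapor density ρ = M / V_m in ng/nL (numerically g/L)."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    return molar_mass / molar_volume


def mix_streams(streams: Iterable[StreamSpec]) -> StreamSpec:
    """Flow-weighted mixing of gas streams (exact per-odorant mass balance).

    The mixed concentration of each odorant is Σ(V̇ᵢ·cᵢ)/ΣV̇ᵢ.
    """
    streams = list(streams)
    total = sum(s.flow for s in streams)
    if total <= 0:
        raise ValueError("total flow must be > 0")
    mixed: dict[str, float] = {}
    for s in streams:
        for name, c in s.concentrations.items():
            mixed[name] = mixed.get(name, 0.0) + s.flow * c
    return StreamSpec(flow=total,
                      concentrations={k: v / total for k, v in mixed.items()})


@dataclass(frozen=True)
class MixturePlan:
    """Generator settings delivering a binary mixture at target intensities."""

    targets_ppm: dict[str, float]          # per-odorant target concentration
    source_ppm: dict[str, float]           # bubbler saturation concentration
    source_flows: dict[str, float]         # per-odorant source stream, mL/s
    dilution_flow: float                   # clean-air make-up, mL/s
    total_flow: float                      # mL/s
    temperature: float                     # K

    def streams(self) -> list[StreamSpec]:
        out = [StreamSpec(flow=f, concentrations={name: self.source_ppm[name]})
               for name, f in self.source_flows.items()]
        out.append(StreamSpec(flow=self.dilution_flow))
        return out

    def delivered(self) -> StreamSpec:
        return mix_streams(self.streams())


def plan_mixture(profile_a: OdorantProfile, profile_b: OdorantProfile,
                 target_oi_a: float, target_oi_b: float | None = None,
                 total_flow: float = 5.0, temperature: float = 293.15) -> MixturePlan:
    """Plan bubbler/dilution settings for a binary mixture at target OI.

    Target concentrations come from inverting each component's
    Weber–Fechner law; each component is drawn saturated from its bubbler
    and diluted into a common stream of ``total_flow`` mL/s (default 5 mL/s,
    i.e. 300 mL/min).  Raises if a target exceeds the bubbler saturation
    concentration or the source flows exceed the total flow.
    """
    if target_oi_b is None:
        target_oi_b = target_oi_a
    targets, source, flows = {}, {}, {}
    for prof, oi in ((profile_a, target_oi_a), (profile_b, target_oi_b)):
        c_target = concentration_for_oi(prof.wf, oi)
        c_sat = saturation_concentration(prof.vapor_pressure, temperature)
        if c_target > c_sat:
            raise ValueError(
                f"target {c_target:.3g} ppm for {prof.name} exceeds bubbler "
                f"saturation {c_sat:.3g} ppm at {temperature} K")
        targets[prof.name] = c_target
        source[prof.name] = c_sat
        flows[prof.name] = c_target * total_flow / c_sat
    dilution = total_flow - sum(flows.values())
    if dilution < 0:
        raise ValueError("source flows exceed the requested total flow; "
                         "increase total_flow")
    return MixturePlan(targets_ppm=targets, source_ppm=source, source_flows=flows,
                       dilution_flow=dilution, total_flow=total_flow,
                       temperature=temperature)
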