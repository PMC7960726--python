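"""Pump-probe geometry and shock-travel kinematics.

In an X-ray-pump/X-ray-probe experiment on a liquid microjet the pump
pulse strikes the jet and launches a shockwave; after a delay ``dt`` the
probe pulse interrogates a segment displaced ``dx`` upstream (toward the
nozzle).  Because the jet itself advects material downstream at speed
``v``, the *effective* inter-pulse spacing experienced by the probed
material is ``dt + dx/v``.  These helpers convert between delay, offset,
jet speed, equivalent repetition rate and the material-frame distance the
shock travels before it reaches the probed segment.

Units are the ones used at the beamline: nanoseconds, micrometres and
metres per second.  1 um / (1 m/s) = 1000 ns, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ShockGeometry",
    "effective_delay",
    "required_delay",
    "equivalent_rep_rate",
    "shock_travel_distance",
    "attenuation_scale",
    "rep_rate_gain",
]

#: exact conversion: time (ns) for material moving at 1 m/s to cover 1 um
_NS_PER_UM_AT_1_MPS = 1000.0


@dataclass(frozen=True)
class ShockGeometry:
    """Pump-probe arrangement on the jet.

    Parameters
    ----------
    delay_ns:
        Pump-to-probe time delay, ns.  Must be positive.
    offset_um:
        Upstream (toward the nozzle) displacement of the probe focus
        relative to the pump focus, um.  Non-negative.
    jet_speed_mps:
        Jet speed, m/s.  Must be positive.
    """

    delay_ns: float
    offset_um: float
    jet_speed_mps: float

    def __post_init__(self) -> None:
        if not self.delay_ns > 0:
            raise ValueError(f"delay_ns must be > 0, got {self.delay_ns}")
        if self.offset_um < 0:
            raise ValueError(f"offset_um must be >= 0, got {self.offset_um}")
        if not self.jet_speed_mps > 0:
            raise ValueError(
                f"jet_speed_mps must be > 0, got {self.jet_speed_mps}"
            )


def _offset_time_ns(offset_um: float, jet_speed_mps: float) -> float:
    return offset_um / jet_speed_mps * _NS_PER_UM_AT_1_MPS


def effective_delay(g: ShockGeometry) -> float:
    """Effective inter-pulse delay in ns: ``dt + dx/v``.

    This is the time separation that a *non-offset* two-pulse experiment
    would need in order to probe material at the same material-frame
    distance from the pump site.
    """
    return g.delay_ns + _offset_time_ns(g.offset_um, g.jet_speed_mps)


def required_delay(target_rate_mhz: float, offset_um: float, jet_speed_mps: float) -> float:
    """Delay (ns) that emulates a repetition rate with an offset probe.

    Solves ``1/f = dt + dx/v`` for ``dt``.  Raises ``ValueError`` when the
    offset alone already exceeds the pulse spacing, i.e. the geometry
    cannot emulate the requested rate.
    """
    if not target_rate_mhz > 0:
        raise ValueError(f"target_rate_mhz must be > 0, got {target_rate_mhz}")
    spacing_ns = 1e3 / target_rate_mhz  # 1/MHz = us = 1000 ns
    dt = spacing_ns - _offset_time_ns(offset_um, jet_speed_mps)
    if dt <= 0:
        raise ValueError(
            "offset travel time exceeds the pulse spacing: geometry cannot "
            f"emulate {target_rate_mhz} MHz (spacing {spacing_ns:.3f} ns)"
        )
    return dt


def equivalent_rep_rate(g: ShockGeometry) -> float:
    """Repetition rate (MHz) whose pulse spacing equals the effective delay."""
    return 1e3 / effective_delay(g)


def shock_travel_distance(g: ShockGeometry) -> float:
    """Material-frame distance (um) between pump site and probed segment.

    The probed material sits ``dx`` upstream at pump time and is carried
    ``v * dt`` further by the jet before the probe arrives, so the shock
    must cover ``v * dt + dx``.
    """
    return g.jet_speed_mps * g.delay_ns / _NS_PER_UM_AT_1_MPS + g.offset_um


def attenuation_scale(
    d_um: float, exponent: float, d_ref_um: float, p_ref: float = 1.0
) -> float:
    """Phenomenological power-law shock attenuation ``p_ref*(d/d_ref)**-n``.

    The exponent is a required user parameter; no value is asserted as
    physical.  Useful only for relative what-if comparisons of travel
    distances.
    """
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    if not (d_um > 0 and d_ref_um > 0):
        raise ValueError("distances must be positive")
    return p_ref * (d_um / d_ref_um) ** (-exponent)


def rep_rate_gain(pulses_per_second: float, baseline_hz: float) -> float:
    """Factor by which a pulse budget exceeds a baseline source rate."""
    if not (pulses_per_second > 0 and baseline_hz > 0):
        raise ValueError("rates must be positive")
    return pulses_per_second / baseline_hz
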