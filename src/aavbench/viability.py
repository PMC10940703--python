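"""Liver-graft viability scoring on normothermic machine perfusion.

Scores a perfusion measurement panel against the transplant-viability
criteria used clinically for ex situ normothermic perfusion: the primary
gate is perfusate lactate <= 2.5 mmol/L, and at least two of the secondary
criteria must hold — bile production, pH >= 7.30, glucose metabolism,
hepatic arterial flow >= 150 mL/min, portal vein flow >= 500 mL/min, or
homogeneous perfusion on inspection. Boundary values satisfy their criteria;
optional measurements that were not recorded count as not satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ViabilityPanel", "ViabilityVerdict", "ViabilityError",
           "assess_viability"]

LACTATE_MAX_MMOL_L = 2.5
PH_MIN = 7.30
HA_FLOW_MIN_ML_MIN = 150.0
PV_FLOW_MIN_ML_MIN = 500.0


class ViabilityError(ValueError):
    pass


@dataclass(frozen=True)
class ViabilityPanel:
    """One timepoint's perfusion measurements; None = not recorded."""

    lactate: float  # mmol/L, required
    ph: float | None = None
    bile_production: bool | None = None
    glucose_metabolism: bool | None = None
    ha_flow: float | None = None  # mL/min
    pv_flow: float | None = None  # mL/min
    homogeneous_perfusion: bool | None = None

    def __post_init__(self) -> None:
        if self.lactate is None:
            raise ViabilityError("lactate is required")
        if self.lactate < 0:
            raise ViabilityError("lactate must be >= 0")
        for flow in (self.ha_flow, self.pv_flow):
            if flow is not None and flow < 0:
                raise ViabilityError("flows must be >= 0")


@dataclass(frozen=True)
class ViabilityVerdict:
    viable: bool
    lactate_ok: bool
    satisfied_secondary: tuple[str, ...]


def assess_viability(panel: ViabilityPanel) -> ViabilityVerdict:
    """Viable iff lactate <= 2.5 mmol/L and >= 2 secondary criteria hold."""
    lactate_ok = panel.lactate <= LACTATE_MAX_MMOL_L
    secondary = {
        "bile_production": bool(panel.bile_production),
        "ph": panel.ph is not None and panel.ph >= PH_MIN,
        "glucose_metabolism": bool(panel.glucose_metabolism),
        "ha_flow": panel.ha_flow is not None and panel.ha_flow >= HA_FLOW_MIN_ML_MIN,
        "pv_flow": panel.pv_flow is not None and panel.pv_flow >= PV_FLOW_MIN_ML_MIN,
        "homogeneous_perfusion": bool(panel.homogeneous_perfusion),
    }
    satisfied = tuple(name for name, ok in secondary.items() if ok)
    return ViabilityVerdict(
        viable=lactate_ok and len(satisfied) >= 2,
        lactate_ok=lactate_ok,
        satisfied_secondary=satisfied,
    )
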