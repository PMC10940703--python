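"""ddPCR quantification, perfusate clearance kinetics, and dose arithmetic.

Total vector load in the perfusate is anchored by droplet digital PCR: with
``n_total`` droplets of volume ``v`` and ``n_positive`` positives, the Poisson
estimate of the mean copies per droplet is lambda = -ln(1 - n_pos/n_tot) and
the concentration is lambda / v times the dilution factor. NGS fractions then
demultiplex the total concentration into per-variant curves C_i(t), expressed
as percent-of-initial q_i(t); variants are binned into persistence classes by
where q lands after the initial clearance. A single-exponential-plus-plateau
fit, C(t) = C0 * ((1 - pi) * exp(-k t) + pi), summarizes each variant's
clearance rate. Dose arithmetic (vg per kg liver/body, per capsid, initial
perfusate concentration) lives here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition import CompositionProfile

__all__ = [
    "DdPCRWell",
    "PerfusateSeries",
    "DoseContext",
    "VcnResult",
    "KineticsError",
    "ddpcr_concentration",
    "demux_concentration",
    "classify_persistence",
    "fit_clearance_rate",
    "dose_report",
    "vector_copy_number",
    "PERSISTENCE_THRESHOLDS",
]

#: Default droplet volume in uL (vendor-standard droplet generator).
DEFAULT_DROPLET_VOLUME_UL = 0.00085

#: Percent-of-initial thresholds (closed lower bounds): persistent >= 10,
#: intermediate >= 0.1, fast-cleared >= 0.01, else neutralized-cleared.
PERSISTENCE_THRESHOLDS = {"persistent": 10.0, "intermediate": 0.1,
                          "fast-cleared": 0.01}


class KineticsError(ValueError):
    """Contract violation in the kinetics/dosimetry stage."""


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdPCRWell:
    n_total: int
    n_positive: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL  # uL
    dilution_factor: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise KineticsError(
                f"{self.sample_id}: n_positive must lie in [0, n_total]"
            )
        if self.droplet_volume <= 0:
            raise KineticsError("droplet_volume must be > 0")


def ddpcr_concentration(well: DdPCRWell) -> float:
    """Poisson concentration estimate in copies/uL of the undiluted sample."""
    if well.n_total == 0:
        raise KineticsError(f"{well.sample_id}: empty well (no droplets)")
    if well.n_positive == well.n_total:
        raise KineticsError(
            f"{well.sample_id}: all droplets positive (saturated); dilute and rerun"
        )
    lam = -math.log((well.n_total - well.n_positive) / well.n_total)
    return lam / well.droplet_volume * well.dilution_factor


@dataclass(frozen=True)
class VcnResult:
    transgene_conc: float
    reference_conc: float

    @property
    def vcn(self) -> float:
        return self.transgene_conc / self.reference_conc


def vector_copy_number(transgene: DdPCRWell, reference: DdPCRWell) -> VcnResult:
    """Vector genomes per haploid cell from paired transgene/reference assays.

    The reference assay detects one copy per haploid genome, so the ratio of
    the two concentrations is the vector copy number directly.
    """
    t = ddpcr_concentration(transgene)
    r = ddpcr_concentration(reference)
    if r == 0:
        raise KineticsError("reference concentration is 0; VCN undefined")
    return VcnResult(transgene_conc=t, reference_conc=r)


# ---------------------------------------------------------------------------
# Perfusate clearance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerfusateSeries:
    """Timepoints (hours) with total vg/mL and per-timepoint NGS fractions."""

    timepoints: tuple[float, ...]
    total_conc: tuple[float, ...]
    variant_fraction: tuple[CompositionProfile, ...]
    initial_total: float
    input_mix: CompositionProfile | None = None

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.total_conc) or \
                len(self.timepoints) != len(self.variant_fraction):
            raise KineticsError("timepoints/concentrations/fractions misaligned")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise KineticsError("timepoints must be strictly increasing")
        if any(c < 0 for c in self.total_conc):
            raise KineticsError("concentrations must be >= 0")


def demux_concentration(series: PerfusateSeries) -> tuple[
        dict[str, list[float]], dict[str, list[float]]]:
    """Per-variant concentrations C_i(t) and percent-of-initial q_i(t).

    C_i(t) = C_tot(t) * f_i(t); the per-variant baseline C_i(0) is the
    initial total concentration split by the pre-injection mix shares, so
    q_i(0) = 100 for every variant when the t=0 fractions equal the mix.
    """
    if series.input_mix is None:
        raise KineticsError("series lacks the pre-injection input mix profile")
    if series.initial_total <= 0:
        raise KineticsError("initial_total must be > 0")
    variants = series.input_mix.variants
    conc: dict[str, list[float]] = {name: [] for name in variants}
    pct: dict[str, list[float]] = {name: [] for name in variants}
    for c_tot, prof in zip(series.total_conc, series.variant_fraction):
        for name in variants:
            c_i = c_tot * prof.fractions[name]
            c0_i = series.initial_total * series.input_mix.fractions[name]
            conc[name].append(c_i)
            pct[name].append(100.0 * c_i / c0_i if c0_i > 0 else 0.0)
    return conc, pct


def classify_persistence(q: float,
                         thresholds: Mapping[str, float] = PERSISTENCE_THRESHOLDS
                         ) -> str:
    """Persistence class of a percent-of-initial value at the stated day.

    Closed lower bounds: a value exactly on a threshold belongs to the upper
    class.
    """
    if q < 0:
        raise KineticsError("percent-of-initial must be >= 0")
    if q >= thresholds["persistent"]:
        return "persistent"
    if q >= thresholds["intermediate"]:
        return "intermediate"
    if q >= thresholds["fast-cleared"]:
        return "fast-cleared"
    return "neutralized-cleared"


def fit_clearance_rate(timepoints: Sequence[float], conc: Sequence[float],
                       estimate_plateau: bool = True,
                       signal_floor_frac: float = 0.05) -> tuple[float, float]:
    """Fit C(t) = C0 * ((1 - pi) e^{-k t} + pi); returns (k per hour, pi).

    The plateau level is estimated as the mean of the last two concentrations
    (0 when ``estimate_plateau`` is False) and subtracted before a log-linear
    least-squares fit. Points whose plateau-subtracted residual falls below
    ``signal_floor_frac`` of the initial residual are excluded from the fit:
    once the curve is within noise of the plateau the log residual is
    dominated by measurement error and would bias the slope.
    """
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(conc, dtype=float)
    if len(t) < 3:
        raise KineticsError("clearance fit needs >= 3 timepoints")
    if np.any(c <= 0):
        raise KineticsError("clearance fit requires positive concentrations")
    plateau_level = float(np.mean(c[-2:])) if estimate_plateau else 0.0
    resid = c - plateau_level
    if resid[0] <= 0:
        raise KineticsError("no decaying signal above the plateau estimate")
    keep = resid >= signal_floor_frac * resid[0]
    if keep.sum() < 2:
        keep = resid > 0
        if keep.sum() < 2:
            raise KineticsError("too few points above the plateau to fit")
    slope, _intercept = np.polyfit(t[keep], np.log(resid[keep]), 1)
    k = max(0.0, -float(slope))
    pi = plateau_level / float(c[0])
    return k, pi


# ---------------------------------------------------------------------------
# Dose arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseContext:
    """Everything needed for the dose report of one perfusion."""

    total_vg: float
    liver_mass: float  # kg, whole organ
    graft_mass: float | None = None  # kg, when only a partial graft is dosed
    body_mass: float | None = None  # kg
    n_variants: int = 14
    perfusate_volume: float = 2.0  # L

    def __post_init__(self) -> None:
        if self.total_vg <= 0 or self.liver_mass <= 0 or self.perfusate_volume <= 0:
            raise KineticsError("doses, masses and volumes must be > 0")
        if self.n_variants < 1:
            raise KineticsError("n_variants must be >= 1")


def dose_report(ctx: DoseContext) -> dict[str, float]:
    """Derived doses: per kg liver/body, per capsid, initial perfusate vg/mL."""
    mass = ctx.graft_mass if ctx.graft_mass is not None else ctx.liver_mass
    report = {
        "total_vg": ctx.total_vg,
        "per_kg_liver": ctx.total_vg / mass,
        "per_variant_per_kg_liver": ctx.total_vg / mass / ctx.n_variants,
        "initial_perfusate_conc_vg_per_ml": ctx.total_vg / (ctx.perfusate_volume * 1000.0),
        "perfusate_volume_l": ctx.perfusate_volume,
    }
    if ctx.body_mass is not None:
        report["per_kg_body"] = ctx.total_vg / ctx.body_mass
        report["per_variant_per_kg_body"] = ctx.total_vg / ctx.body_mass / ctx.n_variants
    return report
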