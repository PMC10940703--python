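"""Anti-AAV serology: ELISA reactivity and end titers, NAb titers, correlation.

A serum dilution is called reactive against a capsid when the mean absorbance
of coated (foreground) wells exceeds twice the mean of uncoated (background)
wells — strictly greater than 2.0, so a ratio of exactly 2.0 is non-reactive.
The end titer is the greatest dilution still reactive; a serum reactive at no
dilution is reported below detection ("<1:25" for the standard 25/50/100
series). Neutralizing-antibody titers come from a transduction-inhibition
assay: the NAb titer is the greatest serum dilution at which reporter signal
is reduced to 50% or less of the no-serum positive control.

Reactivity is rank-encoded (<1:25 -> 0, 1:25 -> 1, 1:50 -> 2, 1:100 -> 3) so
it can be rank-correlated with perfusate clearance (Spearman, implemented
here with average ranks, exact permutation p-values at small n and the
t-approximation otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ElisaAssay",
    "TiterResult",
    "NabAssay",
    "SerologyError",
    "elisa_reactive",
    "end_titer",
    "nab_titer",
    "spearman",
    "reactivity_score",
    "load_elisa_table",
    "REACTIVITY_RATIO_THRESHOLD",
]

REACTIVITY_RATIO_THRESHOLD = 2.0


class SerologyError(ValueError):
    """Contract violation or invalid assay in the serology stage."""


@dataclass(frozen=True)
class ElisaAssay:
    """One capsid's dilution series of 450 nm absorbances plus background."""

    capsid: str
    dilutions: tuple[int, ...]  # e.g. (25, 50, 100), ascending
    foreground_od: Mapping[int, tuple[float, ...]]  # dilution -> replicates
    background_od: tuple[float, ...]  # uncoated wells

    def __post_init__(self) -> None:
        if not self.dilutions:
            raise SerologyError("empty dilution list")
        if any(b <= a for a, b in zip(self.dilutions, self.dilutions[1:])):
            raise SerologyError("dilutions must be strictly increasing")
        for d in self.dilutions:
            if d not in self.foreground_od or not self.foreground_od[d]:
                raise SerologyError(f"no foreground replicates at 1:{d}")
        if not self.background_od:
            raise SerologyError("no background replicates")
        for values in list(self.foreground_od.values()) + [self.background_od]:
            if any(v < 0 for v in values):
                raise SerologyError("absorbances must be >= 0")


@dataclass(frozen=True)
class TiterResult:
    capsid: str
    reactive_at: Mapping[int, bool]
    ratios: Mapping[int, float]
    end_titer: int | None  # None = below detection at the smallest dilution
    below_detection_label: str = ""
    non_monotone: bool = False

    @property
    def label(self) -> str:
        if self.end_titer is None:
            return self.below_detection_label
        return f"1:{self.end_titer}"


def elisa_reactive(foreground_od: Sequence[float],
                   background_od: Sequence[float],
                   threshold: float = REACTIVITY_RATIO_THRESHOLD
                   ) -> tuple[bool, float]:
    """Reactivity call for one dilution: (reactive, foreground/background ratio).

    Reactive iff the ratio is strictly greater than the threshold (2.0).
    """
    bg = float(np.mean(background_od))
    if bg <= 0:
        raise SerologyError("background mean is 0; assay invalid")
    ratio = float(np.mean(foreground_od)) / bg
    return ratio > threshold, ratio


def end_titer(assay: ElisaAssay,
              threshold: float = REACTIVITY_RATIO_THRESHOLD) -> TiterResult:
    """Greatest reactive dilution; below-detection marker when none reactive.

    A non-monotone call pattern (reactive at a higher dilution but not a
    lower one) is physically implausible, so it is flagged but still resolved
    by taking the greatest reactive dilution.
    """
    calls: dict[int, bool] = {}
    ratios: dict[int, float] = {}
    for d in assay.dilutions:
        reactive, ratio = elisa_reactive(assay.foreground_od[d],
                                         assay.background_od, threshold)
        calls[d] = reactive
        ratios[d] = ratio
    reactive_dils = [d for d in assay.dilutions if calls[d]]
    flags = [calls[d] for d in assay.dilutions]
    # monotone non-increasing means no False before a later True
    non_monotone = any(
        not flags[i] and any(flags[i + 1:]) for i in range(len(flags))
    )
    if reactive_dils:
        return TiterResult(capsid=assay.capsid, reactive_at=calls, ratios=ratios,
                           end_titer=max(reactive_dils),
                           non_monotone=non_monotone)
    return TiterResult(capsid=assay.capsid, reactive_at=calls, ratios=ratios,
                       end_titer=None,
                       below_detection_label=f"<1:{assay.dilutions[0]}",
                       non_monotone=False)


def reactivity_score(titer: TiterResult,
                     dilutions: Sequence[int] = (25, 50, 100)) -> int:
    """Ordinal encoding of an end titer: <1:25 -> 0, 1:25 -> 1, 1:50 -> 2, ..."""
    if titer.end_titer is None:
        return 0
    return list(dilutions).index(titer.end_titer) + 1


@dataclass(frozen=True)
class NabAssay:
    """Transduction-inhibition series: reporter luminescence per dilution."""

    dilutions: tuple[int, ...]
    luminescence: Mapping[int, tuple[float, ...]]
    positive_control: float  # no-serum transduction signal
    negative_control: float = 0.0  # untransduced background

    def __post_init__(self) -> None:
        if self.positive_control <= self.negative_control:
            raise SerologyError(
                "positive control does not exceed negative control; assay invalid"
            )


def nab_titer(assay: NabAssay) -> int | None:
    """NAb titer: greatest dilution with signal <= 50% of the positive control.

    Returns None for a NAb-negative serum (no dilution reaches 50%
    inhibition). A normalized signal of exactly 0.5 counts as inhibited.
    """
    inhibited = []
    for d in assay.dilutions:
        normalized = float(np.mean(assay.luminescence[d])) / assay.positive_control
        if normalized <= 0.5:
            inhibited.append(d)
    return max(inhibited) if inhibited else None


def load_elisa_table(path) -> dict[str, ElisaAssay]:
    """Read a plate CSV (capsid, dilution, foreground_od, background_od rows,
    one per replicate) into per-capsid assays."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"capsid", "dilution", "foreground_od", "background_od"}
    if not required.issubset(df.columns):
        raise SerologyError(f"plate table needs columns {sorted(required)}")
    assays: dict[str, ElisaAssay] = {}
    for capsid, grp in df.groupby("capsid", sort=False):
        dilutions = tuple(sorted(grp["dilution"].unique()))
        foreground = {
            int(d): tuple(grp.loc[grp["dilution"] == d, "foreground_od"])
            for d in dilutions
        }
        background = tuple(grp.drop_duplicates(
            subset=["dilution", "background_od"])["background_od"].unique())
        assays[str(capsid)] = ElisaAssay(
            capsid=str(capsid), dilutions=tuple(int(d) for d in dilutions),
            foreground_od=foreground, background_od=background)
    return assays


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def _average_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing the average of their rank block."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise SerologyError("constant vector: correlation undefined")
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = 8) -> tuple[float, float, str]:
    """Spearman rho with tie-aware average ranks; returns (rho, p, method).

    The two-sided p-value is an exact permutation probability
    P(|rho_perm| >= |rho_obs|) for n <= ``exact_max_n`` and the usual
    t-approximation with n-2 degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise SerologyError("spearman needs two equal-length vectors, n >= 3")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rho = _rho_of_ranks(rx, ry)
    n = len(x)
    if n <= exact_max_n:
        count = 0
        total = 0
        obs = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _rho_of_ranks(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs:
                count += 1
        return rho, count / total, "exact-permutation"
    if abs(rho) >= 1.0:
        return rho, 0.0, "t-approximation"
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p), "t-approximation"
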