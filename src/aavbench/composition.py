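"""Composition profiles, input-mix normalization, bias screening, clustering.

Raw barcode counts say little on their own because the injected vector pool is
never perfectly equimolar: every sample is therefore expressed relative to the
pre-injection mix. For a sample with count fractions f_i and a mix with
fractions m_i, the enrichment ratios r_i = f_i / m_i are renormalized to
percentages p_i = 100 * r_i / sum_j r_j, which is what the transduction
heatmaps plot. cDNA/DNA percentage ratios give a per-variant expression
efficiency (uptake vs functional transduction), and average-linkage
hierarchical clustering on the percentage profiles groups capsids with
similar behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .demux import BarcodeCountTable

__all__ = [
    "Analyte",
    "CompositionProfile",
    "EfficiencyProfile",
    "LinkageTree",
    "CompositionError",
    "fractions",
    "normalize_to_input",
    "expression_efficiency",
    "screen_barcode_bias",
    "cluster_profiles",
]

#: Allowed analyte labels; DNA = vector uptake, cDNA = transgene expression.
Analyte = str
ANALYTES = ("DNA", "cDNA", "perfusate", "input")


class CompositionError(ValueError):
    """Contract violation in composition handling."""


@dataclass(frozen=True)
class CompositionProfile:
    """Per-variant fractions, optionally normalized to the pre-injection mix."""

    sample_id: str
    analyte: Analyte
    fractions: Mapping[str, float]
    normalized_pct: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise CompositionError(f"unknown analyte {self.analyte!r}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(
                f"fractions of {self.sample_id} sum to {total!r}, not 1"
            )
        if self.normalized_pct is not None:
            ptot = sum(self.normalized_pct.values())
            if abs(ptot - 100.0) > 1e-6:
                raise CompositionError(
                    f"normalized percentages of {self.sample_id} sum to {ptot!r}"
                )

    @property
    def variants(self) -> list[str]:
        return list(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        data = {"fraction": pd.Series(dict(self.fractions))}
        if self.normalized_pct is not None:
            data["normalized_pct"] = pd.Series(dict(self.normalized_pct))
        df = pd.DataFrame(data)
        df.index.name = "variant"
        return df


@dataclass(frozen=True)
class EfficiencyProfile:
    """cDNA%/DNA% ratio per variant; zero-DNA variants are flagged undefined."""

    ratios: Mapping[str, float]
    undefined: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, value in self.ratios.items():
            if value < 0:
                raise CompositionError(f"negative efficiency for {name}")


def fractions(table: BarcodeCountTable, pseudocount: float = 0.0,
              analyte: Analyte = "DNA") -> CompositionProfile:
    """Counts to fractions: f_i = (c_i + pseudocount) / sum_j (c_j + pseudocount).

    The default pseudocount of 0 keeps genuinely undetected variants at
    exactly zero, which matters for capsids fully neutralized out of a
    sample.
    """
    counts = table.counts
    denom = sum(counts.values()) + pseudocount * len(counts)
    if denom <= 0:
        raise CompositionError(
            f"all-zero counts for {table.sample_id} with pseudocount 0"
        )
    fracs = {name: (c + pseudocount) / denom for name, c in counts.items()}
    return CompositionProfile(sample_id=table.sample_id, analyte=analyte,
                              fractions=fracs)


def normalize_to_input(sample: CompositionProfile,
                       input_mix: CompositionProfile) -> CompositionProfile:
    """Normalize a sample to the pre-injection mix and renormalize to 100%."""
    if set(sample.fractions) != set(input_mix.fractions):
        raise CompositionError("sample and input mix cover different variants")
    ratios = {}
    for name, f in sample.fractions.items():
        m = input_mix.fractions[name]
        if m <= 0:
            if f > 0:
                raise CompositionError(
                    f"variant {name} has reads but zero share in the input mix"
                )
            ratios[name] = 0.0
        else:
            ratios[name] = f / m
    total = sum(ratios.values())
    if total <= 0:
        raise CompositionError("all enrichment ratios are zero")
    pct = {name: 100.0 * r / total for name, r in ratios.items()}
    return CompositionProfile(sample_id=sample.sample_id, analyte=sample.analyte,
                              fractions=sample.fractions, normalized_pct=pct)


def expression_efficiency(dna: CompositionProfile,
                          cdna: CompositionProfile) -> EfficiencyProfile:
    """Per-variant cDNA%/DNA% ratio; ~1 means expression mirrors uptake."""
    if dna.analyte != "DNA" or cdna.analyte != "cDNA":
        raise CompositionError(
            f"expected DNA and cDNA profiles, got {dna.analyte}/{cdna.analyte}"
        )
    if dna.normalized_pct is None or cdna.normalized_pct is None:
        raise CompositionError("profiles must be normalized to the input mix first")
    if set(dna.normalized_pct) != set(cdna.normalized_pct):
        raise CompositionError("DNA and cDNA profiles cover different variants")
    ratios: dict[str, float] = {}
    undefined: set[str] = set()
    for name, p_dna in dna.normalized_pct.items():
        p_cdna = cdna.normalized_pct[name]
        if p_dna == 0:
            undefined.add(name)
        else:
            ratios[name] = p_cdna / p_dna
    return EfficiencyProfile(ratios=ratios, undefined=frozenset(undefined))


def screen_barcode_bias(replicate_profiles: Sequence[CompositionProfile],
                        fold_threshold: float = 2.0) -> tuple[set[str], set[str]]:
    """Discard barcodes over/under-expressed relative to the panel mean.

    For each replicate, a barcode's fold value is its share divided by the
    mean share across barcodes in that replicate; fold values are averaged
    across replicates and barcodes with mean fold > ``fold_threshold`` or
    < 1/``fold_threshold`` are discarded. Returns (kept, discarded).
    """
    if len(replicate_profiles) < 2:
        raise CompositionError("bias screening needs >= 2 replicate profiles")
    if fold_threshold <= 1:
        raise CompositionError("fold_threshold must be > 1")
    variants = replicate_profiles[0].variants
    for prof in replicate_profiles[1:]:
        if set(prof.variants) != set(variants):
            raise CompositionError("replicates cover different variants")
    folds = {name: [] for name in variants}
    for prof in replicate_profiles:
        values = prof.normalized_pct if prof.normalized_pct is not None else prof.fractions
        mean = np.mean([values[n] for n in variants])
        for name in variants:
            folds[name].append(values[name] / mean)
    kept, discarded = set(), set()
    for name, fs in folds.items():
        e = float(np.mean(fs))
        if e > fold_threshold or e < 1.0 / fold_threshold:
            discarded.add(name)
        else:
            kept.add(name)
    return kept, discarded


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative clustering result: ordered merges over variant leaves.

    ``merges`` lists n-1 tuples (cluster_a, cluster_b, height) using scipy's
    cluster numbering (leaves 0..n-1 in ``labels`` order, internal nodes
    n, n+1, ...); heights are non-decreasing for average linkage.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    linkage_matrix: np.ndarray = field(repr=False, compare=False, default=None)
    metadata: Mapping[str, str] = field(
        default_factory=lambda: {"metric": "euclidean", "linkage": "average"}
    )

    def leaf_partitions(self) -> list[frozenset[str]]:
        """Leaf label sets of every internal node, in merge order."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([name]) for i, name in enumerate(self.labels)
        }
        out = []
        nxt = len(self.labels)
        for a, b, _h in self.merges:
            merged = clusters[a] | clusters[b]
            clusters[nxt] = merged
            out.append(merged)
            nxt += 1
        return out

    def to_newick(self) -> str:
        node = hierarchy.to_tree(self.linkage_matrix)

        def fmt(n, parent_dist):
            length = parent_dist - n.dist
            if n.is_leaf():
                return f"{self.labels[n.id]}:{length:.6g}"
            return f"({fmt(n.left, n.dist)},{fmt(n.right, n.dist)}):{length:.6g}"

        return f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)});" \
            if not node.is_leaf() else f"({self.labels[node.id]});"


def cluster_profiles(profiles: pd.DataFrame | Mapping[str, Mapping[str, float]],
                     linkage: str = "average") -> LinkageTree:
    """Cluster variants by their percentage profiles across samples.

    ``profiles`` is a variants x samples table of normalized percentages
    (missing values imputed as 0). Euclidean distance, average linkage,
    deterministic tie-break by lexicographic variant order.
    """
    df = pd.DataFrame(profiles) if not isinstance(profiles, pd.DataFrame) else profiles
    df = df.sort_index().fillna(0.0)
    if len(df) < 2:
        raise CompositionError("clustering needs >= 2 variants")
    Z = hierarchy.linkage(df.to_numpy(dtype=float), method=linkage,
                          metric="euclidean")
    merges = tuple(
        (int(row[0]), int(row[1]), float(row[2])) for row in Z
    )
    return LinkageTree(labels=tuple(df.index), merges=merges, linkage_matrix=Z,
                       metadata={"metric": "euclidean", "linkage": linkage})
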