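"""Synthetic data generators for every stage of the pipeline.

Emulates the statistical structure the analysis assumes so that each stage
can be exercised, and its parameter recovery measured, without external
sequencing data:

* a barcode library of random 44-mers with an enforced minimum pairwise
  Hamming distance, flanked by the standard amplification anchors;
* paired 2x150 amplicon reads drawn multinomially from the mix fractions,
  with independent per-base substitution errors (indel corruption available
  to exercise the length filter) and plausible Phred qualities;
* per-variant perfusate decay C_i(t) = C_i(0) * ((1-pi_i) e^{-(k_i + beta*rank_i) t} + pi_i),
  i.e. exponential clearance to a persistent plateau whose rate grows with
  the variant's antibody-reactivity rank;
* dilution-series ELISA plates whose foreground/background ratio follows
  1 + A_r / dilution_index, so a capsid of reactivity rank r is reactive at
  exactly its first r dilutions (A_r defaults to r + 0.5);
* Poisson droplet partitioning for ddPCR wells.

All generators are fully determined by their seed / Generator argument.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import CompositionProfile
from .demux import (DEFAULT_DOWNSTREAM_ANCHOR, DEFAULT_UPSTREAM_ANCHOR,
                    BarcodeLibrary, ReadPair, reverse_complement)
from .kinetics import DdPCRWell, PerfusateSeries
from .serology import ElisaAssay

__all__ = [
    "SimulationConfig",
    "SimulatedReads",
    "generate_barcode_library",
    "simulate_reads",
    "simulate_perfusate",
    "simulate_elisa",
    "simulate_droplets",
    "write_paired_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic generators.

    Defaults mirror the reference study design: 14 variants tagged with
    44-mer barcodes, a 1:1 molar mix, 2x150 paired-end reads, and clearance
    curves spanning persistent to rapidly neutralized behaviour.
    """

    seed: int = 0
    n_variants: int = 14
    barcode_length: int = 44
    min_barcode_distance: int = 10
    mix_fractions: tuple[float, ...] | None = None  # None = uniform
    n_reads: int = 100_000
    read_length: int = 150
    amplicon_length: int = 220
    base_error_rate: float = 0.003
    indel_rate: float = 0.0
    reactivity_effect: float = 0.0  # beta: extra clearance per reactivity rank, 1/h
    elisa_background_mean: float = 0.2
    elisa_background_sd: float = 0.01
    ddpcr_n_droplets: int = 20_000
    ddpcr_droplet_volume: float = 0.00085  # uL


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_barcode_library(n_variants: int = 14, barcode_length: int = 44,
                             min_distance: int = 10,
                             amplicon_length: int = 220,
                             length_tolerance: int = 0,
                             seed: int | np.random.Generator = 0,
                             max_attempts: int = 10_000) -> BarcodeLibrary:
    """Random barcodes with enforced minimum pairwise Hamming distance.

    Rejection-samples candidate barcodes until ``n_variants`` mutually
    distant ones are found. Variant names are AAV-BC01, AAV-BC02, ...
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = _rng(seed)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_variants:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_variants} barcodes at distance "
                f">= {min_distance} within {max_attempts} attempts"
            )
        cand = rng.choice(_BASES, size=barcode_length)
        if all(int(np.count_nonzero(cand != prev)) >= min_distance
               for prev in accepted):
            accepted.append(cand)
    entries = {
        f"AAV-BC{i + 1:02d}": arr.tobytes().decode()
        for i, arr in enumerate(accepted)
    }
    return BarcodeLibrary(entries=entries,
                          upstream_anchor=DEFAULT_UPSTREAM_ANCHOR,
                          downstream_anchor=DEFAULT_DOWNSTREAM_ANCHOR,
                          expected_merged_length=amplicon_length,
                          length_tolerance=length_tolerance)


@dataclass(frozen=True)
class SimulatedReads:
    pairs: tuple[ReadPair, ...]
    truth_variants: tuple[str, ...]  # per-read generating variant
    truth_counts: Mapping[str, int]
    n_indel_corrupted: int = 0
    corrupted_ids: frozenset[str] = frozenset()


def _apply_substitutions(mat: np.ndarray, rng: np.random.Generator,
                         rate: float) -> np.ndarray:
    """Independent per-base substitutions to a random *different* base."""
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return mat
    base_idx = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_idx[b] = i
    idx = base_idx[mat[mask]]
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    mat[mask] = _BASES[(idx + shift) % 4]
    return mat


def simulate_reads(lib: BarcodeLibrary, config: SimulationConfig | None = None,
                   seed: int | np.random.Generator | None = None,
                   **overrides) -> SimulatedReads:
    """Paired 2x150 amplicon reads drawn from the mix with sequencing error.

    The amplicon is anchor + barcode + anchor padded with a library-seeded
    constant sequence to ``amplicon_length``, so mates always overlap when
    the amplicon is shorter than twice the read length. The per-read
    generating variant is recorded as ground truth. With ``indel_rate`` > 0
    a read's amplicon suffers a single-base insertion or deletion, changing
    its merged length (and so failing a tolerance-0 length filter).
    """
    cfg = config or SimulationConfig()
    if overrides:
        cfg = SimulationConfig(**{**cfg.__dict__, **overrides})
    rng = _rng(cfg.seed if seed is None else seed)
    names = lib.variants
    n_var = len(names)
    mix = (np.full(n_var, 1.0 / n_var) if cfg.mix_fractions is None
           else np.asarray(cfg.mix_fractions, dtype=float))
    if len(mix) != n_var or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("mix_fractions must match the library and sum to 1")

    core_len = (len(lib.upstream_anchor) + lib.barcode_length
                + len(lib.downstream_anchor))
    amp_len = cfg.amplicon_length
    if amp_len < core_len:
        raise ValueError("amplicon_length shorter than anchors + barcode")
    if amp_len > 2 * cfg.read_length:
        raise ValueError("amplicon longer than 2x read length: mates cannot overlap")
    pad = _random_seq(np.random.default_rng(
        abs(hash(tuple(sorted(lib.entries.items())))) % (2**31)), amp_len - core_len)

    amp_by_var = [
        lib.upstream_anchor + lib.entries[name] + lib.downstream_anchor + pad
        for name in names
    ]
    r1_mat_by_var = np.stack([
        np.frombuffer(a[: cfg.read_length].encode(), dtype=np.uint8)
        for a in amp_by_var
    ])
    r2_mat_by_var = np.stack([
        np.frombuffer(reverse_complement(a)[: cfg.read_length].encode(),
                      dtype=np.uint8)
        for a in amp_by_var
    ])

    assign = rng.choice(n_var, size=cfg.n_reads, p=mix)
    reads1 = r1_mat_by_var[assign].copy()
    reads2 = r2_mat_by_var[assign].copy()
    reads1 = _apply_substitutions(reads1, rng, cfg.base_error_rate)
    reads2 = _apply_substitutions(reads2, rng, cfg.base_error_rate)

    # plausible Phred qualities; they matter only for consensus tie-breaking
    q1 = np.clip(np.rint(rng.normal(36, 3, size=reads1.shape)), 2, 40)
    q2 = np.clip(np.rint(rng.normal(36, 3, size=reads2.shape)), 2, 40)
    q1 = (q1 + 33).astype(np.uint8)
    q2 = (q2 + 33).astype(np.uint8)

    corrupted = (rng.random(cfg.n_reads) < cfg.indel_rate
                 if cfg.indel_rate > 0 else np.zeros(cfg.n_reads, dtype=bool))

    pairs: list[ReadPair] = []
    truth: list[str] = []
    corrupted_ids: set[str] = set()
    L = cfg.read_length
    for i in range(cfg.n_reads):
        rid = f"read{i:07d}"
        name = names[assign[i]]
        s1 = reads1[i].tobytes().decode()
        s2 = reads2[i].tobytes().decode()
        qs1 = q1[i].tobytes().decode()
        qs2 = q2[i].tobytes().decode()
        if corrupted[i]:
            # single-base indel in the amplicon: regenerate mates from the
            # corrupted template so the merged length shifts by one
            amp = amp_by_var[assign[i]]
            pos = int(rng.integers(0, len(amp)))
            if rng.random() < 0.5:
                amp_c = amp[:pos] + amp[pos + 1:]  # deletion
            else:
                ins = "ACGT"[int(rng.integers(0, 4))]
                amp_c = amp[:pos] + ins + amp[pos:]  # insertion
            s1 = amp_c[:L]
            s2 = reverse_complement(amp_c)[:L]
            qs1, qs2 = qs1[: len(s1)], qs2[: len(s2)]
            corrupted_ids.add(rid)
        pairs.append(ReadPair(id=rid, seq1=s1, seq2=s2, qual1=qs1, qual2=qs2))
        truth.append(name)

    counts = {name: 0 for name in names}
    for name in truth:
        counts[name] += 1
    return SimulatedReads(pairs=tuple(pairs), truth_variants=tuple(truth),
                          truth_counts=counts,
                          n_indel_corrupted=int(corrupted.sum()),
                          corrupted_ids=frozenset(corrupted_ids))


def write_paired_fastq(sim: SimulatedReads, r1_path: str | Path,
                       r2_path: str | Path) -> None:
    """Write mates to two FASTQ files (gzip when the path ends in .gz)."""
    def _open(path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for pair in sim.pairs:
            f1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")


# ---------------------------------------------------------------------------
# Perfusate kinetics
# ---------------------------------------------------------------------------

#: Sampling grid dense early (the clearance phase) and extending to one week.
DEFAULT_TIMEPOINTS_H = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0,
                        96.0, 120.0, 144.0, 168.0)


def simulate_perfusate(clearance: Mapping[str, tuple[float, float]],
                       timepoints: Sequence[float] = DEFAULT_TIMEPOINTS_H,
                       initial_total: float = 1.55e9,
                       mix_fractions: Mapping[str, float] | None = None,
                       reactivity: Mapping[str, int] | None = None,
                       reactivity_effect: float = 0.0,
                       noise_sd: float = 0.0,
                       seed: int | np.random.Generator = 0) -> PerfusateSeries:
    """Per-variant exponential decay to a plateau, with optional coupling of
    the decay rate to antibody-reactivity rank and lognormal measurement
    noise.

    ``clearance`` maps variant -> (k per hour, plateau fraction pi). The
    effective rate is k + reactivity_effect * rank. Totals and fractions are
    derived consistently from the per-variant curves, and the noiseless mix
    shares become the series' input-mix profile.
    """
    rng = _rng(seed)
    names = list(clearance)
    t = np.asarray(timepoints, dtype=float)
    if mix_fractions is None:
        mix = {name: 1.0 / len(names) for name in names}
    else:
        mix = {name: float(mix_fractions[name]) for name in names}
    conc = np.zeros((len(names), len(t)))
    for i, name in enumerate(names):
        k, pi = clearance[name]
        if k < 0 or not 0 <= pi <= 1:
            raise ValueError(f"invalid clearance parameters for {name}")
        rank = reactivity[name] if reactivity else 0
        k_eff = k + reactivity_effect * rank
        c0 = initial_total * mix[name]
        conc[i] = c0 * ((1 - pi) * np.exp(-k_eff * t) + pi)
    if noise_sd > 0:
        conc = conc * rng.lognormal(mean=0.0, sigma=noise_sd, size=conc.shape)

    totals = conc.sum(axis=0)
    profiles = []
    for j, tj in enumerate(t):
        fracs = {name: conc[i, j] / totals[j] for i, name in enumerate(names)}
        profiles.append(CompositionProfile(
            sample_id=f"perfusate_t{tj:g}h", analyte="perfusate",
            fractions=fracs))
    input_mix = CompositionProfile(sample_id="input_mix", analyte="input",
                                   fractions=mix)
    return PerfusateSeries(timepoints=tuple(t), total_conc=tuple(totals),
                           variant_fraction=tuple(profiles),
                           initial_total=initial_total, input_mix=input_mix)


# ---------------------------------------------------------------------------
# ELISA and ddPCR
# ---------------------------------------------------------------------------


def simulate_elisa(ranks: Mapping[str, int],
                   dilutions: Sequence[int] = (25, 50, 100),
                   background_mean: float = 0.2,
                   background_sd: float = 0.01,
                   amplitudes: Mapping[int, float] | None = None,
                   n_replicates: int = 2,
                   seed: int | np.random.Generator = 0) -> dict[str, ElisaAssay]:
    """Plates whose foreground/background ratio is 1 + A_rank/dilution_index.

    With the default amplitudes (A_0 = 0, A_r = r + 0.5 for r >= 1), a capsid
    of rank r is reactive (ratio > 2) at exactly its first r dilutions,
    reproducing tiered end titers (<1:25, 1:25, 1:50, 1:100 for ranks 0-3),
    and a rank-0 capsid sits at ratio ~1 everywhere.
    """
    rng = _rng(seed)
    assays: dict[str, ElisaAssay] = {}
    for capsid, rank in ranks.items():
        if amplitudes is not None:
            amp = amplitudes[rank]
        else:
            amp = 0.0 if rank == 0 else rank + 0.5
        foreground: dict[int, tuple[float, ...]] = {}
        for idx, d in enumerate(dilutions, start=1):
            mean = background_mean * (1.0 + amp / idx)
            foreground[d] = tuple(
                max(0.0, float(v))
                for v in rng.normal(mean, background_sd, size=n_replicates)
            )
        background = tuple(
            max(0.0, float(v))
            for v in rng.normal(background_mean, background_sd, size=n_replicates)
        )
        assays[capsid] = ElisaAssay(capsid=capsid, dilutions=tuple(dilutions),
                                    foreground_od=foreground,
                                    background_od=background)
    return assays


def simulate_droplets(true_conc: float, n_total: int = 20_000,
                      droplet_volume: float = 0.00085,
                      dilution_factor: float = 1.0,
                      seed: int | np.random.Generator = 0,
                      sample_id: str = "sim") -> DdPCRWell:
    """Poisson droplet partitioning: positives ~ Binomial(n, 1 - e^{-c v}).

    ``true_conc`` is the concentration of the *diluted* material loaded into
    droplets, in copies/uL.
    """
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    rng = _rng(seed)
    p_pos = 1.0 - np.exp(-true_conc * droplet_volume)
    n_positive = int(rng.binomial(n_total, p_pos))
    return DdPCRWell(n_total=n_total, n_positive=n_positive,
                     droplet_volume=droplet_volume,
                     dilution_factor=dilution_factor, sample_id=sample_id)
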