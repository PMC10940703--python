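"""Amplicon barcode demultiplexing.

Turns paired-end amplicon reads into per-variant barcode counts. Each AAV
capsid variant in the multiplexed mix carries a unique 44-mer barcode in its
transgene; the amplicon spanning that barcode is sequenced 2x150 and reads are
attributed to variants by (1) merging mates on their overlap, (2) filtering to
the expected amplicon length, (3) locating the barcode window between fixed
anchor sequences and (4) nearest-Hamming assignment against the barcode
library.

Every read pair ends in exactly one accounting bucket (a variant count,
ambiguous, unmatched, unmerged or length-filtered), so counts are conserved
exactly.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "AMBIGUOUS",
    "UNMATCHED",
    "BarcodeLibrary",
    "ReadPair",
    "MergedRead",
    "BarcodeCountTable",
    "DemuxParams",
    "DemuxError",
    "MalformedReadError",
    "merge_read_pair",
    "length_filter",
    "identify_barcode",
    "count_barcodes",
    "read_paired_fastq",
    "reverse_complement",
    "hamming",
]

# Amplification primers flanking the barcode: the forward primer is the
# upstream anchor as sequenced; the downstream anchor is the reverse
# complement of the reverse primer's binding region.
DEFAULT_UPSTREAM_ANCHOR = "GAGTTCGTGACCGCCG"
_BC_REVERSE_PRIMER = "ATTGCAGCTTATAATGGTTACAAATAAAGC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Sentinel classifications returned by :func:`identify_barcode`.
AMBIGUOUS = "<ambiguous>"
UNMATCHED = "<unmatched>"


class DemuxError(ValueError):
    """Contract violation in the demultiplexing stage."""


class MalformedReadError(DemuxError):
    """Sequence/quality length mismatch within a mate."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


DEFAULT_DOWNSTREAM_ANCHOR = reverse_complement(_BC_REVERSE_PRIMER)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (N counts as mismatch)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeLibrary:
    """Named barcodes plus the anchors that locate them in a merged read.

    Parameters
    ----------
    entries
        Mapping of variant name to barcode nucleotide sequence. All barcodes
        must share one length (44 in the reference design) and be unique.
    upstream_anchor, downstream_anchor
        Fixed amplicon context immediately 5' and 3' of the barcode.
    expected_merged_length
        Length of the full merged amplicon in bases; reads deviating by more
        than ``length_tolerance`` are discarded before barcode lookup.
    """

    entries: Mapping[str, str]
    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR
    expected_merged_length: int = 0
    length_tolerance: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise DemuxError("barcode library is empty")
        entries = {str(k): str(v).upper() for k, v in self.entries.items()}
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "upstream_anchor", self.upstream_anchor.upper())
        object.__setattr__(self, "downstream_anchor", self.downstream_anchor.upper())
        lengths = {len(bc) for bc in entries.values()}
        if len(lengths) != 1:
            raise DemuxError(f"barcodes have mixed lengths: {sorted(lengths)}")
        if len(set(entries.values())) != len(entries):
            raise DemuxError("barcode sequences are not unique")
        for seq in list(entries.values()) + [self.upstream_anchor, self.downstream_anchor]:
            if set(seq) - set("ACGT"):
                raise DemuxError(f"non-ACGT characters in sequence {seq!r}")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @property
    def variants(self) -> list[str]:
        return list(self.entries)

    def min_pairwise_distance(self) -> int:
        names = self.variants
        return min(
            hamming(self.entries[a], self.entries[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )

    @classmethod
    def from_tsv(cls, path: str | Path, config: str | Path | Mapping | None = None,
                 **overrides) -> "BarcodeLibrary":
        """Load a ``variant<TAB>barcode`` table plus anchor/length config.

        ``config`` may be a YAML/JSON file path or a mapping with any of the
        keys ``upstream_anchor``, ``downstream_anchor``,
        ``expected_merged_length``, ``length_tolerance``.
        """
        entries: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in {"variant", "name"}:
                    continue
                entries[fields[0]] = fields[1]
        kwargs: dict = {}
        if config is not None:
            if isinstance(config, (str, Path)):
                with open(config) as fh:
                    kwargs.update(yaml.safe_load(fh))
            else:
                kwargs.update(config)
        kwargs.update(overrides)
        allowed = {"upstream_anchor", "downstream_anchor",
                   "expected_merged_length", "length_tolerance"}
        kwargs = {k: v for k, v in kwargs.items() if k in allowed}
        return cls(entries=entries, **kwargs)


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read; mate 2 is as sequenced (reverse strand)."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise MalformedReadError(
                f"read {self.id}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int


@dataclass
class BarcodeCountTable:
    """Per-sample, per-variant counts with exact read accounting."""

    sample_id: str
    counts: dict[str, int]
    n_ambiguous: int = 0
    n_unmatched: int = 0
    n_unmerged: int = 0
    n_length_filtered: int = 0
    total_input_pairs: int = 0

    def check_conservation(self) -> None:
        total = (sum(self.counts.values()) + self.n_ambiguous + self.n_unmatched
                 + self.n_unmerged + self.n_length_filtered)
        if total != self.total_input_pairs:
            raise DemuxError(
                f"read accounting broken for {self.sample_id}: "
                f"{total} != {self.total_input_pairs}"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\tcount\n")
            for name, count in self.counts.items():
                fh.write(f"{name}\t{count}\n")

    def summary(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_input_pairs": self.total_input_pairs,
            "n_assigned": sum(self.counts.values()),
            "n_ambiguous": self.n_ambiguous,
            "n_unmatched": self.n_unmatched,
            "n_unmerged": self.n_unmerged,
            "n_length_filtered": self.n_length_filtered,
        }

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass(frozen=True)
class DemuxParams:
    """Tunables for the merge/filter/identify pipeline."""

    min_overlap: int = 12
    max_mismatch_frac: float = 0.1
    max_hamming: int = 3


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_read_pair(pair: ReadPair, min_overlap: int = 12,
                    max_mismatch_frac: float = 0.1) -> MergedRead | None:
    """Merge mates on their best suffix/prefix overlap; None if none admissible.

    Mate 2 is reverse-complemented, then every overlap length from
    ``min_overlap`` to ``min(len1, len2)`` is scored by match count (a
    seed-free full offset scan). The admissible offset (mismatch fraction
    within the overlap <= ``max_mismatch_frac``) with the most matches wins;
    ties go to the longer overlap. Within the overlap each disagreeing base is
    taken from the mate with the higher quality (tie -> mate 1) and carries
    the max of the two qualities.
    """
    if min_overlap < 1:
        raise DemuxError("min_overlap must be >= 1")
    s1 = pair.seq1.upper()
    s2 = reverse_complement(pair.seq2)
    q1 = pair.qual1
    q2 = pair.qual2[::-1]
    n1, n2 = len(s1), len(s2)
    max_l = min(n1, n2)
    if max_l < min_overlap:
        return None

    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)

    best_l = 0
    best_matches = -1
    # Scan longest-first so we can stop once no shorter overlap can win.
    for L in range(max_l, min_overlap - 1, -1):
        if L <= best_matches:
            break
        matches = int(np.count_nonzero(a[n1 - L:] == b[:L]))
        if (L - matches) / L > max_mismatch_frac:
            continue
        if matches > best_matches:
            best_matches = matches
            best_l = L
    if best_l == 0:
        return None

    L = best_l
    seq = list(s1[: n1 - L])
    qual = list(q1[: n1 - L])
    for i in range(L):
        c1, c2 = s1[n1 - L + i], s2[i]
        p1, p2 = q1[n1 - L + i], q2[i]
        if c1 == c2:
            base = c1
        else:
            base = c1 if p1 >= p2 else c2
        seq.append(base)
        qual.append(max(p1, p2))
    seq.extend(s2[L:])
    qual.extend(q2[L:])
    return MergedRead(id=pair.id, seq="".join(seq), qual="".join(qual), overlap_len=L)


def length_filter(read: MergedRead, lib: BarcodeLibrary) -> bool:
    """True iff the merged length is within tolerance of the expected length."""
    if lib.expected_merged_length <= 0:
        raise DemuxError("expected_merged_length must be configured (> 0)")
    return abs(len(read.seq) - lib.expected_merged_length) <= lib.length_tolerance


# ---------------------------------------------------------------------------
# Barcode identification
# ---------------------------------------------------------------------------


def _find_anchor(seq: str, anchor: str) -> int:
    """Position of the anchor: exact match first, else best <=1-mismatch scan."""
    pos = seq.find(anchor)
    if pos >= 0:
        return pos
    m = len(anchor)
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    best_pos, best_d = -1, 2
    for i in range(len(seq) - m + 1):
        d = int(np.count_nonzero(s[i:i + m] != a))
        if d < best_d:
            best_pos, best_d = i, d
            if d == 0:
                break
    return best_pos


def _library_matrix(lib: BarcodeLibrary) -> tuple[list[str], np.ndarray]:
    names = lib.variants
    mat = np.frombuffer(
        "".join(lib.entries[n] for n in names).encode(), dtype=np.uint8
    ).reshape(len(names), lib.barcode_length)
    return names, mat


def identify_barcode(read: MergedRead | str, lib: BarcodeLibrary,
                     max_hamming: int = 3,
                     _cache: tuple[list[str], np.ndarray] | None = None) -> str:
    """Assign a merged read to its variant, or ``AMBIGUOUS`` / ``UNMATCHED``.

    The barcode window is located by the anchors (exact, else best
    <=1-mismatch placement); its Hamming distance to every library barcode is
    computed and the unique nearest variant at distance <= ``max_hamming`` is
    returned. A tie at the minimum admissible distance is ``AMBIGUOUS``;
    anchors missing, a malformed window or distance > ``max_hamming`` is
    ``UNMATCHED``. Indels inside the barcode are not rescued.
    """
    seq = (read if isinstance(read, str) else read.seq).upper()
    bc_len = lib.barcode_length
    up = lib.upstream_anchor
    pos = _find_anchor(seq, up)
    if pos < 0:
        return UNMATCHED
    start = pos + len(up)
    end = start + bc_len
    down = lib.downstream_anchor
    if end + len(down) > len(seq):
        return UNMATCHED
    down_obs = seq[end:end + len(down)]
    if hamming(down_obs, down) > 1:
        return UNMATCHED
    window = seq[start:end]
    if len(window) != bc_len:
        return UNMATCHED

    names, mat = _cache if _cache is not None else _library_matrix(lib)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    dists = np.count_nonzero(mat != w, axis=1)
    order = np.argsort(dists, kind="stable")
    d0 = int(dists[order[0]])
    if d0 > max_hamming:
        return UNMATCHED
    if len(names) > 1 and int(dists[order[1]]) == d0:
        return AMBIGUOUS
    return names[order[0]]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def count_barcodes(pairs: Iterable[ReadPair], lib: BarcodeLibrary,
                   params: DemuxParams = DemuxParams(),
                   sample_id: str = "sample") -> BarcodeCountTable:
    """Run merge -> length filter -> identify over all pairs and count.

    Empty input yields a table of zeros. The accounting invariant (assigned +
    ambiguous + unmatched + unmerged + length-filtered = total input pairs)
    is checked before returning.
    """
    table = BarcodeCountTable(
        sample_id=sample_id, counts={name: 0 for name in lib.variants}
    )
    cache = _library_matrix(lib)
    for pair in pairs:
        table.total_input_pairs += 1
        merged = merge_read_pair(pair, params.min_overlap, params.max_mismatch_frac)
        if merged is None:
            table.n_unmerged += 1
            continue
        if not length_filter(merged, lib):
            table.n_length_filtered += 1
            continue
        hit = identify_barcode(merged, lib, params.max_hamming, _cache=cache)
        if hit == AMBIGUOUS:
            table.n_ambiguous += 1
        elif hit == UNMATCHED:
            table.n_unmatched += 1
        else:
            table.counts[hit] += 1
    table.check_conservation()
    return table


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_paired_fastq(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    with _open_maybe_gzip(r1) as fh1, _open_maybe_gzip(r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, seq1, qual1), (id2, seq2, qual2) in zip(it1, it2):
            yield ReadPair(id=id1.split()[0], seq1=seq1, seq2=seq2,
                           qual1=qual1, qual2=qual2)
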