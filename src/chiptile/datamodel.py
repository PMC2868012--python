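"""Shared domain containers for tiling-array ChIP-chip analysis.

All genomic coordinates are 0-based, half-open internally. External
1-based formats (GFF, WIG) are converted at the I/O boundary. A probe
that matches the reverse strand over the forward-strand interval
[s, s+L) is stored with ``start = s`` and ``strand = '-'`` so that
windowing and peak coordinates live in a single coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a container's invariants are violated on construction."""


@dataclass
class ProbeSet:
    """The array's reporters: id, oligo sequence, physical position.

    Invariants: unique probe ids; all sequences over {A,C,G,T,N} and of one
    common length L; sequences are uppercased on ingest.
    """

    probe_ids: List[str]
    sequences: List[str]
    array_x: np.ndarray
    array_y: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        self.array_x = np.asarray(self.array_x, dtype=np.int64)
        self.array_y = np.asarray(self.array_y, dtype=np.int64)
        n = len(self.probe_ids)
        if not (len(self.sequences) == len(self.array_x) == len(self.array_y) == n):
            raise ValidationError("probe field lengths differ")
        if n == 0:
            raise ValidationError("empty probe set")
        if len(set(self.probe_ids)) != n:
            seen, dups = set(), []
            for p in self.probe_ids:
                if p in seen:
                    dups.append(p)
                seen.add(p)
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(f"inconsistent sequence lengths: {sorted(lengths)}")
        bad = [s for s in self.sequences if set(s) - DNA_ALPHABET]
        if bad:
            raise ValidationError(f"illegal characters in sequences, e.g. {bad[0]!r}")
        if (self.array_x < 0).any() or (self.array_y < 0).any():
            raise ValidationError("negative array coordinates")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def probe_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class ProbeAnnotation:
    """Genomic placement of uniquely matching probes (the corrected bpmap).

    ``entries`` maps chromosome -> list of (probe_index, start, strand),
    sorted by start (ties by probe_index). Each probe index appears at most
    once in the whole annotation. ``match_report`` counts the unique / none /
    multiple classification of the originating probe set.
    """

    entries: Dict[str, List[Tuple[int, int, str]]]
    match_report: Dict[str, int] = field(
        default_factory=lambda: {"unique": 0, "none": 0, "multiple": 0}
    )
    probe_length: int = 25

    def __post_init__(self) -> None:
        seen: set = set()
        for chrom, ent in self.entries.items():
            ordered = sorted(ent, key=lambda e: (e[1], e[0]))
            if ordered != list(ent):
                warnings.warn(f"annotation for {chrom} was unsorted; sorted deterministically")
                self.entries[chrom] = ordered
            for idx, start, strand in self.entries[chrom]:
                if strand not in ("+", "-"):
                    raise ValidationError(f"bad strand {strand!r}")
                if start < 0:
                    raise ValidationError("negative start")
                if idx in seen:
                    raise ValidationError(f"probe index {idx} annotated more than once")
                seen.add(idx)

    @property
    def n_annotated(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def chrom_arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(probe_index, start) arrays for one chromosome, sorted by start."""
        ent = self.entries[chrom]
        idx = np.array([e[0] for e in ent], dtype=np.int64)
        starts = np.array([e[1] for e in ent], dtype=np.int64)
        return idx, starts


SCALE_TAGS = ("raw", "log2", "percentile", "enrichment")
# Documented scale transitions: raw -> log2 -> percentile -> enrichment
_SCALE_ORDER = {t: i for i, t in enumerate(SCALE_TAGS)}


@dataclass
class ArrayMeta:
    name: str
    role: str  # "IP" or "reference"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("IP", "reference"):
            raise ValidationError(f"array role must be IP or reference, got {self.role!r}")


@dataclass
class IntensityMatrix:
    """probes x arrays measurements with per-array metadata.

    Row order matches the ProbeSet it was read against. ``scale_tag``
    documents the measurement scale and may only advance along
    raw -> log2 -> percentile -> enrichment via the normalization ops.
    """

    values: np.ndarray
    array_meta: List[ArrayMeta]
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (probes x arrays)")
        if self.values.shape[1] != len(self.array_meta):
            raise ValidationError("array_meta length does not match column count")
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "raw" and np.nanmin(self.values, initial=0) < 0:
            raise ValidationError("raw-scale intensities must be non-negative")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def array_names(self) -> List[str]:
        return [m.name for m in self.array_meta]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.array_names.index(name)]

    def retag(self, new_tag: str) -> None:
        if _SCALE_ORDER[new_tag] < _SCALE_ORDER[self.scale_tag]:
            raise ValidationError(f"scale may not move back from {self.scale_tag} to {new_tag}")
        self.scale_tag = new_tag


@dataclass
class Feature:
    feature_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.feature_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.feature_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on +, rightmost (end-1) on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class FeatureSet:
    features: List[Feature]
    skipped: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def ids(self) -> List[str]:
        return [f.feature_id for f in self.features]


@dataclass
class CmarrtParams:
    """Tuning of the correlation-aware moving-average peak caller.

    w: window half-width in probes (full window 2w+1);
    max_lag: autocorrelation lags estimated (default 2w);
    fdr_q: target FDR level for seed probes;
    max_gap: bp gap allowed between probe intervals when merging;
    min_probes: minimum probes per reported region.
    """

    w: int = 4
    max_lag: Optional[int] = None
    fdr_q: float = 0.05
    max_gap: int = 250
    min_probes: int = 4

    def __post_init__(self) -> None:
        if self.max_lag is None:
            self.max_lag = 2 * self.w
        if self.w < 0 or self.max_gap < 0 or self.min_probes < 1:
            raise ValidationError("w >= 0, max_gap >= 0, min_probes >= 1 required")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValidationError("fdr_q must lie in (0, 1)")


@dataclass
class StatTrack:
    """Per-chromosome peak-calling statistics along the annotation.

    Arrays (equal length, positions strictly increasing): probe start
    positions, standardized scores z, moving averages S, standardized
    moving averages S*, upper-tail p-values and BH-adjusted p-values.
    """

    positions: np.ndarray
    z: np.ndarray
    s: np.ndarray
    s_star: np.ndarray
    p: Optional[np.ndarray] = None
    p_adj: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        for arr in (self.z, self.s, self.s_star):
            if len(arr) != n:
                raise ValidationError("track arrays differ in length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValidationError("positions must be strictly increasing")
        for arr in (self.p, self.p_adj):
            if arr is not None:
                if len(arr) != n:
                    raise ValidationError("p arrays differ in length")
                if np.nanmin(arr, initial=1) < 0 or np.nanmax(arr, initial=0) > 1:
                    raise ValidationError("p values outside [0,1]")
        if self.p is not None and self.p_adj is not None:
            if np.any(self.p_adj < self.p - 1e-12):
                raise ValidationError("p_adj must dominate p elementwise")


@dataclass
class PeakCall:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive; covers last probe start + L
    n_probes: int
    peak_score: float  # mean S* of member probes
    min_p_adj: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("peak end must exceed start")
        if self.n_probes < 1:
            raise ValidationError("peak must contain probes")


@dataclass
class ProfileGrid:
    upstream: int
    downstream: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if self.upstream % self.bin_size or self.downstream % self.bin_size:
            raise ValidationError("bin_size must divide upstream and downstream")

    @property
    def n_bins(self) -> int:
        return (self.upstream + self.downstream) // self.bin_size

    def bin_centers(self) -> np.ndarray:
        """Relative coordinate of each bin center (anchor at 0)."""
        edges = np.arange(-self.upstream, self.downstream + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0


@dataclass
class AlignedProfileMatrix:
    """features x bins matrix of anchored signal; NaN marks empty bins."""

    matrix: np.ndarray
    grid: ProfileGrid
    anchor: str
    feature_ids: List[str]
    n_empty_rows: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.anchor not in ("TSS", "TTS"):
            raise ValidationError("anchor must be TSS or TTS")
        if self.matrix.shape != (len(self.feature_ids), self.grid.n_bins):
            raise ValidationError("matrix shape inconsistent with grid / features")


@dataclass
class QuantileProfile:
    """bins x levels quantile values; values non-decreasing across levels."""

    levels: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.levels <= 0) or np.any(self.levels >= 1):
            raise ValidationError("quantile levels must lie in (0, 1)")
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError("levels must be strictly increasing")
        if self.matrix.shape[1] != len(self.levels):
            raise ValidationError("matrix columns must match levels")
        with np.errstate(invalid="ignore"):
            if np.any(np.diff(self.matrix, axis=1) < -1e-9):
                raise ValidationError("quantiles must be non-decreasing across levels")

    @property
    def median_line(self) -> np.ndarray:
        i = int(np.argmin(np.abs(self.levels - 0.5)))
        if abs(self.levels[i] - 0.5) > 1e-9:
            raise ValidationError("levels do not include 0.5")
        return self.matrix[:, i]


@dataclass
class RegionSpec:
    """A transcript-relative region, e.g. [TSS+0, TSS+300) or [TSS+300, TTS-100).

    Offsets are signed base pairs along the transcription direction. A
    feature for which the resolved region has non-positive length is
    skipped and counted by the consuming operation.
    """

    region_id: str
    start_anchor: str
    start_offset: int
    end_anchor: str
    end_offset: int

    def __post_init__(self) -> None:
        for a in (self.start_anchor, self.end_anchor):
            if a not in ("TSS", "TTS"):
                raise ValidationError("anchors must be TSS or TTS")

    def resolve(self, feature: Feature) -> Optional[Tuple[int, int]]:
        """Transcription-coordinate interval [r0, r1) relative to the TSS.

        Returns None when the region degenerates for this feature.
        """
        length = feature.end - feature.start
        anchor_t = {"TSS": 0, "TTS": length - 1}
        r0 = anchor_t[self.start_anchor] + self.start_offset
        r1 = anchor_t[self.end_anchor] + self.end_offset
        if r1 <= r0:
            return None
        return r0, r1
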