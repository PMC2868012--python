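"""Anchored binding profiles and occupancy-expression correlation.

Probe-level signal is aligned along a feature anchor (TSS or TTS), always
in transcription direction: for a minus-strand gene "downstream" points
left on the chromosome and the profile row is mirrored accordingly. The
aligned rows are summarized either by the per-position mean or — more
informatively — by per-position quantiles (the profileplot), which shows
whether an apparent mean enrichment is carried by the bulk of genes or by
a handful of extreme ones.

Region-wise analysis averages the signal in transcript-relative windows
(e.g. promoter, early elongation, pre-TTS) and correlates those means with
gene expression across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    AlignedProfileMatrix,
    FeatureSet,
    ProbeAnnotation,
    ProfileGrid,
    QuantileProfile,
    RegionSpec,
    ValidationError,
)

DEFAULT_QUANTILE_LEVELS = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _relative_positions(
    starts: np.ndarray, anchor_pos: int, strand: str
) -> np.ndarray:
    """Strand-signed probe coordinates relative to an anchor position."""
    if strand == "+":
        return starts - anchor_pos
    return anchor_pos - starts


def align_profiles(
    anno: ProbeAnnotation,
    signal: np.ndarray,
    features: FeatureSet,
    anchor: str = "TSS",
    upstream: int = 500,
    downstream: int = 1500,
    bin_size: int = 50,
) -> AlignedProfileMatrix:
    """Average probe signal in bins around each feature's anchor.

    A probe belongs to a feature's window when its strand-signed relative
    start lies in [-upstream, downstream); bins with no probe are NaN.
    Windows running past chromosome ends are simply empty there (features
    are truncated, not dropped).
    """
    grid = ProfileGrid(upstream=upstream, downstream=downstream, bin_size=bin_size)
    signal = np.asarray(signal, dtype=float)
    n_bins = grid.n_bins
    matrix = np.full((len(features), n_bins), np.nan)
    counts = np.zeros((len(features), n_bins), dtype=np.int64)
    sums = np.zeros((len(features), n_bins))
    usable = {f.strand for f in features} & {"+", "-"}
    if len(features) == 0 or not usable:
        raise ValidationError("no stranded features to align")
    per_chrom = {
        chrom: anno.chrom_arrays(chrom) for chrom in anno.entries
    }
    n_empty = 0
    for fi, feat in enumerate(features):
        if feat.chrom not in per_chrom:
            n_empty += 1
            continue
        idx, starts = per_chrom[feat.chrom]
        a = feat.tss if anchor == "TSS" else feat.tts
        rel = _relative_positions(starts, a, feat.strand)
        inside = (rel >= -upstream) & (rel < downstream)
        if not inside.any():
            n_empty += 1
            continue
        bins = (rel[inside] + upstream) // bin_size
        vals = signal[idx[inside]]
        ok = ~np.isnan(vals)
        np.add.at(sums[fi], bins[ok], vals[ok])
        np.add.at(counts[fi], bins[ok], 1)
    with np.errstate(invalid="ignore"):
        matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AlignedProfileMatrix(
        matrix=matrix,
        grid=grid,
        anchor=anchor,
        feature_ids=features.ids,
        n_empty_rows=n_empty,
    )


def mean_profile(m: AlignedProfileMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bin mean over features, ignoring NaN; also returns per-bin n."""
    if m.matrix.shape[0] == 0:
        raise ValidationError("empty profile matrix")
    valid = ~np.isnan(m.matrix)
    n = valid.sum(axis=0)
    sums = np.where(valid, m.matrix, 0.0).sum(axis=0)
    means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return means, n


def quantile_profiles(
    m: AlignedProfileMatrix, levels: Optional[Sequence[float]] = None
) -> QuantileProfile:
    """Per-bin quantiles across features (the profileplot summary).

    Default levels are 0.05, 0.10, ..., 0.95. Quantiles use linear
    interpolation between order statistics; bins with no defined value get
    NaN at every level.
    """
    levels_arr = (
        np.asarray(levels, dtype=float) if levels is not None else DEFAULT_QUANTILE_LEVELS
    )
    if levels_arr.size == 0:
        raise ValidationError("no quantile levels")
    n_bins = m.matrix.shape[1]
    out = np.full((n_bins, levels_arr.size), np.nan)
    for b in range(n_bins):
        col = m.matrix[:, b]
        col = col[~np.isnan(col)]
        if col.size:
            out[b] = np.quantile(col, levels_arr)
    return QuantileProfile(levels=levels_arr, matrix=out)


def outlier_profiles(
    m: AlignedProfileMatrix,
    q_low: float = 0.05,
    q_high: float = 0.95,
    fraction: float = 0.5,
) -> Tuple[List[int], int]:
    """Indices of features lying outside the quantile band too often.

    A feature is flagged when more than ``fraction`` of its non-missing
    bins fall outside the [q_low, q_high] per-bin band. Returns the flagged
    row indices and the number of all-missing rows (counted separately,
    never flagged).
    """
    qp = quantile_profiles(m, levels=[q_low, q_high])
    lo = qp.matrix[:, 0]
    hi = qp.matrix[:, 1]
    flagged: List[int] = []
    n_all_missing = 0
    for fi in range(m.matrix.shape[0]):
        row = m.matrix[fi]
        ok = ~np.isnan(row)
        if not ok.any():
            n_all_missing += 1
            continue
        outside = (row[ok] < lo[ok]) | (row[ok] > hi[ok])
        if outside.mean() > fraction:
            flagged.append(fi)
    return flagged, n_all_missing


@dataclass
class RegionOccupancy:
    """Per-feature mean signal in transcript-relative regions."""

    region_ids: List[str]
    feature_ids: List[str]
    matrix: np.ndarray  # regions x features, NaN = no probes / skipped
    n_skipped: Dict[str, int] = field(default_factory=dict)


def region_mean_occupancy(
    anno: ProbeAnnotation,
    signal: np.ndarray,
    features: FeatureSet,
    region: RegionSpec,
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Mean probe signal in one transcript-relative region, per feature.

    Features for which the region degenerates (non-positive length) are
    skipped; features whose region holds no probe get NaN. Both are
    counted.
    """
    signal = np.asarray(signal, dtype=float)
    out = np.full(len(features), np.nan)
    counters = {"degenerate": 0, "no_probes": 0}
    per_chrom = {chrom: anno.chrom_arrays(chrom) for chrom in anno.entries}
    for fi, feat in enumerate(features):
        span = region.resolve(feat)
        if span is None:
            counters["degenerate"] += 1
            continue
        r0, r1 = span
        if feat.chrom not in per_chrom:
            counters["no_probes"] += 1
            continue
        idx, starts = per_chrom[feat.chrom]
        rel = _relative_positions(starts, feat.tss, feat.strand)
        inside = (rel >= r0) & (rel < r1)
        vals = signal[idx[inside]]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            counters["no_probes"] += 1
            continue
        out[fi] = vals.mean()
    return out, counters


def region_occupancy_matrix(
    anno: ProbeAnnotation,
    signal: np.ndarray,
    features: FeatureSet,
    regions: Sequence[RegionSpec],
) -> RegionOccupancy:
    rows = []
    skipped: Dict[str, int] = {}
    for region in regions:
        means, counters = region_mean_occupancy(anno, signal, features, region)
        rows.append(means)
        skipped[region.region_id] = counters["degenerate"]
    return RegionOccupancy(
        region_ids=[r.region_id for r in regions],
        feature_ids=features.ids,
        matrix=np.vstack(rows),
        n_skipped=skipped,
    )


def region_expression_correlation(
    occupancy: RegionOccupancy,
    expression: Mapping[str, float],
) -> Dict[str, Dict[str, float]]:
    """Pearson correlation of region occupancy with expression, per region.

    Features are joined by exact id match; unmatched ids are counted in
    the ``_join`` entry. Each region needs at least 3 complete pairs.
    """
    expr = np.array(
        [expression.get(fid, np.nan) for fid in occupancy.feature_ids], dtype=float
    )
    n_unmatched = sum(1 for fid in occupancy.feature_ids if fid not in expression)
    result: Dict[str, Dict[str, float]] = {
        "_join": {"n_features": len(occupancy.feature_ids), "n_unmatched": n_unmatched}
    }
    for ri, rid in enumerate(occupancy.region_ids):
        occ = occupancy.matrix[ri]
        ok = ~np.isnan(occ) & ~np.isnan(expr)
        n = int(ok.sum())
        if n < 3:
            raise ValidationError(
                f"region {rid!r} has only {n} complete pairs (need >= 3)"
            )
        r = float(np.corrcoef(occ[ok], expr[ok])[0, 1])
        result[rid] = {"r": r, "n": n}
    return result


def default_regions() -> List[RegionSpec]:
    """A transcript-region set spanning promoter to post-TTS.

    Editable via configuration; these defaults cover the upstream promoter,
    the TSS, early/mid elongation, the stretch before the TTS and the
    region downstream of it.
    """
    return [
        RegionSpec("promoter", "TSS", -300, "TSS", 0),
        RegionSpec("tss", "TSS", -100, "TSS", 100),
        RegionSpec("early_elongation", "TSS", 100, "TSS", 400),
        RegionSpec("elongation", "TSS", 400, "TTS", -200),
        RegionSpec("pre_tts", "TTS", -200, "TTS", 0),
        RegionSpec("post_tts", "TTS", 0, "TTS", 300),
    ]


def expression_groups(
    expression: Mapping[str, float],
    low_fraction: float = 0.2,
    high_fraction: float = 0.1,
) -> Tuple[List[str], List[str]]:
    """Split genes into bottom/top expression groups by percentile cutoffs.

    Returns (low_ids, high_ids): ids whose expression falls in the lowest
    ``low_fraction`` resp. the highest ``high_fraction`` of all values.
    """
    ids = list(expression)
    vals = np.array([expression[i] for i in ids], dtype=float)
    ok = ~np.isnan(vals)
    lo_cut = np.quantile(vals[ok], low_fraction)
    hi_cut = np.quantile(vals[ok], 1.0 - high_fraction)
    low = [i for i, v in zip(ids, vals) if not np.isnan(v) and v <= lo_cut]
    high = [i for i, v in zip(ids, vals) if not np.isnan(v) and v >= hi_cut]
    return low, high
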