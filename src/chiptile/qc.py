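"""Hybridization-bias diagnostics and array-level quality control.

Affymetrix oligo probes hybridize more strongly the more G/C their 25-mer
contains, and each base contributes a position-dependent offset. Improper
normalization leaves these sequence effects in the data, so the toolkit
summarizes them before and after normalization: intensity distributions per
GC-content group, a 4 x L matrix of mean intensity per nucleotide per
position, an in-silico reconstruction of the physical array image, and MA
values for pairwise array comparison. All outputs are plot-ready tables;
the scale (raw/log2/percentile/enrichment) of the input is reported
alongside, never assumed.

Probes containing N are excluded from both sequence-bias diagnostics so the
per-position counts are identical across positions and the count-weighted
column means reproduce the global mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .datamodel import ProbeSet, ValidationError

_BASES = "ACGT"


def gc_content(seq: str) -> int:
    """Number of G or C bases in an uppercase DNA string; N contributes 0."""
    return seq.count("G") + seq.count("C")


@dataclass
class GCBiasTable:
    """Per-GC-group intensity summary (empty groups omitted)."""

    table: pd.DataFrame  # columns: gc, n_probes, median, q1, q3, mean
    scale_tag: str = "raw"


@dataclass
class PositionBiasMatrix:
    """means[b, p]: mean intensity of probes with base b at position p."""

    means: np.ndarray  # 4 x L
    counts: np.ndarray  # 4 x L
    bases: str = _BASES
    n_excluded_n_probes: int = 0
    scale_tag: str = "raw"


def gc_bias_summary(
    intensity: np.ndarray, probes: ProbeSet, scale_tag: str = "raw"
) -> GCBiasTable:
    """Group probes by GC count and summarize each group's intensities.

    Quartiles use linear interpolation between order statistics. Probes
    with NaN intensity are dropped; groups left empty are omitted, so group
    sizes partition the probes with defined intensity.
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(intensity) != probes.n_probes:
        raise ValidationError("intensity length does not match probe set")
    gc = np.array([gc_content(s) for s in probes.sequences])
    ok = ~np.isnan(intensity)
    if not ok.any():
        raise ValidationError("all intensities are NaN")
    rows = []
    for g in range(probes.probe_length + 1):
        sel = ok & (gc == g)
        if not sel.any():
            continue
        vals = intensity[sel]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "gc": g,
                "n_probes": int(sel.sum()),
                "median": med,
                "q1": q1,
                "q3": q3,
                "mean": vals.mean(),
            }
        )
    return GCBiasTable(table=pd.DataFrame(rows), scale_tag=scale_tag)


def position_nucleotide_bias(
    intensity: np.ndarray, probes: ProbeSet, scale_tag: str = "raw"
) -> PositionBiasMatrix:
    """Mean intensity per base per probe position (4 x L).

    Cell (b, p) averages the intensity of all N-free probes whose base at
    position p is b; cells with no qualifying probe are NaN.
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(intensity) != probes.n_probes:
        raise ValidationError("intensity length does not match probe set")
    L = probes.probe_length
    keep = np.array(
        ["N" not in s for s in probes.sequences]
    ) & ~np.isnan(intensity)
    n_excluded = int((~keep).sum())
    seq_codes = np.full((probes.n_probes, L), -1, dtype=np.int8)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for i, s in enumerate(probes.sequences):
        if keep[i]:
            seq_codes[i] = [base_idx[c] for c in s]
    sums = np.zeros((4, L))
    counts = np.zeros((4, L), dtype=np.int64)
    vals = intensity[keep]
    codes = seq_codes[keep]
    for b in range(4):
        mask = codes == b
        counts[b] = mask.sum(axis=0)
        sums[b] = np.where(mask, vals[:, None], 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PositionBiasMatrix(
        means=means,
        counts=counts,
        n_excluded_n_probes=n_excluded,
        scale_tag=scale_tag,
    )


def array_image(intensity: np.ndarray, probes: ProbeSet) -> np.ndarray:
    """Reconstruct the physical array image from probe (x, y) coordinates.

    Returns a (max_y+1) x (max_x+1) grid with NaN for cells holding no
    probe. Duplicate coordinates are an error listing the offenders.
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(intensity) != probes.n_probes:
        raise ValidationError("intensity length does not match probe set")
    coords = list(zip(probes.array_x.tolist(), probes.array_y.tolist()))
    if len(set(coords)) != len(coords):
        seen, dups = set(), []
        for c in coords:
            if c in seen:
                dups.append(c)
            seen.add(c)
        raise ValidationError(f"duplicate array coordinates: {dups[:5]}")
    grid = np.full((probes.array_y.max() + 1, probes.array_x.max() + 1), np.nan)
    grid[probes.array_y, probes.array_x] = intensity
    return grid


def ma_values(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """MA transform of two positive intensity vectors.

    M = log2(a/b), A = (log2 a + log2 b) / 2. Zeros are replaced by the
    smallest positive value of their vector, as in log2_transform.
    """
    out = []
    for v in (np.asarray(a, dtype=float), np.asarray(b, dtype=float)):
        v = v.copy()
        zero = v == 0
        if zero.any():
            pos = v[(v > 0) & np.isfinite(v)]
            if pos.size == 0:
                raise ValidationError("vector has no positive values")
            v[zero] = pos.min()
        if np.nanmin(v) < 0:
            raise ValidationError("MA values require non-negative intensities")
        out.append(np.log2(v))
    la, lb = out
    return la - lb, (la + lb) / 2.0
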