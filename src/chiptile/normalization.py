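"""Normalization of tiling-array intensities against a reference IP.

The recommended route is a rank-percentile normalization of both the
experiment and the reference (mock IP or digested genomic DNA) followed by
a per-probe subtraction of the reference percentile from the experiment
percentile. Ranking removes between-array scale differences entirely; the
subtraction removes unspecific binding that the control captures. The
Buck & Lieb median-rank-percentile combination of replicate arrays is also
provided.

Percentiles are rank/n with average ranks for ties, so the maximum is
exactly 1 and the output is invariant under any strictly monotone transform
of the input. NaN cells are carried through as NaN and counted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy.stats import rankdata

from .datamodel import IntensityMatrix, ValidationError


@dataclass
class NormalizationResult:
    """Per-probe enrichment (experiment minus reference, percentile scale)."""

    enrichment: np.ndarray
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        finite = self.enrichment[np.isfinite(self.enrichment)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValidationError("percentile-scale enrichment must lie in [-1, 1]")


def log2_transform(mat: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of a raw-scale matrix.

    Zeros are replaced by the smallest positive value of their array before
    transforming; the replacement count is recorded in the result's
    ``n_zeros_replaced`` attribute.
    """
    if mat.scale_tag != "raw":
        raise ValidationError(f"log2_transform expects raw scale, got {mat.scale_tag}")
    values = mat.values.copy()
    n_replaced = 0
    for j in range(values.shape[1]):
        col = values[:, j]
        zero = col == 0
        if zero.any():
            pos = col[(col > 0) & np.isfinite(col)]
            if pos.size == 0:
                raise ValidationError(f"array {mat.array_meta[j].name} has no positive values")
            col[zero] = pos.min()
            n_replaced += int(zero.sum())
    if np.nanmin(values) <= 0:
        raise ValidationError("negative intensities cannot be log-transformed")
    out = IntensityMatrix(
        values=np.log2(values), array_meta=list(mat.array_meta), scale_tag="log2"
    )
    out.n_zeros_replaced = n_replaced  # type: ignore[attr-defined]
    return out


def rank_percentile(values: np.ndarray) -> np.ndarray:
    """Within-array percentile ranks: rank_i / n, average ranks for ties.

    NaNs are excluded from ranking and re-inserted as NaN; n counts the
    non-NaN entries. Output lies in (0, 1] and preserves strict order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValidationError("rank_percentile expects a non-empty 1-D vector")
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("all-NaN input")
    out[mask] = rankdata(values[mask], method="average") / n
    return out


def percentile_normalize(mat: IntensityMatrix) -> IntensityMatrix:
    """Apply rank_percentile to every array (column) of a matrix."""
    cols = [rank_percentile(mat.values[:, j]) for j in range(mat.values.shape[1])]
    out = IntensityMatrix(
        values=np.column_stack(cols),
        array_meta=list(mat.array_meta),
        scale_tag=mat.scale_tag,
    )
    out.retag("percentile")
    return out


def subtract_reference(
    ip: IntensityMatrix,
    ref: IntensityMatrix,
    pairing: Mapping[str, str],
) -> NormalizationResult:
    """Enrichment = IP percentile minus paired reference percentile.

    ``pairing`` maps IP array name -> reference array name. When several
    pairs are given, the per-probe enrichments are averaged across pairs.
    """
    for m in (ip, ref):
        if m.scale_tag != "percentile":
            raise ValidationError("subtract_reference expects percentile-scaled inputs")
    if ip.n_probes != ref.n_probes:
        raise ValidationError("IP and reference probe counts differ")
    if not pairing:
        raise ValidationError("empty pairing")
    diffs = []
    for ip_name, ref_name in pairing.items():
        if ip_name not in ip.array_names:
            raise ValidationError(f"unknown IP array {ip_name!r}")
        if ref_name not in ref.array_names:
            raise ValidationError(f"unknown reference array {ref_name!r}")
        diffs.append(ip.column(ip_name) - ref.column(ref_name))
    enrichment = np.mean(diffs, axis=0)
    return NormalizationResult(
        enrichment=enrichment,
        provenance={
            "method": "rank-percentile-subtract",
            "pairs": dict(pairing),
            "tie_rule": "average",
        },
    )


def median_rank_percentile(values: np.ndarray) -> np.ndarray:
    """Buck & Lieb replicate combination.

    Each replicate array (column) is converted to within-array ranks
    (average ties); the per-probe median rank across arrays is divided by
    the probe count to give one percentile per probe. With a single array
    this reduces to rank_percentile.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, k = values.shape
    if n == 0 or k == 0:
        raise ValidationError("empty replicate matrix")
    ranks = np.column_stack(
        [rankdata(values[:, j], method="average") for j in range(k)]
    )
    return np.median(ranks, axis=1) / n


def normalize_ip_reference(
    raw: IntensityMatrix, pairing: Optional[Mapping[str, str]] = None
) -> NormalizationResult:
    """Full recommended route on one raw matrix holding IP + reference arrays.

    Percentile-normalizes every array, then subtracts each reference from
    its IP. Without an explicit pairing, every IP array is paired with every
    reference array in turn and results averaged.
    """
    logged = log2_transform(raw)
    pct = percentile_normalize(logged)
    ip_names = [m.name for m in pct.array_meta if m.role == "IP"]
    ref_names = [m.name for m in pct.array_meta if m.role == "reference"]
    if not ip_names or not ref_names:
        raise ValidationError("need at least one IP and one reference array")
    if pairing is None:
        diffs = [
            pct.column(ip_n) - pct.column(ref_n)
            for ip_n in ip_names
            for ref_n in ref_names
        ]
        enrichment = np.mean(diffs, axis=0)
        return NormalizationResult(
            enrichment=enrichment,
            provenance={
                "method": "rank-percentile-subtract",
                "pairs": [(i, r) for i in ip_names for r in ref_names],
                "tie_rule": "average",
            },
        )
    return subtract_reference(pct, pct, pairing)
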