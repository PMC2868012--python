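"""Synthetic tiling-array data with known ground truth.

Every other module is testable offline against fixtures fabricated here:
an i.i.d. random genome, probes cut from it at fixed spacing (optionally
with planted duplicate and scrambled sequences to exercise the remapping
classifier), log-scale intensities with injected GC slope, per-position
nucleotide effects, planted enrichment blocks on the IP arrays and
Gaussian noise, plus gene features and expression values tied to the
occupancy of a chosen transcript region. Reference arrays share all
sequence biases but carry no enrichment — emulating a control IP that
captures only unspecific binding.

One master seed fans out to per-component child seeds through fixed
offsets, so adding a generator never perturbs existing fixtures, and the
whole dataset regenerates byte-identically from (parameters, seed).

What this generator does NOT emulate: fragment-size smoothing of true
enrichment (planted blocks have sharp edges), spatial artefacts on the
array surface, saturation, or dye effects. Tests passing on these
fixtures certify algorithmic correctness, not robustness to every
real-data pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    ArrayMeta,
    Feature,
    FeatureSet,
    IntensityMatrix,
    ProbeAnnotation,
    ProbeSet,
    RegionSpec,
    reverse_complement,
)
from .qc import gc_content

_BASES = np.array(list("ACGT"))

# fixed fan-out offsets from the master seed (kept < 2**31 by masking)
_SEED_GENOME = 11
_SEED_PROBES = 23
_SEED_INTENSITY = 37
_SEED_FEATURES = 53
_SEED_EXPRESSION = 71


def _child_seed(master: int, offset: int) -> int:
    return int((master * 1_000_003 + offset) % (2**31 - 1))


@dataclass
class PeakBlock:
    chrom: str
    start: int
    end: int
    shift: float  # enrichment in units of the noise sd


@dataclass
class TruthTable:
    """Ground truth fully determining a generated dataset (given the seed)."""

    master_seed: int
    expected_class: Dict[str, str] = field(default_factory=dict)
    planted_starts: Dict[str, Tuple[str, int]] = field(default_factory=dict)
    gc_slope: float = 0.0
    position_effects: Dict[Tuple[str, int], float] = field(default_factory=dict)
    peak_blocks: List[PeakBlock] = field(default_factory=list)
    expression_region: Optional[str] = None
    expression_slope: float = 0.0
    expression_noise_sd: float = 0.0


def generate_genome(
    lengths: Mapping[str, int], gc_fraction: float = 0.4, seed: int = 0
) -> Dict[str, str]:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction."""
    rng = np.random.default_rng(_child_seed(seed, _SEED_GENOME))
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    genome = {}
    for chrom in sorted(lengths):
        codes = rng.choice(4, size=lengths[chrom], p=p)
        genome[chrom] = "".join(_BASES[codes])
    return genome


def _count_occurrences(genome: Mapping[str, str], seq: str) -> int:
    """Occurrences of seq on both strands, overlapping counted (oracle-grade)."""
    total = 0
    rc = reverse_complement(seq)
    for text in genome.values():
        for pat in ({seq, rc}):
            start = text.find(pat)
            while start != -1:
                total += 1
                start = text.find(pat, start + 1)
    return total


def plant_probes(
    genome: Dict[str, str],
    spacing: int = 20,
    probe_length: int = 25,
    dup_fraction: float = 0.0,
    scramble_fraction: float = 0.0,
    seed: int = 0,
    appendix_per_dup: int = 40,
    verify: bool = True,
) -> Tuple[ProbeSet, Dict[str, str], TruthTable]:
    """Cut probes from the genome; plant duplicates and scrambles.

    Probes are genome substrings every ``spacing`` bp. A ``dup_fraction``
    of them get their sequence copied into a reserved appendix chromosome
    (expected classification "multiple"); a ``scramble_fraction`` are
    replaced by random sequences absent from both genome strands (expected
    "none"); the rest are expected "unique". Returns the probe set, the
    genome extended with the appendix, and the truth table. With
    ``verify=True`` the realized occurrence counts are checked against the
    intended classes (naive counting) and a mismatch raises.
    """
    rng = np.random.default_rng(_child_seed(seed, _SEED_PROBES))
    probe_ids: List[str] = []
    sequences: List[str] = []
    sources: List[Tuple[str, int]] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for start in range(0, len(seq) - probe_length + 1, spacing):
            sub = seq[start : start + probe_length]
            if "N" in sub:
                continue
            probe_ids.append(f"p_{chrom}_{start}")
            sequences.append(sub)
            sources.append((chrom, start))
    n = len(probe_ids)
    n_dup = int(round(dup_fraction * n))
    n_scramble = int(round(scramble_fraction * n))
    chosen = rng.choice(n, size=n_dup + n_scramble, replace=False)
    dup_idx = sorted(int(i) for i in chosen[:n_dup])
    scramble_idx = sorted(int(i) for i in chosen[n_dup:])

    truth = TruthTable(master_seed=seed)
    for i, pid in enumerate(probe_ids):
        truth.expected_class[pid] = "unique"
        truth.planted_starts[pid] = sources[i]

    # scrambles: random sequences verified absent from both strands
    full_text = "".join(genome[c] for c in sorted(genome))
    for i in scramble_idx:
        while True:
            cand = "".join(_BASES[rng.choice(4, size=probe_length)])
            if (
                cand not in full_text
                and reverse_complement(cand) not in full_text
                and cand not in sequences
            ):
                break
        sequences[i] = cand
        truth.expected_class[probe_ids[i]] = "none"
        del truth.planted_starts[probe_ids[i]]

    # duplicates: second copies written into a reserved appendix chromosome,
    # separated by random spacer so they cannot collide with each other
    extended = dict(genome)
    if dup_idx:
        parts: List[str] = []
        for i in dup_idx:
            spacer = "".join(
                _BASES[rng.choice(4, size=appendix_per_dup - probe_length)]
            )
            parts.append(sequences[i] + spacer)
            truth.expected_class[probe_ids[i]] = "multiple"
            del truth.planted_starts[probe_ids[i]]
        extended["appendix"] = "".join(parts)

    probes = ProbeSet(
        probe_ids=probe_ids,
        sequences=sequences,
        array_x=np.arange(n) % 512,
        array_y=np.arange(n) // 512,
    )
    if verify:
        _verify_truth(extended, probes, truth)
    return probes, extended, truth


def _verify_truth(
    genome: Mapping[str, str], probes: ProbeSet, truth: TruthTable
) -> None:
    for pid, seq in zip(probes.probe_ids, probes.sequences):
        count = _count_occurrences(genome, seq)
        expected = truth.expected_class[pid]
        realized = "none" if count == 0 else ("unique" if count == 1 else "multiple")
        if realized != expected:
            raise RuntimeError(
                f"planting failed for {pid}: expected {expected}, "
                f"realized {realized} ({count} hits); re-seed the generator"
            )


def annotation_from_truth(probes: ProbeSet, truth: TruthTable) -> ProbeAnnotation:
    """The annotation a correct remapper must produce for a planted fixture."""
    entries: Dict[str, List[Tuple[int, int, str]]] = {}
    for i, pid in enumerate(probes.probe_ids):
        if truth.expected_class[pid] != "unique":
            continue
        chrom, start = truth.planted_starts[pid]
        entries.setdefault(chrom, []).append((i, start, "+"))
    for chrom in entries:
        entries[chrom].sort(key=lambda e: (e[1], e[0]))
    report = {
        cls: sum(1 for v in truth.expected_class.values() if v == cls)
        for cls in ("unique", "none", "multiple")
    }
    return ProbeAnnotation(
        entries=entries, match_report=report, probe_length=probes.probe_length
    )


@dataclass
class IntensityModel:
    """Log-scale generative model for probe intensities."""

    baseline: float = 8.0
    gc_slope: float = 0.0
    position_effects: Dict[Tuple[str, int], float] = field(default_factory=dict)
    peak_blocks: List[PeakBlock] = field(default_factory=list)
    noise_sd: float = 0.25
    n_ip: int = 2
    n_ref: int = 1


def simulate_intensities(
    probes: ProbeSet,
    anno: ProbeAnnotation,
    model: IntensityModel,
    seed: int = 0,
) -> Tuple[IntensityMatrix, TruthTable]:
    """Draw raw intensities under the log-scale bias + enrichment model.

    log2 value = baseline + gc_slope * GC + sum of position effects
    (+ shift * noise_sd inside a planted block, IP arrays only)
    + N(0, noise_sd^2). Reference arrays share the sequence biases but no
    enrichment. The returned matrix is on the raw scale (2**log2 value).
    """
    rng = np.random.default_rng(_child_seed(seed, _SEED_INTENSITY))
    n = probes.n_probes
    gc = np.array([gc_content(s) for s in probes.sequences], dtype=float)
    base = model.baseline + model.gc_slope * gc
    for (nuc, pos), delta in model.position_effects.items():
        hits = np.array([s[pos] == nuc for s in probes.sequences])
        base = base + delta * hits
    in_block = np.zeros(n, dtype=bool)
    for block in model.peak_blocks:
        if block.chrom not in anno.entries:
            continue
        idx, starts = anno.chrom_arrays(block.chrom)
        sel = (starts >= block.start) & (starts < block.end)
        in_block[idx[sel]] = True
    shift = np.zeros(n)
    for block in model.peak_blocks:
        if block.chrom not in anno.entries:
            continue
        idx, starts = anno.chrom_arrays(block.chrom)
        sel = (starts >= block.start) & (starts < block.end)
        shift[idx[sel]] = block.shift * model.noise_sd
    cols = []
    meta = []
    for j in range(model.n_ip):
        noise = rng.normal(0.0, model.noise_sd, size=n)
        cols.append(base + shift + noise)
        meta.append(ArrayMeta(name=f"ip_{j + 1}", role="IP"))
    for j in range(model.n_ref):
        noise = rng.normal(0.0, model.noise_sd, size=n)
        cols.append(base + noise)
        meta.append(ArrayMeta(name=f"ref_{j + 1}", role="reference"))
    values = np.exp2(np.column_stack(cols))
    truth = TruthTable(
        master_seed=seed,
        gc_slope=model.gc_slope,
        position_effects=dict(model.position_effects),
        peak_blocks=list(model.peak_blocks),
    )
    return IntensityMatrix(values=values, array_meta=meta, scale_tag="raw"), truth


def generate_features(
    genome: Mapping[str, str],
    n_features: int,
    length_range: Tuple[int, int] = (600, 2400),
    seed: int = 0,
    exclude_chroms: Sequence[str] = ("appendix",),
) -> FeatureSet:
    """Random non-overlapping gene features with alternating strands."""
    rng = np.random.default_rng(_child_seed(seed, _SEED_FEATURES))
    chroms = [c for c in sorted(genome) if c not in exclude_chroms]
    features: List[Feature] = []
    total_len = sum(len(genome[c]) for c in chroms)
    per_chrom = {
        c: max(1, int(round(n_features * len(genome[c]) / total_len)))
        for c in chroms
    }
    for chrom in chroms:
        L = len(genome[chrom])
        k = per_chrom[chrom]
        slot = L // k
        for j in range(k):
            lo, hi = length_range
            flen = int(rng.integers(lo, min(hi, max(lo + 1, slot - 100)) + 1))
            start = j * slot + int(rng.integers(0, max(1, slot - flen)))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    feature_id=f"g_{chrom}_{j}",
                    chrom=chrom,
                    start=start,
                    end=start + flen,
                    strand=strand,
                )
            )
    return FeatureSet(features=features[:n_features] if n_features else features)


def simulate_expression(
    features: FeatureSet,
    occupancy: np.ndarray,
    slope: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    region_id: str = "",
) -> Tuple[Dict[str, float], TruthTable]:
    """Expression tied linearly to region occupancy plus Gaussian noise."""
    rng = np.random.default_rng(_child_seed(seed, _SEED_EXPRESSION))
    occupancy = np.asarray(occupancy, dtype=float)
    noise = rng.normal(0.0, noise_sd, size=len(occupancy))
    expr = slope * occupancy + noise
    table = {
        fid: float(v)
        for fid, v in zip(features.ids, expr)
        if not np.isnan(v)
    }
    truth = TruthTable(
        master_seed=seed,
        expression_region=region_id,
        expression_slope=slope,
        expression_noise_sd=noise_sd,
    )
    return table, truth


@dataclass
class FixtureConfig:
    """Desk-scale default fixture: one 200 kb chromosome, ~10k probes."""

    chrom_lengths: Dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    gc_fraction: float = 0.4
    spacing: int = 20
    probe_length: int = 25
    dup_fraction: float = 0.0
    scramble_fraction: float = 0.0
    n_peaks: int = 20
    peak_width: int = 300
    # 8 noise-sd = 2 log2 units at the default noise: a four-fold
    # enrichment, typical for a clearly bound region
    peak_shift: float = 8.0
    gc_slope: float = 0.0
    noise_sd: float = 0.25
    n_ip: int = 2
    n_ref: int = 1
    n_features: int = 80
    expression_slope: float = 2.0
    expression_noise_sd: float = 0.5


@dataclass
class Fixture:
    genome: Dict[str, str]
    probes: ProbeSet
    annotation: ProbeAnnotation
    intensities: IntensityMatrix
    features: FeatureSet
    expression: Dict[str, float]
    truth: TruthTable
    config: FixtureConfig


def default_fixture(seed: int = 0, config: Optional[FixtureConfig] = None) -> Fixture:
    """Generate the full default dataset used across the test-suite."""
    cfg = config or FixtureConfig()
    genome = generate_genome(cfg.chrom_lengths, cfg.gc_fraction, seed)
    probes, genome, plant_truth = plant_probes(
        genome,
        spacing=cfg.spacing,
        probe_length=cfg.probe_length,
        dup_fraction=cfg.dup_fraction,
        scramble_fraction=cfg.scramble_fraction,
        seed=seed,
        verify=False,
    )
    anno = annotation_from_truth(probes, plant_truth)
    rng = np.random.default_rng(_child_seed(seed, _SEED_INTENSITY + 1))
    blocks: List[PeakBlock] = []
    chroms = sorted(cfg.chrom_lengths)
    for _ in range(cfg.n_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_lengths[chrom] - cfg.peak_width))
        blocks.append(
            PeakBlock(chrom=chrom, start=start, end=start + cfg.peak_width, shift=cfg.peak_shift)
        )
    model = IntensityModel(
        gc_slope=cfg.gc_slope,
        peak_blocks=blocks,
        noise_sd=cfg.noise_sd,
        n_ip=cfg.n_ip,
        n_ref=cfg.n_ref,
    )
    intensities, int_truth = simulate_intensities(probes, anno, model, seed)
    features = generate_features(genome, cfg.n_features, seed=seed)

    from .normalization import normalize_ip_reference
    from .profiles import RegionSpec as _RS, region_mean_occupancy

    enrichment = normalize_ip_reference(intensities).enrichment
    region = _RS("elongation", "TSS", 100, "TTS", -100)
    occ, _ = region_mean_occupancy(anno, enrichment, features, region)
    expression, expr_truth = simulate_expression(
        features,
        occ,
        slope=cfg.expression_slope,
        noise_sd=cfg.expression_noise_sd,
        seed=seed,
        region_id=region.region_id,
    )
    truth = TruthTable(
        master_seed=seed,
        expected_class=plant_truth.expected_class,
        planted_starts=plant_truth.planted_starts,
        gc_slope=int_truth.gc_slope,
        position_effects=int_truth.position_effects,
        peak_blocks=int_truth.peak_blocks,
        expression_region=expr_truth.expression_region,
        expression_slope=expr_truth.expression_slope,
        expression_noise_sd=expr_truth.expression_noise_sd,
    )
    return Fixture(
        genome=genome,
        probes=probes,
        annotation=anno,
        intensities=intensities,
        features=features,
        expression=expression,
        truth=truth,
        config=cfg,
    )
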