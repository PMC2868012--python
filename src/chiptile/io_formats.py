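"""Readers and writers for the toolkit's external formats.

Text stand-ins replace the binary Affymetrix formats: the probe table
(tab-delimited id/sequence/x/y) stands in for BPMAP content and the
intensity table (probes x arrays) for CEL content. Genomic features come in
as GFF3 (1-based inclusive, converted to 0-based half-open on read). All
text output is UTF-8 with LF line endings and tab separators, and floats
are serialized with repr-shortest form so identical inputs give
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ArrayMeta,
    Feature,
    FeatureSet,
    IntensityMatrix,
    PeakCall,
    ProbeAnnotation,
    ProbeSet,
    ValidationError,
)


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a (possibly multi-record) FASTA into chrom -> uppercase sequence.

    Record ids are the first whitespace-delimited token of the header.
    """
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValidationError(f"duplicate FASTA record id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValidationError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    lines: List[str] = []
    for chrom in sorted(genome):
        lines.append(f">{chrom}")
        seq = genome[chrom]
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_probe_table(path: str | Path) -> ProbeSet:
    """Probe table: tab-delimited probe_id / sequence / x / y with header."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sequence": str})
    required = {"probe_id", "sequence", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"probe table missing columns {sorted(missing)}")
    return ProbeSet(
        probe_ids=df["probe_id"].tolist(),
        sequences=df["sequence"].tolist(),
        array_x=df["x"].to_numpy(),
        array_y=df["y"].to_numpy(),
    )


def write_probe_table(probes: ProbeSet, path: str | Path) -> None:
    lines = ["probe_id\tsequence\tx\ty"]
    for i in range(probes.n_probes):
        lines.append(
            f"{probes.probe_ids[i]}\t{probes.sequences[i]}"
            f"\t{probes.array_x[i]}\t{probes.array_y[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_annotation_table(path: str | Path, probes: ProbeSet) -> ProbeAnnotation:
    """Read a corrected annotation table written by the remap stage."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    index_of = {pid: i for i, pid in enumerate(probes.probe_ids)}
    entries: Dict[str, List[Tuple[int, int, str]]] = {}
    for row in df.itertuples(index=False):
        if row.probe_id not in index_of:
            raise ValidationError(f"annotation references unknown probe {row.probe_id!r}")
        entries.setdefault(row.chrom, []).append(
            (index_of[row.probe_id], int(row.start), row.strand)
        )
    report_path = Path(str(path) + ".report.txt")
    report = {"unique": 0, "none": 0, "multiple": 0}
    if report_path.exists():
        for line in report_path.read_text().splitlines():
            k, v = line.split("\t")
            report[k] = int(v)
    return ProbeAnnotation(
        entries=entries, match_report=report, probe_length=probes.probe_length
    )


def read_gff(path: str | Path) -> FeatureSet:
    """Read GFF3 features into 0-based half-open coordinates.

    feature_id is the ID attribute, falling back to "seqid:start-end" (the
    1-based printed coordinates). Strandless ('.') features are excluded —
    anchored analyses need an orientation — and counted, as are malformed
    lines (start > end, unparsable records).
    """
    skipped = {"strandless": 0, "malformed": 0}
    malformed_lines: List[int] = []
    features: List[Feature] = []
    # Pre-pass: drop structurally broken lines (recording their numbers) so
    # one bad record does not abort the whole import.
    clean: List[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            clean.append(line)
            continue
        cols = line.split("\t")
        ok = len(cols) == 9
        if ok:
            try:
                start, end = int(cols[3]), int(cols[4])
                ok = start <= end and start >= 1
            except ValueError:
                ok = False
        if ok:
            clean.append(line)
        else:
            skipped["malformed"] += 1
            malformed_lines.append(lineno)
    db = gffutils.create_db(
        "\n".join(clean) + "\n",
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for rec in db.all_features():
        if rec.strand not in ("+", "-"):
            skipped["strandless"] += 1
            continue
        fid = rec.attributes.get("ID", [f"{rec.seqid}:{rec.start}-{rec.end}"])[0]
        features.append(
            Feature(
                feature_id=fid,
                chrom=rec.seqid,
                start=rec.start - 1,  # GFF is 1-based inclusive
                end=rec.end,
                strand=rec.strand,
            )
        )
    fs = FeatureSet(features=features, skipped=skipped)
    fs.malformed_lines = malformed_lines  # type: ignore[attr-defined]
    return fs


def write_gff(features: FeatureSet, path: str | Path, source: str = "chiptile") -> None:
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            f"{f.chrom}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t."
            f"\tID={f.feature_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_intensity_table(
    path: str | Path,
    probe_order: ProbeSet,
    roles: Optional[Mapping[str, str]] = None,
) -> IntensityMatrix:
    """Read a probes x arrays intensity table and align rows to the ProbeSet.

    Header row names the arrays; the first column is probe_id. Rows are
    reordered to the ProbeSet's order. Probes of the ProbeSet missing from
    the table are an error; extra table rows are dropped (with a count kept
    on the returned object as ``n_extra_dropped``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ValidationError("intensity table must have a probe_id column")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate probe row {dup!r}")
    df = df.set_index("probe_id")
    missing = [p for p in probe_order.probe_ids if p not in df.index]
    if missing:
        raise ValidationError(f"intensity table missing probes, e.g. {missing[0]!r}")
    n_extra = len(df.index.difference(probe_order.probe_ids))
    df = df.loc[probe_order.probe_ids]
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    roles = roles or {}
    meta = [
        ArrayMeta(name=c, role=roles.get(c, "IP")) for c in df.columns
    ]
    mat = IntensityMatrix(values=values, array_meta=meta, scale_tag="raw")
    mat.n_extra_dropped = n_extra  # type: ignore[attr-defined]
    return mat


def write_intensity_table(
    mat: IntensityMatrix, probes: ProbeSet, path: str | Path
) -> None:
    lines = ["probe_id\t" + "\t".join(mat.array_names)]
    for i, pid in enumerate(probes.probe_ids):
        row = "\t".join(repr(float(v)) for v in mat.values[i])
        lines.append(f"{pid}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_expression_table(path: str | Path) -> Dict[str, float]:
    """Two-column gene -> value table with header."""
    df = pd.read_csv(path, sep="\t")
    gene_col, value_col = df.columns[:2]
    return {str(g): float(v) for g, v in zip(df[gene_col], df[value_col])}


def write_expression_table(
    expression: Mapping[str, float], path: str | Path
) -> None:
    lines = ["feature_id\texpression"]
    for fid in expression:
        lines.append(f"{fid}\t{repr(float(expression[fid]))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_values_table(
    values: np.ndarray, probes: ProbeSet, path: str | Path, column: str = "enrichment"
) -> None:
    """Per-probe value vector keyed by probe id (e.g. enrichment scores)."""
    lines = [f"probe_id\t{column}"]
    for pid, v in zip(probes.probe_ids, values):
        lines.append(f"{pid}\t{repr(float(v))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_values_table(path: str | Path, probe_order: ProbeSet) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}).set_index("probe_id")
    missing = [p for p in probe_order.probe_ids if p not in df.index]
    if missing:
        raise ValidationError(f"values table missing probes, e.g. {missing[0]!r}")
    return df.loc[probe_order.probe_ids].iloc[:, 0].to_numpy(dtype=float)


def peak_score_to_bed(score: float, lo: float = 0.0, hi: float = 10.0) -> int:
    """Affine map of a peak score onto the BED 0-1000 range, clamped.

    Scores <= ``lo`` map to 0 and >= ``hi`` to 1000.
    """
    if score <= lo:
        return 0
    if score >= hi:
        return 1000
    return int(round(1000 * (score - lo) / (hi - lo)))


def write_peaks_bed(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """BED6: chrom, start0, end, name=peak_i, clamped score, strand '.'."""
    lines = []
    for i, p in enumerate(peaks):
        lines.append(
            f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}"
            f"\t{peak_score_to_bed(p.peak_score)}\t."
        )
    Path(path).write_text(
        ("\n".join(lines) + "\n") if lines else "", encoding="utf-8", newline="\n"
    )


def write_track_wig(
    anno: ProbeAnnotation,
    values: np.ndarray,
    path: str | Path,
    track_name: str = "chiptile",
) -> int:
    """Fixed-span variableStep wiggle of per-probe values (1-based starts).

    NaN values are skipped; returns the skip count.
    """
    values = np.asarray(values, dtype=float)
    span = anno.probe_length
    lines = [f'track type=wiggle_0 name="{track_name}"']
    n_skipped = 0
    for chrom in sorted(anno.entries):
        lines.append(f"variableStep chrom={chrom} span={span}")
        for idx, start, _strand in anno.entries[chrom]:
            v = values[idx]
            if np.isnan(v):
                n_skipped += 1
                continue
            lines.append(f"{start + 1}\t{repr(float(v))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return n_skipped
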