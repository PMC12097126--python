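"""Readers and writers for every external file the pipeline touches.

All readers validate strictly and reject malformed input rather than
repairing it.  Coordinates are 0-based half-open throughout; BED input
that "looks 1-based" is taken at face value and never auto-corrected.
"""

from __future__ import annotations

import io
import os
from bisect import bisect_right
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import GenomicInterval, PasRecord, SampleMeta, MotifPwm


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, path: str, n_min: int = 6):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise FormatError(
            f"{path}, line {lineno}: expected >= {n_min} tab-separated "
            f"fields, got {len(fields)}"
        )
    chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(
            f"{path}, line {lineno}: non-integer coordinates "
            f"{start_s!r}/{end_s!r}"
        ) from None
    score_s = fields[4]
    if score_s == ".":
        score = None
    else:
        try:
            score = float(score_s)
        except ValueError:
            raise FormatError(
                f"{path}, line {lineno}: score {score_s!r} is neither "
                "numeric nor '.'"
            ) from None
    strand = fields[5]
    if strand not in ("+", "-"):
        raise FormatError(
            f"{path}, line {lineno}: strand must be '+' or '-', "
            f"got {strand!r}"
        )
    if not (0 <= start < end):
        raise FormatError(
            f"{path}, line {lineno}: invalid interval [{start}, {end})"
        )
    family = fields[6] if len(fields) > 6 else None
    return GenomicInterval(chrom, start, end, strand, name, score, family)


def read_intervals_bed(path: str, with_family: bool = False
                       ) -> List[GenomicInterval]:
    """Read a BED6 (or BED6+family) file into sorted intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, path,
                                 n_min=7 if with_family else 6)
            out.append(iv)
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def read_pas_bed(path: str, min_score: float = 4.0) -> List[PasRecord]:
    """Read polyA sites from BED6; drop records with score < ``min_score``.

    The BED name field must be ``gene_id:pas_id``; every record must be a
    point feature (end - start == 1, the cleavage base).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, path)
            if iv.length != 1:
                raise FormatError(
                    f"{path}, line {lineno}: pAS must be a point feature "
                    f"(end - start == 1), got length {iv.length}"
                )
            if ":" not in iv.name:
                raise FormatError(
                    f"{path}, line {lineno}: pAS name must be "
                    f"'gene_id:pas_id', got {iv.name!r}"
                )
            if iv.score is not None and iv.score < min_score:
                continue
            gene_id, pas_id = iv.name.split(":", 1)
            records.append(PasRecord(gene_id=gene_id, pas_id=pas_id,
                                     interval=iv))
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records


def write_pas_bed(records: List[PasRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            score = "." if iv.score is None else _fmt_num(iv.score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{r.gene_id}:{r.pas_id}\t{score}\t{iv.strand}\n")


def write_intervals_bed(intervals: List[GenomicInterval], path: str,
                        with_family: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else _fmt_num(iv.score)
            line = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t" \
                   f"{score}\t{iv.strand}"
            if with_family:
                line += f"\t{iv.family if iv.family is not None else '.'}"
            fh.write(line + "\n")


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.6f}"


DEFAULT_MERGE_WINDOW_NT = 24


def merge_pas_annotations(primary: List[PasRecord],
                          secondary: List[PasRecord],
                          merge_window_nt: int = DEFAULT_MERGE_WINDOW_NT
                          ) -> List[PasRecord]:
    """Combine two pAS annotation sources, keeping primary coordinates.

    A secondary record within ``merge_window_nt`` of a primary record of
    the same gene and strand is considered the same pAS and dropped (the
    primary source's coordinate is retained).  The matching window is a
    convention parameter, default 24 nt.
    """
    by_gene: Dict[tuple, List[int]] = {}
    for r in primary:
        by_gene.setdefault((r.gene_id, r.interval.chrom, r.strand),
                           []).append(r.position)
    out = list(primary)
    for r in secondary:
        near = by_gene.get((r.gene_id, r.interval.chrom, r.strand), ())
        if any(abs(r.position - p) <= merge_window_nt for p in near):
            continue
        out.append(r)
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


# ---------------------------------------------------------------------------
# Quantification tables and sample metadata
# ---------------------------------------------------------------------------

def read_quant_table(path) -> pd.DataFrame:
    """Read a TSV of isoform TPMs into a (gene_id, pas_id)-indexed frame.

    Columns after the two key columns are sample ids; values must be
    finite and >= 0; duplicate keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "pas_id": str})
    for col in ("gene_id", "pas_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.set_index(["gene_id", "pas_id"])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate (gene_id, pas_id) key {dup}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite TPM value")
    if (values < 0).any():
        raise FormatError(f"{path}: negative TPM value")
    return df.astype(float)


def write_quant_table(table: pd.DataFrame, path) -> None:
    """Write a (gene_id, pas_id)-indexed table as TSV with 6-decimal reals."""
    table.to_csv(path, sep="\t", float_format="%.6f")


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    """Generic TSV writer: fixed column order, 6-decimal reals."""
    table.to_csv(path, sep="\t", float_format="%.6f", index=index)


def read_sample_meta(path) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str,
                                            "stage": str})
    required = {"sample_id", "tissue", "stage", "stage_index", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    metas = [SampleMeta(r.sample_id, r.tissue, r.stage,
                        int(r.stage_index), int(r.replicate))
             for r in df.itertuples()]
    keys = {(m.tissue, m.stage, m.replicate) for m in metas}
    if len(keys) != len(metas):
        raise FormatError(f"{path}: duplicate (tissue, stage, replicate)")
    return metas


def write_sample_meta(metas: List[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.tissue, m.stage, m.stage_index, m.replicate)
         for m in metas],
        columns=["sample_id", "tissue", "stage", "stage_index", "replicate"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Conservation track (bedGraph)
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Sparse per-base score track from non-overlapping bedGraph intervals.

    Positions outside every interval return NaN ("missing"); missing
    values are meant to be excluded from averages, never imputed as 0.
    """

    def __init__(self, intervals: Dict[str, tuple]):
        # intervals: chrom -> (starts, ends, scores) sorted arrays
        self._data = intervals

    @classmethod
    def from_records(cls, records) -> "ConservationTrack":
        """Build from an iterable of (chrom, start, end, score)."""
        by_chrom: Dict[str, list] = {}
        for chrom, start, end, score in records:
            if not (0 <= start < end):
                raise FormatError(
                    f"invalid bedGraph interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, float(score)))
        data = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = np.array([i[0] for i in items], dtype=np.int64)
            ends = np.array([i[1] for i in items], dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                j = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise FormatError(
                    f"overlapping bedGraph intervals on {chrom} near "
                    f"{starts[j + 1]}")
            scores = np.array([i[2] for i in items], dtype=float)
            data[chrom] = (starts, ends, scores)
        return cls(data)

    def iter_records(self):
        for chrom in sorted(self._data):
            starts, ends, scores = self._data[chrom]
            for s, e, v in zip(starts, ends, scores):
                yield chrom, int(s), int(e), float(v)

    def score_at(self, chrom: str, pos: int) -> float:
        """Score of one base, NaN if missing."""
        if chrom not in self._data:
            return float("nan")
        starts, ends, scores = self._data[chrom]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return float(scores[i])
        return float("nan")

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); NaN where missing."""
        out = np.full(end - start, np.nan)
        if chrom not in self._data or end <= start:
            return out
        starts, ends, scores = self._data[chrom]
        i = max(0, bisect_right(starts, start) - 1)
        while i < len(starts) and starts[i] < end:
            lo = max(int(starts[i]), start)
            hi = min(int(ends[i]), end)
            if lo < hi:
                out[lo - start:hi - start] = scores[i]
            i += 1
        return out


def read_conservation_bedgraph(path: str) -> ConservationTrack:
    """Read a bedGraph into a sparse position -> score track."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}, line {lineno}: expected 4 fields, "
                    f"got {len(fields)}")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]),
                                float(fields[3])))
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}: malformed bedGraph line"
                ) from None
    return ConservationTrack.from_records(records)


def write_conservation_bedgraph(track: ConservationTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.6f}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA into {name: uppercase sequence}."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def check_intervals_against_genome(intervals, genome: Dict[str, str]) -> None:
    """Raise if any interval names a chromosome absent from the genome
    or runs past its end."""
    for iv in intervals:
        if iv.chrom not in genome:
            raise FormatError(
                f"interval {iv.name!r}: chromosome {iv.chrom!r} absent "
                "from genome")
        if iv.end > len(genome[iv.chrom]):
            raise FormatError(
                f"interval {iv.name!r}: end {iv.end} beyond {iv.chrom} "
                f"length {len(genome[iv.chrom])}")


# ---------------------------------------------------------------------------
# MEME-minimal PWMs
# ---------------------------------------------------------------------------

def read_meme_pwms(path: str) -> List[MotifPwm]:
    """Read motifs from MEME minimal format (letter-probability matrices).

    Each probability row must sum to 1 +- 1e-6.
    """
    motifs = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            vals = lines[i].split()
            freq = {vals[j]: float(vals[j + 1])
                    for j in range(0, len(vals), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability"):
                i += 1
            if i >= len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id} lacks a "
                    "letter-probability matrix")
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    row = [float(x) for x in parts]
                except ValueError:
                    break
                rows.append(row)
                i += 1
            matrix = np.array(rows)
            if matrix.size == 0:
                raise FormatError(f"{path}: motif {motif_id} has no rows")
            if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
                raise FormatError(
                    f"{path}: motif {motif_id} has a probability row not "
                    "summing to 1 +- 1e-6")
            motifs.append(MotifPwm(motif_id, matrix, background))
            continue
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no motifs found")
    return motifs


def write_meme_pwms(motifs: List[MotifPwm], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 "
                     f"w= {m.width}\n")
            for row in m.matrix:
                fh.write("  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# polyA-signal catalog (data file, not code)
# ---------------------------------------------------------------------------

def read_signal_catalog(path: Optional[str] = None) -> List[str]:
    """Read the ordered polyA-signal hexamer catalog.

    Defaults to the packaged 18-hexamer list (from the cited PolyASite
    signal set; verify against PolyASite when substituting your own).
    Order encodes priority: AATAAA first, ATTAAA second.
    """
    if path is None:
        path = os.path.join(os.path.dirname(__file__), "data",
                            "polya_signals.txt")
    hexamers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            h = line.strip().upper()
            if not h or h.startswith("#"):
                continue
            if len(h) != 6 or set(h) - set("ACGT"):
                raise FormatError(
                    f"{path}, line {lineno}: {h!r} is not a DNA hexamer")
            if h in hexamers:
                raise FormatError(
                    f"{path}, line {lineno}: duplicate hexamer {h}")
            hexamers.append(h)
    if hexamers[:2] != ["AATAAA", "ATTAAA"]:
        raise FormatError(
            f"{path}: catalog must start with AATAAA then ATTAAA")
    return hexamers
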