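"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: BED3/BED4 intervals, a minimal SAM dialect (mandatory
columns only, CIGAR ignored), a 4-column read TSV, FASTA, JASPAR-style PFM
text, fixed-step wiggle / bedGraph score tracks, and the TSV feature table.

All coordinates are 0-based half-open internally (BED convention); SAM's
1-based starts and wiggle's 1-based positions are converted on ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
#: per-cell pseudocount added to PFM counts before column normalization
PWM_PSEUDOCOUNT = 0.01
#: uniform nucleotide background used for log-odds scoring
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
#: significant digits used when printing numeric TSV values
TSV_PRECISION = 6


class ParseError(ValueError):
    """Malformed input data; carries the offending path and line number."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Read:
    """A mapped read interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    """Mapped reads plus the library size used for per-million normalization."""

    reads: list[Read]
    total_mapped: int

    def __post_init__(self):
        if self.total_mapped < 0:
            raise ValueError("total_mapped must be non-negative")


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with a background model."""

    motif_id: str
    matrix: np.ndarray  # (4, width) column-stochastic
    background: np.ndarray = field(
        default_factory=lambda: np.asarray(UNIFORM_BACKGROUND, dtype=float))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"PWM matrix must be 4 x width>=1, got {self.matrix.shape}")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1 within 1e-6")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


class ScoreTrack:
    """Sparse per-base score map; bases absent from the track score 0."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        # chrom -> (sorted positions, scores)
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, sc) in data.items():
                pos = np.asarray(pos, dtype=np.int64)
                sc = np.asarray(sc, dtype=float)
                order = np.argsort(pos, kind="stable")
                self._data[chrom] = (pos[order], sc[order])

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def region_scores(self, region: GenomicRegion) -> np.ndarray:
        """Per-base scores across ``region``; missing bases are 0."""
        out = np.zeros(region.length, dtype=float)
        entry = self._data.get(region.chrom)
        if entry is None:
            return out
        pos, sc = entry
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        out[pos[lo:hi] - region.start] = sc[lo:hi]
        return out


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Parse a BED3/BED4 file into regions, preserving file order."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            try:
                regions.append(GenomicRegion(fields[0], start, end, name))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path,
              scores: Sequence[float] | None = None) -> None:
    regions = list(regions)
    if scores is not None and len(scores) != len(regions):
        raise ValueError("scores length must match regions")
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or scores is not None:
                fields.append(r.name if r.name is not None else ".")
            if scores is not None:
                fields.append(_fmt(scores[i]))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Alignments (minimal SAM dialect or 4-column TSV)

_SAM_FLAG_UNMAPPED = 0x4
_SAM_FLAG_REVERSE = 0x10


def read_alignments(path: str | Path, min_mapq: int = 0) -> ReadSet:
    """Read mapped reads from SAM text or a chrom/start/end/strand TSV.

    SAM handling is deliberately minimal: only the 11 mandatory columns are
    consulted, the CIGAR is ignored, and the read span is POS..POS+len(SEQ)
    converted to 0-based half-open. Unmapped records (flag bit 4) and records
    below ``min_mapq`` are dropped; ``total_mapped`` counts retained records.
    """
    reads: list[Read] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) >= 11:
                read = _parse_sam_record(fields, path, lineno, min_mapq)
                if read is not None:
                    reads.append(read)
            elif len(fields) == 4:
                chrom, s, e, strand = fields
                try:
                    read = Read(chrom, int(s), int(e), strand)
                except ValueError as exc:
                    raise ParseError(str(exc), path, lineno) from None
                reads.append(read)
            else:
                raise ParseError(
                    f"expected SAM (11+ columns) or TSV (4 columns), got "
                    f"{len(fields)} columns", path, lineno)
    return ReadSet(reads=reads, total_mapped=len(reads))


def _parse_sam_record(fields: list[str], path, lineno, min_mapq) -> Read | None:
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq = int(fields[4])
    except ValueError:
        raise ParseError("non-integer SAM FLAG/POS/MAPQ", path, lineno) from None
    if flag & _SAM_FLAG_UNMAPPED:
        return None
    if mapq < min_mapq:
        return None
    seq = fields[9]
    if seq == "*":
        raise ParseError("SEQ '*' unsupported: read length unknown", path, lineno)
    start = pos - 1  # SAM is 1-based
    strand = "-" if flag & _SAM_FLAG_REVERSE else "+"
    return Read(fields[2], start, start + len(seq), strand)


def write_sam(read_set: ReadSet, path: str | Path,
              chrom_lengths: Mapping[str, int]) -> None:
    """Write reads as minimal single-end SAM records (fixed 'N' sequence)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, r in enumerate(read_set.reads):
            flag = 16 if r.strand == "-" else 0
            seq = "N" * r.length
            fh.write(f"read{i}\t{flag}\t{r.chrom}\t{r.start + 1}\t255\t"
                     f"{r.length}M\t*\t0\t0\t{seq}\t*\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file into a name -> sequence dict.

    Soft-masking (lowercase) is preserved; it encodes the repeat annotation
    used by the sequence-composition features.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, read_long_names=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def region_sequence(sequences: Mapping[str, str], region: GenomicRegion) -> str:
    if region.chrom not in sequences:
        raise KeyError(f"chromosome {region.chrom!r} absent from FASTA")
    seq = sequences[region.chrom]
    if region.end > len(seq):
        raise ValueError(
            f"region [{region.start}, {region.end}) exceeds {region.chrom} "
            f"length {len(seq)}")
    return seq[region.start:region.end]


# ---------------------------------------------------------------------------
# JASPAR-style PFM

def read_pwm(path: str | Path) -> list[PWM]:
    """Parse JASPAR-style PFM text into probability matrices.

    Accepts '>id' header lines followed by four base rows, either bare
    numbers or the bracketed 'A [ 1 2 3 ]' JASPAR flavor. Counts get a 0.01
    per-cell pseudocount and are normalized column-wise to probabilities.
    """
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    row_start_line = 0

    def flush(lineno: int):
        nonlocal rows, motif_id
        if motif_id is None and not rows:
            return
        if len(rows) != 4:
            raise ParseError(
                f"motif {motif_id!r} has {len(rows)} base rows, expected 4",
                path, lineno)
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ParseError(
                f"motif {motif_id!r} has rows of unequal width {sorted(widths)}",
                path, lineno)
        counts = np.asarray(rows, dtype=float) + PWM_PSEUDOCOUNT
        matrix = counts / counts.sum(axis=0, keepdims=True)
        pwms.append(PWM(motif_id or f"motif{len(pwms) + 1}", matrix))
        rows = []
        motif_id = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                motif_id = line[1:].split()[0] if line[1:].split() else None
                row_start_line = lineno
                continue
            # strip 'A [ ... ]' decoration if present
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError:
                raise ParseError(f"non-numeric PFM row: {line!r}", path, lineno) from None
            if not values:
                raise ParseError("empty PFM row", path, lineno)
            rows.append(values)
        flush(row_start_line)
    return pwms


def write_pwm(pwms: Iterable[PWM], path: str | Path, counts_scale: float = 100.0) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for b, row in zip(BASES, pwm.matrix * counts_scale):
                fh.write(b + " [ " + " ".join(_fmt(v) for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# Score tracks (fixed-step wiggle or bedGraph)

def read_score_track(path: str | Path) -> ScoreTrack:
    """Read per-base conservation-style scores.

    Supports fixed-step wiggle (``fixedStep chrom=.. start=.. step=1``,
    1-based starts) and 4-column bedGraph (0-based half-open)."""
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    mode = None  # "wig" within a fixedStep block, else bedGraph per line
    chrom, cursor, step = None, 0, 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(tok.split("=", 1) for tok in line.split()[1:])
                try:
                    chrom = attrs["chrom"]
                    cursor = int(attrs["start"]) - 1  # wiggle is 1-based
                    step = int(attrs.get("step", 1))
                except (KeyError, ValueError):
                    raise ParseError("malformed fixedStep header", path, lineno) from None
                mode = "wig"
                continue
            fields = line.split()
            if mode == "wig" and len(fields) == 1:
                pos_list, sc_list = per_chrom.setdefault(chrom, ([], []))
                try:
                    sc_list.append(float(fields[0]))
                except ValueError:
                    raise ParseError("non-numeric wiggle value", path, lineno) from None
                pos_list.append(cursor)
                cursor += step
            elif len(fields) == 4:
                mode = None
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError:
                    raise ParseError("malformed bedGraph line", path, lineno) from None
                if end <= start:
                    raise ParseError("bedGraph end <= start", path, lineno)
                pos_list, sc_list = per_chrom.setdefault(fields[0], ([], []))
                pos_list.extend(range(start, end))
                sc_list.extend([value] * (end - start))
            else:
                raise ParseError("unrecognized score-track line", path, lineno)
    return ScoreTrack({c: (np.asarray(p), np.asarray(s))
                       for c, (p, s) in per_chrom.items()})


# ---------------------------------------------------------------------------
# Feature tables and density matrices (TSV)

def _fmt(value: float) -> str:
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.{TSV_PRECISION}g}"


def write_feature_table(table: pd.DataFrame, labels: Sequence[int],
                        path: str | Path) -> None:
    """Write a feature table TSV: sample_id, feature columns, label.

    Numeric values are printed with 6 significant digits, so a written table
    re-reads to exactly its printed precision."""
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels length must match table rows")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dupes}")
    if "label" in table.columns:
        raise ValueError("feature table must not already contain a 'label' column")
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", *table.columns, "label"]) + "\n")
        ids = table.index.astype(str)
        values = table.to_numpy()
        for i in range(len(table)):
            row = [ids[i], *(_fmt(v) for v in values[i]), str(int(labels[i]))]
            fh.write("\t".join(row) + "\n")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a feature-table TSV back into (features DataFrame, label vector)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"duplicate column names: {dupes}", path)
    if "label" not in df.columns:
        raise ParseError("missing required 'label' column", path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
        df.index.name = None
    labels = df.pop("label").to_numpy(dtype=int)
    return df, labels


def write_density_matrix(regions: Sequence[GenomicRegion], matrix: pd.DataFrame,
                         path: str | Path) -> None:
    """Write densities with their region coordinates (chrom/start/end first)."""
    if len(regions) != len(matrix):
        raise ValueError("regions length must match matrix rows")
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "start", "end", *matrix.columns]) + "\n")
        values = matrix.to_numpy()
        for r, row in zip(regions, values):
            fh.write("\t".join([r.chrom, str(r.start), str(r.end),
                                *(_fmt(v) for v in row)]) + "\n")


def read_density_matrix(path: str | Path) -> tuple[list[GenomicRegion], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ParseError(f"missing required {col!r} column", path)
    regions = [GenomicRegion(str(c), int(s), int(e))
               for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    matrix = df.drop(columns=["chrom", "start", "end"])
    return regions, matrix
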