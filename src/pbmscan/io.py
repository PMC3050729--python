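"""Readers and writers for the formats the tool touches.

E-score tables are whitespace/tab-delimited text in the style of published PBM
downloads: octamer, reverse-complement octamer, E-score, and optionally a
median-intensity column (ignored). FASTA goes through Bio.SeqIO; BED6 output
and TRANSFAC matrix input are handled here because their dialects are small
and exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import kmers
from .errors import (
    CompletenessError,
    ParseError,
    PbmScanError,
    ScoreRangeError,
    SymmetryError,
)
from .kmers import N_OCTAMERS, RC_CODES, decode_octamer, encode_octamer, reverse_complement

__all__ = [
    "EScoreTable",
    "PwmMatrix",
    "BindingMeasurement",
    "SeqRecord",
    "read_escore_table",
    "write_escore_table",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_transfac_matrix",
    "write_transfac_matrix",
    "read_measurements",
]


# ---------------------------------------------------------------------------
# E-score tables
# ---------------------------------------------------------------------------


@dataclass
class EScoreTable:
    """A total map from every octamer to its PBM enrichment score.

    ``values`` is indexed by octamer code (see :mod:`pbmscan.kmers`). The table
    is total (no NaN), bounded in [-0.5, 0.5] and reverse-complement symmetric
    once validated; :func:`pbmscan.kmers.build_dense_array` re-checks and wraps
    it for scanning.
    """

    values: np.ndarray
    tf_name: str = ""
    source: str = ""

    def score(self, octamer: str) -> float:
        return float(self.values[encode_octamer(octamer)])

    __getitem__ = score

    def validate(self) -> None:
        kmers.DenseScoreArray(self.values, self.tf_name)  # raises on violation

    @classmethod
    def from_dict(
        cls,
        scores: dict[str, float],
        tf_name: str = "",
        source: str = "",
        default: float | None = None,
    ) -> "EScoreTable":
        """Build a table from an octamer -> score mapping, mirror-filling
        reverse complements. ``default`` fills octamers not listed (handy for
        toy tables); without it the mapping must cover every octamer pair.
        """
        values = np.full(N_OCTAMERS, np.nan)
        for oct_, s in scores.items():
            c = encode_octamer(oct_)
            values[c] = s
            values[RC_CODES[c]] = s
        if default is not None:
            values[np.isnan(values)] = float(default)
        missing = int(np.isnan(values).sum())
        if missing:
            raise CompletenessError(f"table incomplete: {missing} octamers missing")
        table = cls(values, tf_name=tf_name, source=source)
        table.validate()
        return table

    def to_dict(self) -> dict[str, float]:
        return {decode_octamer(c): float(self.values[c]) for c in range(N_OCTAMERS)}


def read_escore_table(path: str | Path, strict_symmetry: bool = False, tf_name: str = "") -> EScoreTable:
    """Read a UniPROBE-style 8-mer E-score table.

    Columns: octamer, reverse-complement octamer, E-score[, intensity...];
    ``#`` lines ignored. Both listed octamers receive the score (mirror-fill).
    Conflicting scores for a pair raise :class:`SymmetryError` when
    ``strict_symmetry`` and are averaged with a warning otherwise. The final
    table must cover all 65,536 octamers.
    """
    path = Path(path)
    values = np.full(N_OCTAMERS, np.nan)
    conflicts = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"expected >= 3 columns, got {len(fields)}", line=lineno)
            fwd, rev, score_s = fields[0], fields[1], fields[2]
            # skip a header row of column names
            if lineno == 1 and not _is_octamerish(fwd):
                continue
            try:
                c_fwd = encode_octamer(fwd)
                c_rev = encode_octamer(rev)
            except PbmScanError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"bad E-score {score_s!r}", line=lineno) from exc
            if not -0.5 <= score <= 0.5:
                raise ScoreRangeError(
                    f"line {lineno}: E-score {score} outside [-0.5, 0.5] for {fwd}"
                )
            for c in (c_fwd, RC_CODES[c_fwd], c_rev, RC_CODES[c_rev]):
                prev = values[c]
                if np.isnan(prev):
                    values[c] = score
                elif prev != score:
                    if strict_symmetry:
                        raise SymmetryError(
                            f"line {lineno}: conflicting scores for {decode_octamer(int(c))}: "
                            f"{prev} vs {score}"
                        )
                    conflicts += 1
                    values[c] = 0.5 * (prev + score)
    if conflicts:
        warnings.warn(
            f"{path.name}: averaged {conflicts} conflicting octamer/revcomp scores",
            stacklevel=2,
        )
    missing = int(np.isnan(values).sum())
    if missing:
        raise CompletenessError(
            f"{path.name}: table incomplete after mirror-fill: {missing} octamers missing"
        )
    table = EScoreTable(values, tf_name=tf_name or path.stem, source=str(path))
    table.validate()
    return table


def _is_octamerish(token: str) -> bool:
    return len(token) == 8 and all(c in "ACGTacgt" for c in token)


def write_escore_table(table: EScoreTable, path: str | Path) -> None:
    """Write the 32,896 canonical octamer-pair rows, tab-delimited."""
    path = Path(path)
    codes = np.arange(N_OCTAMERS)
    canonical = codes[codes <= RC_CODES]
    with open(path, "w") as fh:
        fh.write(f"# 8-mer E-score table for {table.tf_name or 'unknown TF'}\n")
        fh.write("# octamer\trevcomp\te_score\n")
        for c in canonical:
            fh.write(
                f"{decode_octamer(int(c))}\t{decode_octamer(int(RC_CODES[c]))}\t"
                f"{table.values[c]:.17g}\n"  # full precision: read(write(x)) == x
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named sequence with its soft-mask.

    ``seq`` is uppercase; ``mask`` flags positions that were lowercase in the
    source (soft-masked repeats). ``mask`` is None when nothing was masked.
    """

    name: str
    seq: str
    mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def soft_masked(self) -> bool:
        return self.mask is not None and bool(self.mask.any())


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA records; uppercase sequence, lowercase retained as mask."""
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path.name}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        lower = (mask >= ord("a")) & (mask <= ord("z"))
        records.append(SeqRecord(rec.id, raw.upper(), lower if lower.any() else None))
    if not records:
        raise ParseError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records, restoring lowercase at soft-masked positions."""
    bio_records = []
    for rec in records:
        seq = rec.seq
        if rec.mask is not None:
            chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            chars[rec.mask] += 32  # to lowercase
            seq = chars.tobytes().decode("ascii")
        bio_records.append(_BioSeqRecord(Seq(seq), id=rec.name, description=""))
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    sites: Sequence,
    path: str | Path,
    tf_name: str = "site",
    threshold: float | None = None,
    window: int | None = None,
) -> None:
    """Write predicted sites as BED6 (0-based half-open).

    The BED score column rescales the peak moving average linearly from
    [threshold, 0.5] onto [0, 1000]; calls are strandless (".") because the
    E-score table is reverse-complement symmetric. Sites are sorted by
    (chrom, start); names are ``<tf>_<rank>`` with rank by descending peak
    score.
    """
    sites = list(sites)
    for s in sites:
        if s.start >= s.end:
            raise ValueError(f"invalid interval {s.chrom}:{s.start}-{s.end} (start >= end)")
    thr = threshold if threshold is not None else min((s.peak_score for s in sites), default=0.0)
    span = 0.5 - thr
    by_score = sorted(sites, key=lambda s: (-s.peak_score, s.chrom, s.start))
    rank = {id(s): i + 1 for i, s in enumerate(by_score)}
    with open(path, "w") as fh:
        fh.write(
            f"# pbmscan predicted sites for {tf_name}"
            + (f"; window={window}" if window is not None else "")
            + (f"; threshold={threshold}" if threshold is not None else "")
            + "\n"
        )
        for s in sorted(sites, key=lambda s: (s.chrom, s.start, s.end)):
            if span > 0:
                bed_score = int(round(np.clip((s.peak_score - thr) / span, 0, 1) * 1000))
            else:
                bed_score = 1000
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{tf_name}_{rank[id(s)]}\t{bed_score}\t.\n"
            )


# ---------------------------------------------------------------------------
# TRANSFAC matrices
# ---------------------------------------------------------------------------


@dataclass
class PwmMatrix:
    """A position count/frequency matrix in A,C,G,T column order.

    ``counts`` has shape (width, 4) and is nonnegative; ``background`` is a
    per-base frequency vector summing to 1. The pseudocount enters log-odds
    scoring as log((f + p·bg) / (bg·(1+p))).
    """

    counts: np.ndarray
    name: str = ""
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError("counts must be a (width, 4) array with width >= 1")
        if (self.counts < 0).any():
            raise ValueError("matrix counts must be nonnegative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if (self.background <= 0).any() or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("matrix has an all-zero position row")
        return self.counts / sums

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=1))


def read_transfac_matrix(path: str | Path) -> PwmMatrix:
    """Read a TRANSFAC flat-file matrix block (P0/PO header, numbered rows)."""
    path = Path(path)
    name = path.stem
    col_order: list[int] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.startswith(("#", "//", "XX")):
                continue
            fields = line.split()
            tag = fields[0]
            if tag in ("ID", "NA"):
                if len(fields) > 1:
                    name = fields[1]
                continue
            if tag in ("P0", "PO"):
                letters = [f.upper() for f in fields[1:]]
                missing = [b for b in "ACGT" if b not in letters]
                if missing:
                    raise ParseError(
                        f"matrix header missing column(s) {','.join(missing)}", line=lineno
                    )
                # map ACGT slot -> file column
                col_order = [letters.index(b) for b in "ACGT"]
                continue
            if tag.isdigit():
                if col_order is None:
                    raise ParseError("matrix row before P0 header", line=lineno)
                vals = fields[1:]
                numeric = []
                for v in vals:
                    try:
                        numeric.append(float(v))
                    except ValueError:
                        break  # trailing consensus letter
                if len(numeric) < 4:
                    raise ParseError(
                        f"ragged matrix row: expected 4 counts, got {len(numeric)}", line=lineno
                    )
                row = [numeric[i] for i in col_order]
                if any(v < 0 for v in row):
                    raise ParseError("negative count in matrix row", line=lineno)
                rows.append(row)
    if not rows:
        raise ParseError(f"{path.name}: no matrix rows found")
    return PwmMatrix(np.array(rows), name=name)


def write_transfac_matrix(pwm: PwmMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"NA {pwm.name or 'matrix'}\n")
        fh.write("P0 A C G T\n")
        for i, row in enumerate(pwm.counts, start=1):
            fh.write(f"{i:02d} " + " ".join(f"{v:g}" for v in row) + "\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# Binding measurements
# ---------------------------------------------------------------------------


@dataclass
class BindingMeasurement:
    """One probe with its measured binding: fraction bound and/or Kd."""

    name: str
    sequence: str
    fraction_bound: float | None = None
    kd: float | None = None

    def __post_init__(self) -> None:
        if any(c not in "ACGT" for c in self.sequence.upper()):
            raise ValueError(f"probe {self.name}: sequence must be A/C/G/T only")
        self.sequence = self.sequence.upper()
        if self.fraction_bound is None and self.kd is None:
            raise ValueError(f"probe {self.name}: need fraction_bound or kd")
        if self.fraction_bound is not None and not 0 <= self.fraction_bound <= 1:
            raise ValueError(f"probe {self.name}: fraction_bound outside [0, 1]")


def read_measurements(path: str | Path) -> list[BindingMeasurement]:
    """Read a TSV of probe measurements: name, sequence, fraction_bound, kd.

    Column names are matched case-insensitively; fraction_bound and kd are
    each optional but at least one must be present per row. Empty cells mean
    "not measured".
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "name" not in df.columns or "sequence" not in df.columns:
        raise ParseError(f"{Path(path).name}: need 'name' and 'sequence' columns")
    out = []
    for _, row in df.iterrows():
        fb = row.get("fraction_bound")
        kd = row.get("kd")
        out.append(
            BindingMeasurement(
                name=str(row["name"]),
                sequence=str(row["sequence"]),
                fraction_bound=None if pd.isna(fb) else float(fb),
                kd=None if pd.isna(kd) else float(kd),
            )
        )
    return out
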