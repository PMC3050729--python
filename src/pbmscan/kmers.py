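"""Octamer encoding and dense E-score lookup.

Every 8-mer over A/C/G/T maps bijectively to an integer in [0, 65535] with two
bits per base (A=0, C=1, G=2, T=3; leftmost base most significant). The dense
array indexed by these codes is what the scanner consumes: one contiguous
float64 vector of all 4^8 = 65,536 E-scores, symmetric under reverse
complementation because the PBM assay cannot distinguish a double-stranded
probe from its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CompletenessError, ScoreRangeError, SymmetryError, UnscoreableOctamerError

K = 8
N_OCTAMERS = 4**K  # 65,536

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 255 marks anything outside A/C/G/T (case-insensitive)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c

_POWERS = (4 ** np.arange(K - 1, -1, -1)).astype(np.int64)


def encode_octamer(s: str) -> int:
    """Encode an 8-mer into its integer code.

    Raises :class:`UnscoreableOctamerError` if the string is not a length-8
    A/C/G/T word (ambiguity codes included) — callers mask such windows.
    """
    if len(s) != K:
        raise UnscoreableOctamerError(f"expected an 8-mer, got {len(s)} bases: {s!r}")
    code = 0
    for ch in s.upper():
        b = _BASE_CODE.get(ch)
        if b is None:
            raise UnscoreableOctamerError(f"unscoreable octamer {s!r}: base {ch!r} is not A/C/G/T")
        code = (code << 2) | b
    return code


def decode_octamer(code: int) -> str:
    """Inverse of :func:`encode_octamer`."""
    if not 0 <= code < N_OCTAMERS:
        raise ValueError(f"octamer code out of range: {code}")
    out = []
    for shift in range(2 * (K - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def reverse_complement(s: str) -> str:
    """Standard DNA reverse complement (an involution on A/C/G/T strings)."""
    for ch in s:
        if ch not in "ACGTacgt":
            raise ValueError(f"cannot reverse-complement base {ch!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _build_rc_code_table() -> np.ndarray:
    """codes -> codes of the reverse complement, vectorized over all 65,536."""
    codes = np.arange(N_OCTAMERS, dtype=np.int64)
    rc = np.zeros(N_OCTAMERS, dtype=np.int64)
    for pos in range(K):
        base = (codes >> (2 * (K - 1 - pos))) & 3
        comp = 3 - base
        rc |= comp << (2 * pos)  # position pos lands at mirrored slot
    return rc


RC_CODES: np.ndarray = _build_rc_code_table()


def revcomp_code(code: int) -> int:
    """Octamer code of the reverse complement."""
    return int(RC_CODES[code])


def base_codes(seq: str) -> np.ndarray:
    """Per-position 2-bit base codes for a sequence; 255 where not A/C/G/T."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def octamer_codes(seq: str) -> np.ndarray:
    """Codes of all overlapping octamers of ``seq``; -1 marks unscoreable windows.

    Returns an int64 array of length ``len(seq) - 7`` (empty if shorter).
    """
    b = base_codes(seq)
    L = len(b)
    if L < K:
        return np.empty(0, dtype=np.int64)
    valid_pos = b != 255
    windows = np.lib.stride_tricks.sliding_window_view(b.astype(np.int64), K)
    codes = windows @ _POWERS
    ok = np.lib.stride_tricks.sliding_window_view(valid_pos, K).all(axis=1)
    codes = np.where(ok, codes, -1)
    return codes


@dataclass
class DenseScoreArray:
    """All 65,536 E-scores indexed by octamer code.

    Validated at construction: total, in [-0.5, 0.5], reverse-complement
    symmetric. This is the scanner's substrate.
    """

    values: np.ndarray
    tf_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_OCTAMERS,):
            raise CompletenessError(
                f"dense score array must have {N_OCTAMERS} entries, got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            n = int(np.isnan(self.values).sum())
            raise CompletenessError(f"score array incomplete: {n} octamers missing")
        if (self.values < -0.5).any() or (self.values > 0.5).any():
            raise ScoreRangeError("E-scores must lie in [-0.5, 0.5]")
        if not np.array_equal(self.values, self.values[RC_CODES]):
            bad = int((self.values != self.values[RC_CODES]).sum())
            raise SymmetryError(
                f"score array violates reverse-complement symmetry at {bad} octamers"
            )

    def __getitem__(self, octamer: str) -> float:
        return float(self.values[encode_octamer(octamer)])

    def score_octamers(self, codes: np.ndarray) -> np.ndarray:
        """Scores for an array of octamer codes; NaN where code == -1."""
        out = np.where(codes >= 0, self.values[np.clip(codes, 0, None)], np.nan)
        return out


def build_dense_array(table) -> DenseScoreArray:
    """Validate an :class:`~pbmscan.io.EScoreTable` and expose it as a dense array.

    Raises if the table is incomplete, out of range, or asymmetric; the array
    is a defensive copy so later mutation of the table cannot corrupt scans.
    """
    return DenseScoreArray(np.array(table.values, dtype=np.float64, copy=True), table.tf_name)
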