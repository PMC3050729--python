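"""PBM-mapping: sliding-window averages of octamer E-scores.

The method scores every locus with the mean E-score of W overlapping octamers
(W = 7 by default, so a window spans W + 7 = 14 bases and all octamers in it
share at least one base). Runs of windows whose average exceeds a per-factor
threshold are merged into predicted sites. Because the E-score table is
reverse-complement symmetric, a single-strand scan suffices and calls are
strandless.

A log-odds PWM scanner over TRANSFAC-style matrices is included as the
comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ScanError
from .io import PwmMatrix, SeqRecord
from .kmers import (
    DenseScoreArray,
    base_codes,
    build_dense_array,
    decode_octamer,
    octamer_codes,
)

__all__ = [
    "ScanConfig",
    "ScanProfile",
    "PredictedSite",
    "ProbeScore",
    "PBMScanner",
    "score_profile",
    "score_probe",
    "call_sites",
    "scan_regions",
    "promoter_regions",
    "pwm_log_odds_score",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning parameters.

    window_w
        Number of overlapping octamers averaged per window. 7 is the default
        (homeodomain factors such as Nkx2.2); nuclear receptors like Hnf4a use 6.
    threshold
        Minimum moving average for a site call (0.37 default, the Nkx2.2
        operating point; always report the value used — it differs per factor).
    skip_masked
        If set, windows touching soft-masked (lowercase) sequence are excluded.
    """

    window_w: int = 7
    threshold: float = 0.37
    skip_masked: bool = False
    chunk_size: int = 1 << 20

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if not -0.5 <= self.threshold <= 0.5:
            raise ValueError("threshold must lie in [-0.5, 0.5]")
        if self.chunk_size < self.window_w + 7:
            raise ValueError("chunk_size smaller than one window")

    @property
    def window_span(self) -> int:
        """Bases covered by one window of window_w overlapping octamers."""
        return self.window_w + 7


@dataclass
class ScanProfile:
    """Per-window moving-average E-scores along one sequence.

    ``scores[i]`` is the mean E-score of the window_w octamers starting at
    ``window_starts[i]``; NaN where ``mask`` is False (window contains an
    unscoreable octamer, or soft-masked sequence under skip_masked).
    """

    seq_name: str
    window_starts: np.ndarray
    scores: np.ndarray
    mask: np.ndarray
    window_w: int

    @property
    def n_windows(self) -> int:
        return len(self.scores)

    def max_score(self) -> float:
        if not self.mask.any():
            return float("nan")
        return float(np.nanmax(self.scores))


@dataclass
class PredictedSite:
    """A maximal run of above-threshold windows, merged into one interval.

    Coordinates are 0-based half-open and cover every base of every window in
    the run, so the interval is at least window_w + 7 bp long.
    """

    chrom: str
    start: int
    end: int
    peak_score: float
    peak_octamer: str
    region: str | None = None
    shared: bool = False

    @property
    def strand(self) -> str:
        return "."


@dataclass
class ProbeScore:
    """Probe-level summary: best single octamer and best window average.

    The moving average of window_w values can never exceed their maximum, so
    ``pbm_mapping_score <= max_escore`` always holds when both are defined.
    """

    max_escore: float
    pbm_mapping_score: float | None
    n_windows: int

    @property
    def has_window(self) -> bool:
        return self.pbm_mapping_score is not None


class PBMScanner(TransformerMixin, BaseEstimator):
    """Sequence scorer over a PBM E-score table (sklearn-style transformer).

    Parameters mirror :class:`ScanConfig`. ``fit`` binds an E-score table;
    ``transform`` maps an iterable of sequences to a (n, 2) array of
    [max_escore, pbm_mapping_score] features. Richer outputs (profiles, site
    calls) are exposed as methods.
    """

    def __init__(self, window: int = 7, threshold: float = 0.37, skip_masked: bool = False,
                 chunk_size: int = 1 << 20):
        self.window = window
        self.threshold = threshold
        self.skip_masked = skip_masked
        self.chunk_size = chunk_size

    @property
    def config(self) -> ScanConfig:
        return ScanConfig(self.window, self.threshold, self.skip_masked, self.chunk_size)

    def fit(self, table, y=None) -> "PBMScanner":
        """Bind an E-score table (EScoreTable or DenseScoreArray)."""
        if isinstance(table, DenseScoreArray):
            self.array_ = table
        else:
            self.array_ = build_dense_array(table)
        self.tf_name_ = self.array_.tf_name
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "array_"):
            raise ScanError("scanner not fitted: call fit(table) first")

    def transform(self, X: Iterable) -> np.ndarray:
        """Score sequences; returns (n, 2) [max_escore, pbm_mapping_score]."""
        self._check_fitted()
        rows = []
        for seq in X:
            ps = self.score_probe(seq)
            rows.append([ps.max_escore,
                         np.nan if ps.pbm_mapping_score is None else ps.pbm_mapping_score])
        return np.array(rows, dtype=np.float64)

    def fit_transform(self, table, X) -> np.ndarray:
        return self.fit(table).transform(X)

    # -- scoring ------------------------------------------------------------
    def score_profile(self, seq, mask: np.ndarray | None = None,
                      seq_name: str = "seq") -> ScanProfile:
        """Moving-average profile of one sequence.

        ``seq`` may be a string or a :class:`~pbmscan.io.SeqRecord` (whose
        soft-mask is honoured under ``skip_masked``).
        """
        self._check_fitted()
        cfg = self.config
        if isinstance(seq, SeqRecord):
            seq_name, mask, seq = seq.name, seq.mask, seq.seq
        L = len(seq)
        min_len = cfg.window_span
        if L < min_len:
            raise ScanError(
                f"{seq_name}: no scoreable window: length {L} < minimum {min_len} "
                f"(window of {cfg.window_w} octamers spans {min_len} bases)"
            )
        scores, valid = _window_scores(seq, self.array_, cfg, mask)
        starts = np.arange(len(scores), dtype=np.int64)
        return ScanProfile(seq_name, starts, scores, valid, cfg.window_w)

    def score_probe(self, seq, mask: np.ndarray | None = None) -> ProbeScore:
        """Best single-octamer E-score and best window average over a probe."""
        self._check_fitted()
        if isinstance(seq, SeqRecord):
            mask, seq = seq.mask, seq.seq
        if len(seq) < 8:
            raise ScanError(f"probe shorter than 8 bases (length {len(seq)})")
        codes = octamer_codes(seq)
        e = self.array_.score_octamers(codes)
        if self.skip_masked and mask is not None:
            win = np.lib.stride_tricks.sliding_window_view(mask, 8).any(axis=1)
            e[win] = np.nan
        if np.isnan(e).all():
            raise ScanError("probe has no scoreable octamer")
        max_e = float(np.nanmax(e))
        try:
            prof = self.score_profile(seq, mask=mask)
            pbm = prof.max_score()
            pbm = None if np.isnan(pbm) else float(pbm)
            n_win = prof.n_windows
        except ScanError:
            pbm, n_win = None, 0
        return ProbeScore(max_e, pbm, n_win)

    def call_sites(self, records: Iterable) -> list[PredictedSite]:
        """Merge maximal runs of above-threshold windows into predicted sites.

        Scans each record in chunks of ``chunk_size`` bases with a
        window_span - 1 overlap so every window is computed exactly once;
        output is independent of the chunking.
        """
        self._check_fitted()
        cfg = self.config
        sites: list[PredictedSite] = []
        for rec in _as_records(records):
            if len(rec.seq) < cfg.window_span:
                continue
            scores, valid = self._chunked_window_scores(rec)
            sites.extend(_merge_runs(rec, scores, valid, self.array_, cfg))
        sites.sort(key=lambda s: (s.chrom, s.start, s.end))
        return sites

    def _chunked_window_scores(self, rec: SeqRecord) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        L = len(rec.seq)
        n_win = L - cfg.window_span + 1
        scores = np.empty(n_win)
        valid = np.empty(n_win, dtype=bool)
        step = cfg.chunk_size - (cfg.window_span - 1)
        pos = 0
        while pos < n_win:
            chunk_end = min(pos + cfg.chunk_size, L)
            sub_mask = rec.mask[pos:chunk_end] if rec.mask is not None else None
            s, v = _window_scores(rec.seq[pos:chunk_end], self.array_, cfg, sub_mask)
            take = min(len(s), n_win - pos)
            scores[pos:pos + take] = s[:take]
            valid[pos:pos + take] = v[:take]
            pos += step
        return scores, valid

    def scan_regions(self, records: Iterable, regions: Sequence) -> dict[str, list[PredictedSite]]:
        """Call sites inside BED-style regions, lifting coordinates back.

        ``regions`` are (chrom, start, end[, name]) tuples. A site spanning
        two regions is reported under each and flagged ``shared``.
        """
        self._check_fitted()
        recs = {r.name: r for r in _as_records(records)}
        per_region: dict[str, list[PredictedSite]] = {}
        all_sites: list[PredictedSite] = []
        for i, region in enumerate(regions):
            chrom, start, end = region[0], int(region[1]), int(region[2])
            name = region[3] if len(region) > 3 else f"{chrom}:{start}-{end}"
            if chrom not in recs:
                raise ScanError(f"region {name}: unknown sequence {chrom!r}")
            rec = recs[chrom]
            if start < 0 or end > len(rec.seq) or start >= end:
                raise ScanError(
                    f"region {name} out of bounds for {chrom} (length {len(rec.seq)})"
                )
            sub = SeqRecord(chrom, rec.seq[start:end],
                            rec.mask[start:end] if rec.mask is not None else None)
            calls = self.call_sites([sub])
            lifted = [replace(s, start=s.start + start, end=s.end + start, region=name)
                      for s in calls]
            per_region[name] = lifted
            all_sites.extend(lifted)
        counts: dict[tuple, int] = {}
        for s in all_sites:
            counts[(s.chrom, s.start, s.end)] = counts.get((s.chrom, s.start, s.end), 0) + 1
        for s in all_sites:
            s.shared = counts[(s.chrom, s.start, s.end)] > 1
        return per_region


# ---------------------------------------------------------------------------
# Low-level window scoring
# ---------------------------------------------------------------------------


def _window_scores(seq: str, array: DenseScoreArray, cfg: ScanConfig,
                   mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-sum window averages; (scores, valid) with NaN where invalid."""
    W = cfg.window_w
    codes = octamer_codes(seq)
    n_oct = len(codes)
    if n_oct < W:
        return np.empty(0), np.empty(0, dtype=bool)
    e = array.score_octamers(codes)
    oct_ok = codes >= 0
    if cfg.skip_masked and mask is not None:
        masked_oct = np.lib.stride_tricks.sliding_window_view(mask, 8).any(axis=1)
        oct_ok = oct_ok & ~masked_oct
    e_filled = np.where(oct_ok, e, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(e_filled)])
    cok = np.concatenate([[0], np.cumsum(oct_ok.astype(np.int64))])
    totals = csum[W:] - csum[:-W]
    n_ok = cok[W:] - cok[:-W]
    valid = n_ok == W
    scores = np.where(valid, totals / W, np.nan)
    return scores, valid


def _merge_runs(rec: SeqRecord, scores: np.ndarray, valid: np.ndarray,
                array: DenseScoreArray, cfg: ScanConfig) -> list[PredictedSite]:
    above = valid & (scores > cfg.threshold)
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(idx) - 1]])
    sites = []
    W = cfg.window_w
    for rs, re_ in zip(run_starts, run_ends):
        first, last = int(idx[rs]), int(idx[re_])
        start = first
        end = last + cfg.window_span
        oct_codes = octamer_codes(rec.seq[start:end])
        e = array.score_octamers(oct_codes)
        # recompute run window scores locally so the peak is independent of
        # any chunking used for the threshold pass
        csum = np.concatenate([[0.0], np.cumsum(e)])
        run = (csum[W:] - csum[:-W]) / W
        peak = float(run[int(np.argmax(run))])  # leftmost max
        peak_oct = decode_octamer(int(oct_codes[int(np.nanargmax(e))]))
        sites.append(PredictedSite(rec.name, start, end, peak, peak_oct))
    return sites


def _as_records(records) -> list[SeqRecord]:
    if isinstance(records, (str, SeqRecord)):
        records = [records]
    out = []
    for i, r in enumerate(records):
        out.append(r if isinstance(r, SeqRecord) else SeqRecord(f"seq{i + 1}", str(r)))
    return out


# ---------------------------------------------------------------------------
# Functional wrappers (the op surface)
# ---------------------------------------------------------------------------


def _scanner(array, cfg: ScanConfig) -> PBMScanner:
    sc = PBMScanner(cfg.window_w, cfg.threshold, cfg.skip_masked, cfg.chunk_size)
    return sc.fit(array)


def score_profile(seq, array, cfg: ScanConfig = ScanConfig(), mask=None) -> ScanProfile:
    """Moving-average E-score profile of one sequence (see PBMScanner)."""
    return _scanner(array, cfg).score_profile(seq, mask=mask)


def score_probe(seq, array, cfg: ScanConfig = ScanConfig(), mask=None) -> ProbeScore:
    """Max single-octamer E-score and max window average of a probe."""
    return _scanner(array, cfg).score_probe(seq, mask=mask)


def call_sites(records, array, cfg: ScanConfig = ScanConfig()) -> list[PredictedSite]:
    """Thresholded, merged site calls over sequence records."""
    return _scanner(array, cfg).call_sites(records)


def scan_regions(records, regions, array, cfg: ScanConfig = ScanConfig()):
    """Site calls restricted to regions, lifted to genome coordinates."""
    return _scanner(array, cfg).scan_regions(records, regions)


def promoter_regions(tss_table: Sequence, upstream: int = 2500, downstream: int = 1000,
                     chrom_sizes: dict[str, int] | None = None) -> list[tuple]:
    """Strand-aware promoter windows around transcription start sites.

    ``tss_table`` rows are (gene, chrom, tss, strand). The default window runs
    2.5 kb upstream to 1 kb downstream of the TSS; coordinates are clipped to
    [0, chrom length] when sizes are given.
    """
    regions = []
    for gene, chrom, tss, strand in tss_table:
        tss = int(tss)
        if strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            start, end = tss - upstream, tss + downstream
        start = max(start, 0)
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        regions.append((chrom, start, end, gene))
    return regions


# ---------------------------------------------------------------------------
# PWM comparison scanner
# ---------------------------------------------------------------------------


def pwm_log_odds_score(seq: str, pwm: PwmMatrix) -> float:
    """Best log-odds PWM score over all offsets on both strands.

    Per position: log((f + p·bg) / (bg·(1+p))) with pseudocount p from the
    matrix. Zero-frequency cells with p = 0 make the windows that touch them
    -inf; an error advising a pseudocount is raised only if no window scores
    finitely.
    """
    w = pwm.width
    if len(seq) < w:
        raise ScanError(f"sequence shorter than matrix width {w}")
    freqs = pwm.frequencies
    p, bg = pwm.pseudocount, pwm.background
    with np.errstate(divide="ignore"):
        lods = np.log((freqs + p * bg[None, :]) / (bg[None, :] * (1.0 + p)))
    best = -np.inf
    b_fwd = base_codes(seq)
    b_rev = np.where(b_fwd == 255, 255, 3 - b_fwd).astype(np.uint8)[::-1]
    for b in (b_fwd, b_rev):
        ok = b != 255
        bwin = np.lib.stride_tricks.sliding_window_view(np.clip(b, 0, 3).astype(np.int64), w)
        okwin = np.lib.stride_tricks.sliding_window_view(ok, w).all(axis=1)
        if not okwin.any():
            continue
        pos = np.arange(w)
        scores = lods[pos[None, :], bwin].sum(axis=1)
        scores = np.where(okwin, scores, -np.inf)
        best = max(best, float(scores.max()))
    if best == -np.inf:
        raise ScanError(
            "no window attains a finite log-odds score: the matrix has zero "
            "frequencies and pseudocount is 0 — set a positive pseudocount"
        )
    return best
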