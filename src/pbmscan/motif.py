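"""Core-motif analytics over a complete 8-mer E-score table.

Homeodomain factors recognise a short, nearly invariant tetramer core (for
Nkx2.2 the canonical AAGT, plus the low-affinity alternative GAGT) embedded in
less-conserved flanks. These routines census the cores among the top-scoring
octamers, profile core occurrence across the E-score distribution, classify
dual-core octamers by orientation, and test whether predicted sites cluster
near transcription start sites of a gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import PbmScanError
from .io import EScoreTable
from .kmers import N_OCTAMERS, RC_CODES, decode_octamer, reverse_complement

__all__ = [
    "CoreAnalysisConfig",
    "CoreCensus",
    "DualCoreRecord",
    "HistogramResult",
    "EnrichmentResult",
    "core_census",
    "first_position_histogram",
    "dual_core_scan",
    "tss_proximity_enrichment",
]


@dataclass(frozen=True)
class CoreAnalysisConfig:
    """Census parameters: selection cutoff, ordered core list, strand policy.

    Core order is a precedence: an octamer containing several cores is counted
    under the first. With ``count_revcomp`` (default) a core is "contained" if
    the octamer carries the core or its reverse complement.
    """

    escore_cutoff: float = 0.45
    cores: tuple[str, ...] = ("AAGT", "GAGT")
    count_revcomp: bool = True

    def __post_init__(self) -> None:
        if not -0.5 <= self.escore_cutoff <= 0.5:
            raise ValueError("escore_cutoff must lie in [-0.5, 0.5]")
        for c in self.cores:
            if len(c) != 4 or any(b not in "ACGT" for b in c):
                raise ValueError(f"core must be an A/C/G/T 4-mer, got {c!r}")


@dataclass
class CoreCensus:
    """Counts and group means from a top-octamer census.

    ``core_counts`` partitions the ``n_top`` top octamers by core precedence;
    the leftover is ``n_neither`` (counts always sum to n_top). ``core_means``
    average over ALL octamers containing each core (not just the top set);
    ``p_values`` are one-sided Welch t-tests of each core group against the
    all-octamer background.
    """

    cutoff: float
    n_top: int
    core_counts: dict[str, int]
    n_neither: int
    core_means: dict[str, float]
    mean_all: float
    p_values: dict[str, float]
    core_totals: dict[str, int] = field(default_factory=dict)


@dataclass
class DualCoreRecord:
    """An octamer whose two tetramer halves are both cores (or core revcomps)."""

    octamer: str
    left_core: str
    right_core: str
    content_class: str  # "identical" | "mixed"
    orientation_class: str  # "inline" | "reverse-complement"
    escore: float


@dataclass
class HistogramResult:
    """Per-bin fraction of octamers containing each first-position core variant.

    Bins of width ``bin_width`` partition [-0.5, 0.5], top bin right-closed.
    Fractions across variants need not sum to 1 (an octamer can hold several
    cores); empty bins carry fraction 0 and are flagged in ``empty``.
    """

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    fractions: dict[str, np.ndarray]
    empty: np.ndarray
    suffix: str


@dataclass
class EnrichmentResult:
    """2x2 Fisher test of near-TSS site possession between two gene sets."""

    table: np.ndarray  # [[a_in, a_out], [b_in, b_out]]
    odds_ratio: float
    p_value: float
    distances_a: dict[str, float]
    distances_b: dict[str, float]
    window: int


# ---------------------------------------------------------------------------
# Containment helpers
# ---------------------------------------------------------------------------


def _containment_mask(core: str, count_revcomp: bool) -> np.ndarray:
    """Boolean over all 65,536 octamer codes: contains core (or its revcomp)."""
    probes = {core}
    if count_revcomp:
        probes.add(reverse_complement(core))
    mask = np.zeros(N_OCTAMERS, dtype=bool)
    for c in range(N_OCTAMERS):
        o = decode_octamer(c)
        if any(p in o for p in probes):
            mask[c] = True
    return mask


_containment_cache: dict[tuple[str, bool], np.ndarray] = {}


def containment_mask(core: str, count_revcomp: bool = True) -> np.ndarray:
    key = (core, count_revcomp)
    if key not in _containment_cache:
        _containment_cache[key] = _containment_mask(core, count_revcomp)
    return _containment_cache[key]


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def core_census(table: EScoreTable, cfg: CoreAnalysisConfig = CoreAnalysisConfig()) -> CoreCensus:
    """Census the cores among octamers scoring above the cutoff.

    Octamer/revcomp pairs are counted once (canonical member); assignment
    follows the core precedence in ``cfg.cores``. Group means and significance
    are computed over all octamers containing each core, against the
    all-octamer background.
    """
    values = np.asarray(table.values, dtype=np.float64)
    codes = np.arange(N_OCTAMERS)
    canonical = codes <= RC_CODES
    top = canonical & (values > cfg.escore_cutoff)
    n_top = int(top.sum())
    if n_top == 0:
        warnings.warn("no octamers above cutoff: census is empty", stacklevel=2)

    masks = {core: containment_mask(core, cfg.count_revcomp) for core in cfg.cores}
    unassigned = top.copy()
    core_counts: dict[str, int] = {}
    for core in cfg.cores:
        hit = unassigned & masks[core]
        core_counts[core] = int(hit.sum())
        unassigned &= ~masks[core]
    n_neither = int(unassigned.sum())

    mean_all = float(values.mean())
    core_means: dict[str, float] = {}
    p_values: dict[str, float] = {}
    core_totals: dict[str, int] = {}
    for core in cfg.cores:
        group = values[masks[core]]
        core_totals[core] = int(masks[core].sum())
        if len(group) == 0:
            core_means[core] = float("nan")
            p_values[core] = float("nan")
            continue
        core_means[core] = float(group.mean())
        res = stats.ttest_ind(group, values, equal_var=False, alternative="greater")
        p_values[core] = float(res.pvalue)

    return CoreCensus(
        cutoff=cfg.escore_cutoff,
        n_top=n_top,
        core_counts=core_counts,
        n_neither=n_neither,
        core_means=core_means,
        mean_all=mean_all,
        p_values=p_values,
        core_totals=core_totals,
    )


# ---------------------------------------------------------------------------
# First-position histogram
# ---------------------------------------------------------------------------


def first_position_histogram(
    table: EScoreTable,
    core_suffix: str = "AGT",
    bin_width: float = 0.10,
    count_revcomp: bool = True,
) -> HistogramResult:
    """Fraction of octamers per E-score bin containing X + suffix, X in ACGT.

    Bins of the given width partition [-0.5, 0.5]; the top bin is
    right-closed. All 65,536 octamers are binned (no canonical-pair dedup:
    palindromic octamers would otherwise carry double weight relative to the
    full population).
    """
    n_bins_f = 1.0 / bin_width
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin_width {bin_width} does not divide 1.0 evenly")
    edges = -0.5 + bin_width * np.arange(n_bins + 1)
    edges[-1] = 0.5

    v = np.asarray(table.values, dtype=np.float64)
    idx = np.minimum(((v + 0.5) / bin_width).astype(np.int64), n_bins - 1)
    bin_counts = np.bincount(idx, minlength=n_bins)
    empty = bin_counts == 0

    fractions: dict[str, np.ndarray] = {}
    for x in "ACGT":
        core = x + core_suffix
        mask = containment_mask(core, count_revcomp)
        hits = np.bincount(idx[mask], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            frac = np.where(bin_counts > 0, hits / np.maximum(bin_counts, 1), 0.0)
        fractions[core] = frac
    return HistogramResult(edges, bin_counts, fractions, empty, core_suffix)


# ---------------------------------------------------------------------------
# Dual-core octamers
# ---------------------------------------------------------------------------


def dual_core_scan(table: EScoreTable, cfg: CoreAnalysisConfig = CoreAnalysisConfig()) -> list[DualCoreRecord]:
    """Enumerate octamers whose two disjoint tetramer halves are both cores.

    Each half (positions 1-4 and 5-8) must be a configured core or its reverse
    complement. Orientation is "inline" when both halves read in the same
    strand sense and "reverse-complement" when they oppose; content is
    "identical" when both halves derive from the same core.
    """
    forward = {c: c for c in cfg.cores}
    backward = {reverse_complement(c): c for c in cfg.cores}
    records: list[DualCoreRecord] = []
    for c in range(N_OCTAMERS):
        o = decode_octamer(c)
        left, right = o[:4], o[4:]
        ls = _half_sense(left, forward, backward)
        rs = _half_sense(right, forward, backward)
        if ls is None or rs is None:
            continue
        lcore, lsense = ls
        rcore, rsense = rs
        records.append(
            DualCoreRecord(
                octamer=o,
                left_core=lcore,
                right_core=rcore,
                content_class="identical" if lcore == rcore else "mixed",
                orientation_class="inline" if lsense == rsense else "reverse-complement",
                escore=float(table.values[c]),
            )
        )
    return records


def _half_sense(half: str, forward: dict, backward: dict) -> tuple[str, str] | None:
    if half in forward:
        return forward[half], "+"
    if half in backward:
        return backward[half], "-"
    return None


# ---------------------------------------------------------------------------
# TSS-proximity enrichment
# ---------------------------------------------------------------------------


def tss_proximity_enrichment(
    genes_a,
    sites_a,
    genes_b,
    sites_b,
    tss_window: int = 500,
    upstream_only: bool = True,
) -> EnrichmentResult:
    """Fisher's exact test: do genes in set A carry a predicted site near
    their TSS more often than genes in set B?

    ``genes_*`` rows are (gene, chrom, tss, strand); sites are
    :class:`~pbmscan.scanner.PredictedSite` lists for each set. Distance is
    the strand-aware signed offset from the TSS to the nearest site midpoint
    (positive = upstream); a gene is "near" when 0 <= distance <= window
    (``upstream_only``) or |distance| <= window otherwise.
    """
    if not len(genes_a) or not len(genes_b):
        raise PbmScanError("empty gene set in TSS enrichment")
    da = _nearest_site_distances(genes_a, sites_a)
    db = _nearest_site_distances(genes_b, sites_b)

    def near(d: float) -> bool:
        if np.isnan(d):
            return False
        return (0 <= d <= tss_window) if upstream_only else (abs(d) <= tss_window)

    a_in = sum(near(d) for d in da.values())
    b_in = sum(near(d) for d in db.values())
    tbl = np.array([[a_in, len(da) - a_in], [b_in, len(db) - b_in]])
    odds, p = stats.fisher_exact(tbl, alternative="two-sided")
    return EnrichmentResult(tbl, float(odds), float(p), da, db, tss_window)


def _nearest_site_distances(genes, sites) -> dict[str, float]:
    by_chrom: dict[str, list[float]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append((s.start + s.end) / 2.0)
    out: dict[str, float] = {}
    for gene, chrom, tss, strand in genes:
        mids = by_chrom.get(chrom, [])
        if not mids:
            out[gene] = float("nan")
            continue
        # signed, strand-aware: positive means upstream of the TSS
        signed = [(tss - m) if strand != "-" else (m - tss) for m in mids]
        out[gene] = min(signed, key=abs)
    return out
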