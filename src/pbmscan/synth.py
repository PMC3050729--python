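"""Synthetic E-score tables, genomes and probe sets with ground truth.

The table generator emulates the structure of a homeodomain PBM dataset: a
strong primary tetramer core and a weaker secondary core, position-dependent
flank contributions including a pairwise (non-additive) interdependency term,
Gaussian measurement noise, and exact reverse-complement symmetry. The genome
generator plants sites with known peak scores in low-scoring background; the
probe-set generator derives fraction-bound and Kd measurements from the
package's own occupancy identities. Every generator is deterministic under its
seed and returns a manifest sufficient to recompute expected outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FixtureError
from .io import BindingMeasurement, EScoreTable, SeqRecord
from .kmers import (
    N_OCTAMERS,
    RC_CODES,
    DenseScoreArray,
    build_dense_array,
    decode_octamer,
    encode_octamer,
    octamer_codes,
    reverse_complement,
)
from .motif import containment_mask
from .scanner import ScanConfig, score_probe

__all__ = [
    "SyntheticTableSpec",
    "PlantedGenomeSpec",
    "TableManifest",
    "GenomeManifest",
    "PlantedSite",
    "ProbeSetManifest",
    "make_table",
    "make_genome",
    "make_probe_set",
    "evaluate_calls",
]


# ---------------------------------------------------------------------------
# Synthetic E-score tables
# ---------------------------------------------------------------------------

# flank contributions relative to the core occurrence: offset -1 is the base
# immediately 5' of the core, offset 4 immediately 3'. The pairwise term makes
# the flanks non-additive (T...A straddling the core is worth extra). The
# favoured flanks coincide with a tandem (period-4) core repeat, so octamers
# tiled across a repeated-core site all score high — the dense-window
# structure real binding sites show under PBM scoring.
_DEFAULT_FLANKS = {
    (-1, "T"): 0.10,
    (-2, "G"): 0.02,
    (4, "A"): 0.10,
    (5, "C"): 0.02,
}
_DEFAULT_PAIR = ((-1, "T"), (4, "A"), 0.10)


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Parameters of the synthetic PBM table.

    Default weights put the best primary-core octamer (GT+core+AC, all flank
    bonuses earned) at 0.498 and the best secondary-only octamer at 0.478,
    with coreless background at the baseline, so a 0.45 census cutoff
    separates planted cores from background by a wide margin as in real
    homeodomain PBM data.
    """

    primary_core: str = "AAGT"
    primary_weight: float = 0.20
    secondary_core: str = "GAGT"
    secondary_weight: float = 0.18
    baseline: float = -0.05
    flank_effects: tuple = tuple(sorted(_DEFAULT_FLANKS.items()))
    pair_effect: tuple = _DEFAULT_PAIR
    position_weights: tuple = (0.0, 0.004, 0.008, 0.012, 0.016)
    noise_sd: float = 0.02
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        for core in (self.primary_core, self.secondary_core):
            if len(core) != 4 or any(b not in "ACGT" for b in core):
                raise ValueError(f"core must be an A/C/G/T 4-mer, got {core!r}")
        if self.secondary_weight >= self.primary_weight:
            raise ValueError("secondary core weight must be below primary")


@dataclass
class TableManifest:
    """Ground truth for a synthetic table: per-octamer noiseless scores."""

    spec: SyntheticTableSpec
    noiseless: np.ndarray  # (65536,), reverse-complement symmetric

    def expected_census(self, cutoff: float = 0.45,
                        cores: Sequence[str] | None = None) -> dict:
        """Census counts implied by the noiseless scores (canonical pairs)."""
        if cores is None:
            cores = (self.spec.primary_core, self.spec.secondary_core)
        codes = np.arange(N_OCTAMERS)
        top = (codes <= RC_CODES) & (self.noiseless > cutoff)
        unassigned = top.copy()
        counts = {}
        for core in cores:
            hit = unassigned & containment_mask(core, True)
            counts[core] = int(hit.sum())
            unassigned &= ~containment_mask(core, True)
        counts["neither"] = int(unassigned.sum())
        counts["n_top"] = int(top.sum())
        return counts


def _core_contribution(octamer: str, core: str, weight: float,
                       flanks: dict, pair: tuple,
                       position_weights: tuple = (0.0,) * 5) -> float:
    """Best contribution of one core over all occurrences on either strand.

    The per-start-position weight gradient makes otherwise equivalent core
    placements score slightly differently, as on real arrays where probe
    position modulates measured intensity.
    """
    best = None
    (p1_off, p1_base), (p2_off, p2_base), pair_delta = pair
    for rendering in (octamer, reverse_complement(octamer)):
        pos = rendering.find(core)
        while pos != -1:
            contrib = weight + position_weights[pos]
            for (off, base), delta in flanks.items():
                j = pos + (off if off < 0 else off)
                if 0 <= j < 8 and rendering[j] == base:
                    contrib += delta
            j1, j2 = pos + p1_off, pos + p2_off
            if (0 <= j1 < 8 and rendering[j1] == p1_base
                    and 0 <= j2 < 8 and rendering[j2] == p2_base):
                contrib += pair_delta
            best = contrib if best is None else max(best, contrib)
            pos = rendering.find(core, pos + 1)
    return 0.0 if best is None else best


def make_table(spec: SyntheticTableSpec = SyntheticTableSpec()) -> tuple[EScoreTable, TableManifest]:
    """Generate a complete, symmetric synthetic E-score table plus manifest.

    Noiseless score of an octamer = baseline + the best core contribution over
    both strands (0 if no core); this is reverse-complement symmetric by
    construction. Gaussian noise is drawn once per canonical octamer pair and
    mirrored, so symmetry is exact even with noise; scores are clipped to
    [-0.5, 0.5]. Out-of-range noiseless scores are an error.
    """
    flanks = dict(spec.flank_effects)
    noiseless = np.empty(N_OCTAMERS)
    for c in range(N_OCTAMERS):
        rc = int(RC_CODES[c])
        if rc < c:
            noiseless[c] = noiseless[rc]
            continue
        o = decode_octamer(c)
        contrib = max(
            _core_contribution(o, spec.primary_core, spec.primary_weight,
                               flanks, spec.pair_effect, spec.position_weights),
            _core_contribution(o, spec.secondary_core, spec.secondary_weight,
                               flanks, spec.pair_effect, spec.position_weights),
        )
        noiseless[c] = spec.baseline + contrib
    if noiseless.min() < -0.5 - 1e-9 or noiseless.max() > 0.5 + 1e-9:
        raise FixtureError(
            f"spec produces noiseless scores outside [-0.5, 0.5] "
            f"(range {noiseless.min():.3f}..{noiseless.max():.3f})"
        )
    noiseless = np.clip(noiseless, -0.5, 0.5)  # snap float rounding at the bounds
    primary_top = noiseless[containment_mask(spec.primary_core, True)].max()
    if primary_top <= 0.45:
        raise FixtureError(
            f"primary-core weight too low: best primary octamer scores {primary_top:.3f} <= 0.45"
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, N_OCTAMERS) if spec.noise_sd > 0 else np.zeros(N_OCTAMERS)
    canonical = np.minimum(np.arange(N_OCTAMERS), RC_CODES)
    values = noiseless + noise[canonical]
    if spec.clip:
        values = np.clip(values, -0.5, 0.5)
    table = EScoreTable(values, tf_name=f"synthetic-{spec.primary_core}",
                        source=f"pbmscan.synth seed={spec.seed}")
    table.validate()
    return table, TableManifest(spec, noiseless)


# ---------------------------------------------------------------------------
# Site construction
# ---------------------------------------------------------------------------


def _site_peak(seq: str, array: DenseScoreArray, window: int) -> float:
    """Max window average of a candidate sequence, computed directly for
    speed: the ladder search evaluates tens of thousands of candidates."""
    e = array.values[octamer_codes(seq)]
    if len(e) == window:
        return float(e.mean())
    csum = np.concatenate([[0.0], np.cumsum(e)])
    return float((csum[window:] - csum[:-window]).max() / window)


def _candidate_starts(array: DenseScoreArray, window: int) -> list[str]:
    """High-scoring seed sequences: tandem repeats of each tetramer of the
    table's best octamer (dense core tilings), plus a greedy octamer chain."""
    span = window + 7
    best = decode_octamer(int(np.argmax(array.values)))
    cands = []
    for i in range(5):
        rep = best[i:i + 4] * (span // 4 + 2)
        for r in range(4):
            cands.append(rep[r:r + span])
    seq = best
    for _ in range(window - 1):
        seq += max("ACGT", key=lambda b: array.values[encode_octamer(seq[-7:] + b)])
    cands.append(seq)
    return cands


_ladder_cache: dict[tuple, list[tuple[str, float]]] = {}


def build_score_ladder(array: DenseScoreArray, window: int = 7,
                       length: int | None = None,
                       floor: float = -0.02) -> list[tuple[str, float]]:
    """A descending ladder of (sequence, max-window-average) pairs.

    Starts from the best dense core tiling (padded to ``length`` with a
    core-free CA repeat) and repeatedly applies the single-base mutation that
    lowers the peak the LEAST, recording every rung until the peak drops
    below ``floor``. The achievable peak scores of a core-driven table are
    quantized (breaking a core moves several octamers at once), so the ladder
    enumerates the realisable levels; generators plant the rung nearest each
    requested target and record the achieved value in the manifest. The
    ladder is deterministic for a given table and cached.
    """
    span = length if length is not None else window + 7
    if span < window + 7:
        raise FixtureError(f"site length {span} below one window ({window + 7})")
    key = (hash(array.values.tobytes()), window, span, floor)
    if key in _ladder_cache:
        return _ladder_cache[key]

    def pad(core_seq: str) -> str:
        extra = span - len(core_seq)
        left = extra // 2
        fill = ("CA" * span)
        return fill[:left] + core_seq + fill[:extra - left]

    # breadth-first level collection: explore single mutations outward from
    # the dense-core seeds, recording one representative sequence per score
    # level (rounded to 1e-4); compositions of a few mutations fill in levels
    # a single mutation cannot reach.
    levels: dict[int, tuple[str, float]] = {}

    def note(seq: str, peak: float) -> bool:
        k = round(peak * 10000)
        if peak >= floor and k not in levels:
            levels[k] = (seq, peak)
            return True
        return False

    frontier: list[tuple[str, float]] = []
    for s in (pad(c) for c in _candidate_starts(array, window)):
        p = _site_peak(s, array, window)
        if note(s, p):
            frontier.append((s, p))
    for _depth in range(8):
        new: list[tuple[str, float]] = []
        for seq, _p in frontier:
            for i in range(span):
                prefix, suffix = seq[:i], seq[i + 1:]
                for b in "ACGT":
                    if seq[i] == b:
                        continue
                    cand = prefix + b + suffix
                    p = _site_peak(cand, array, window)
                    if note(cand, p):
                        new.append((cand, p))
        if not new:
            break
        # keep the frontier small but spread over the score range
        new.sort(key=lambda sp: sp[1])
        step = max(len(new) // 60, 1)
        frontier = new[::step]
    ladder = sorted(levels.values(), key=lambda sp: -sp[1])
    _ladder_cache[key] = ladder
    return ladder


def construct_site(array: DenseScoreArray, target: float, rng: np.random.Generator,
                   window: int = 7, tol: float = 0.02, length: int | None = None,
                   below: float | None = None, above: float | None = None) -> tuple[str, float]:
    """Pick a sequence whose maximum window average is closest to ``target``.

    ``length`` defaults to window + 7 (a single window, the unit planted into
    genomes); longer lengths control the max over all windows — what probe
    scoring sees — so junction windows cannot push a probe above its intended
    score. Selection comes from :func:`build_score_ladder`; ``below`` /
    ``above`` optionally constrain the achieved peak to one side of a
    boundary (used to plant sites strictly under or over a call threshold).
    Raises when no ladder rung satisfies the constraints within ``tol``.
    """
    ladder = build_score_ladder(array, window, length)
    pool = [sp for sp in ladder
            if (below is None or sp[1] < below) and (above is None or sp[1] > above)]
    if not pool:
        raise FixtureError(
            f"no achievable site score in ({above}, {below}): ladder spans "
            f"{ladder[-1][1]:.3f}..{ladder[0][1]:.3f}"
        )
    seq, peak = min(pool, key=lambda sp: abs(sp[1] - target))
    if abs(peak - target) > tol:
        raise FixtureError(
            f"target window average {target:.3f} unachievable within ±{tol}: "
            f"nearest realisable level is {peak:.3f}"
        )
    return seq, peak


# ---------------------------------------------------------------------------
# Planted genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedGenomeSpec:
    """A background genome with sites planted at known scores.

    ``site_scores`` are target window averages; defaults straddle nothing —
    all five sit comfortably above the 0.37 threshold plus margin. Planted
    intervals are non-overlapping and at least ``min_spacing`` bp apart.
    """

    length: int = 10_000
    gc_content: float = 0.42
    site_scores: tuple[float, ...] = (0.40, 0.41, 0.42, 0.43, 0.44)
    window: int = 7
    threshold: float = 0.37
    margin: float = 0.02
    min_spacing: int = 50
    seed: int = 0
    name: str = "chrSyn"

    @property
    def n_sites(self) -> int:
        return len(self.site_scores)


@dataclass
class PlantedSite:
    start: int
    end: int
    target: float
    peak_score: float  # achieved window average, exactly recomputable

    @property
    def supra_threshold(self) -> bool:  # relative to the spec threshold at plant time
        return self._supra

    _supra: bool = field(default=False, repr=False)


@dataclass
class GenomeManifest:
    spec: PlantedGenomeSpec
    sites: list[PlantedSite]

    def expected_sites(self, threshold: float | None = None) -> list[PlantedSite]:
        thr = self.spec.threshold if threshold is None else threshold
        return [s for s in self.sites if s.peak_score > thr]


def make_genome(spec: PlantedGenomeSpec, table: EScoreTable) -> tuple[SeqRecord, GenomeManifest]:
    """Assemble background sequence with planted sites and verify by scanning.

    Background is order-0 with the requested GC content; the assembled genome
    is rescanned and accepted only if thresholded site calls correspond 1:1
    (by overlap) with the supra-threshold planted sites, so spurious
    background or junction calls cannot slip into the manifest. Bounded
    retries with fresh background; unsatisfiable specs raise.
    """
    from .scanner import call_sites  # local import to avoid cycle at module load

    array = build_dense_array(table)
    rng = np.random.default_rng(spec.seed)
    span = spec.window + 7
    needed = spec.n_sites * (span + spec.min_spacing) + spec.min_spacing
    if spec.length < needed:
        raise FixtureError(f"genome length {spec.length} too short for {spec.n_sites} sites")

    # plant each site strictly on its intended side of the call threshold so
    # manifest-vs-call comparisons are never decided by selection slack
    site_seqs = [
        construct_site(
            array, t, rng, spec.window,
            below=spec.threshold if t <= spec.threshold else None,
            above=spec.threshold if t > spec.threshold else None,
        )
        for t in spec.site_scores
    ]

    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _attempt in range(50):
        positions = _place_sites(rng, spec.length, spec.n_sites, span, spec.min_spacing)
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=spec.length, p=probs)
        seq = bytearray(bases.tobytes())
        sites = []
        genome = None
        for pos, ((sseq, _peak), target) in zip(positions, zip(site_seqs, spec.site_scores)):
            seq[pos:pos + span] = sseq.encode("ascii")
            sites.append(PlantedSite(pos, pos + span, float(target), float("nan")))
        genome = seq.decode("ascii")
        # manifest peak = in-situ peak: max average over windows overlapping
        # the planted interval, measured in the assembled genome — junction
        # windows next to a site belong to its call and must be part of the
        # ground truth
        for ps in sites:
            lo = max(ps.start - (span - 1), 0)
            hi = min(ps.end + (span - 1), spec.length)
            local = _site_peak(genome[lo:hi], array, spec.window)
            ps.peak_score = local
            ps._supra = local > spec.threshold
        sites.sort(key=lambda s: s.start)
        rec = SeqRecord(spec.name, genome)
        cfg = ScanConfig(window_w=spec.window, threshold=spec.threshold)
        calls = call_sites([rec], array, cfg)
        expected = [s for s in sites if s.peak_score > spec.threshold]
        if _calls_match(calls, expected):
            return rec, GenomeManifest(spec, sites)
    raise FixtureError("could not assemble a clean genome in 50 attempts")


def _place_sites(rng: np.random.Generator, length: int, n: int, span: int,
                 spacing: int) -> list[int]:
    for _ in range(1000):
        pos = np.sort(rng.integers(spacing, length - span - spacing, size=n))
        if n <= 1 or np.diff(pos).min() >= span + spacing:
            return [int(p) for p in pos]
    raise FixtureError("could not place non-overlapping sites")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _calls_match(calls, expected) -> bool:
    """1:1 overlap correspondence between calls and expected planted sites,
    with each call's peak equal to the planted window average (junction
    windows next to the site must not out-score it)."""
    if len(calls) != len(expected):
        return False
    used = set()
    for c in calls:
        hit = [i for i, s in enumerate(expected)
               if i not in used and _overlaps(c.start, c.end, s.start, s.end)]
        if len(hit) != 1:
            return False
        if abs(c.peak_score - expected[hit[0]].peak_score) > 1e-9:
            return False
        used.add(hit[0])
    return True


def evaluate_calls(calls, manifest: GenomeManifest,
                   threshold: float | None = None) -> dict[str, float]:
    """Overlap-based precision and recall of site calls against the manifest."""
    expected = manifest.expected_sites(threshold)
    tp_calls = [c for c in calls
                if any(_overlaps(c.start, c.end, s.start, s.end) for s in expected)]
    recalled = [s for s in expected
                if any(_overlaps(c.start, c.end, s.start, s.end) for c in calls)]
    precision = len(tp_calls) / len(calls) if calls else (1.0 if not expected else 0.0)
    recall = len(recalled) / len(expected) if expected else 1.0
    return {"precision": precision, "recall": recall,
            "n_calls": len(calls), "n_expected": len(expected)}


# ---------------------------------------------------------------------------
# Probe sets for regression fixtures
# ---------------------------------------------------------------------------


@dataclass
class ProbeSetManifest:
    a: float
    b: float
    z: float
    scores: np.ndarray
    fraction_bound_true: np.ndarray
    kd_true: np.ndarray
    window: int


def make_probe_set(
    table: EScoreTable,
    n_probes: int = 24,
    affinity_model: tuple[float, float, float] = (0.8, 0.1, 2.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    window: int = 7,
    flank: int = 8,
    score_range: tuple[float, float] = (0.05, 0.44),
) -> tuple[list[BindingMeasurement], ProbeSetManifest]:
    """Probes whose measured binding follows the occupancy model exactly.

    Each probe is constructed whole (site plus flanks, ``2·flank + window + 7``
    bases) so its maximum window average — the PBM-mapping score x the scanner
    will report — lands on a target spread across ``score_range``. x sets
    occupancy F = a·x + b, fraction bound = F, and Kd = z(1 − F)/F.
    Multiplicative Gaussian noise of ``noise_sd`` perturbs the two
    measurements independently. Raises if the realised scores span < 0.3 or
    occupancy leaves (0, 1).
    """
    a, b, z = affinity_model
    array = build_dense_array(table)
    rng = np.random.default_rng(seed)
    targets = np.linspace(score_range[0], score_range[1], n_probes)
    probe_len = 2 * flank + window + 7
    cfg = ScanConfig(window_w=window)
    probes: list[BindingMeasurement] = []
    xs, fbs, kds = [], [], []
    for i, t in enumerate(targets):
        probe_seq, _ = construct_site(array, float(t), rng, window, length=probe_len)
        x = score_probe(probe_seq, array, cfg).pbm_mapping_score
        occ = a * x + b
        if not 0.0 < occ < 1.0:
            raise FixtureError(f"probe {i}: occupancy a·x+b = {occ:.3f} left (0, 1)")
        fb_true = occ
        kd_true = z * (1.0 - occ) / occ
        fb = fb_true * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 else fb_true
        kd = kd_true * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 else kd_true
        fb = float(np.clip(fb, 0.0, 1.0))
        kd = float(max(kd, 1e-9))
        probes.append(BindingMeasurement(f"probe{i + 1:02d}", probe_seq,
                                         fraction_bound=fb, kd=kd))
        xs.append(x)
        fbs.append(fb_true)
        kds.append(kd_true)
    xs = np.array(xs)
    if np.ptp(xs) < 0.3:
        raise FixtureError(f"insufficient score spread: {np.ptp(xs):.3f} < 0.3")
    manifest = ProbeSetManifest(a, b, z, xs, np.array(fbs), np.array(kds), window)
    return probes, manifest
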