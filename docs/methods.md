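# Methods

## The scoring model

PBM-mapping scores a locus by the mean enrichment score (E-score) of the `W`
overlapping octamers covering it. E-scores are rank-based statistics in
[−0.5, 0.5] computed from protein-binding-microarray intensities, defined for
all 4^8 = 65,536 octamers, and invariant under reverse complementation
(double-stranded probes cannot distinguish an octamer from its reverse
complement). Three consequences shape the implementation:

* **Totality.** The scanner's substrate is a dense float64 vector indexed by
  a 2-bit-per-base octamer code (A=0, C=1, G=2, T=3, leftmost base most
  significant). `read_escore_table` mirror-fills each listed octamer onto its
  reverse complement and refuses tables that remain incomplete; no partially
  constructed table escapes into scanning.
* **Strandlessness.** Because `e(o) = e(rc(o))`, a single-strand scan is
  exhaustive. Profiles mirror exactly under reverse complementation
  (property-tested), and BED output reports strand ".".
* **Window geometry.** A window of `W` octamers spans `W + 7` bases; with the
  default `W = 7` every octamer in the 14 bp window shares at least one base,
  the largest `W` for which that holds. Scores are computed with a rolling
  cumulative sum and are contract-equal to naive per-window recomputation to
  1e-12 (tested on random tables and sequences).

### Parameters

| parameter  | default | meaning |
|------------|---------|---------|
| `window_w` | 7       | octamers averaged per window; 6 suits dimeric nuclear-receptor sites (shorter effective footprint), larger homeodomain-like footprints use 7 |
| `threshold`| 0.37    | minimum moving average for a site call; dimensionless on the E-score scale. Factor-specific — every output records the value actually used |
| `skip_masked` | off  | drop windows touching soft-masked (lowercase) sequence; the default scans raw sequence |
| `pseudocount` | 0.0  | PWM log-odds smoothing, `log((f + p·bg)/(bg·(1+p)))` per position |

Windows containing any non-ACGT base are unscoreable and masked: E-scores
are defined only over A/C/G/T, so assembly gaps and ambiguity codes exclude
the windows that touch them rather than receiving an arbitrary value. Runs of
above-threshold windows merge into one site covering every base of every
window in the run (so sites are ≥ `W+7` bp); the site's peak is recomputed
locally from its octamer scores at merge time, which makes output bit-stable
between whole-sequence and chunked scans (chunks overlap by `W+6` bases so
every window is computed exactly once). Ties for peak window and peak octamer
break leftmost.

## Affinity regressions

Fraction bound `F` is regressed on the score `x` by ordinary least squares
(`F = a·x + b`); probes with no detectable binding can be named as exclusions
and are carried in the result for plotting but not fitted. The dissociation
constant follows from the occupancy identity `Kd = [ligand](1 − F)/F`,
giving the fitted model `Kd = z(1 − (a·x + b))/(a·x + b)` with `z` the free
ligand-concentration scale. `KdRegression` minimises squared residuals on the
Kd scale with bounded least squares (`z > 0`) from 16 starts: a log-spaced
grid of `z` values, each pinning a linear initialisation of `(a, b)` through
the implied occupancies `z/(Kd+z)`. r² is reported on both the Kd and the
occupancy scale. Solutions whose fitted occupancy leaves (0, 1] over the
observed score range are flagged `boundary` rather than silently clipped.

Identifiability: at zero noise the three parameters are recovered to < 1e-6
relative error (50 random draws, tested). Under 5 % multiplicative Kd noise
the slope `a` stays tightly identified (~3 % median relative error) but `b`
and `z` partially trade off against each other (~14–18 % each at n = 12
design points); the pooled median across parameters is ~9 %. Users wanting
tight `z` estimates should fix the ligand concentration when it is known.

## Motif analytics

The census selects octamers above a cutoff (default 0.45), counting each
octamer/reverse-complement pair once, and assigns them to cores by precedence
(default AAGT before GAGT, so dual-core octamers count under the primary
core — the convention under which the per-core counts plus "neither" sum to
the top-set size, an identity the tests assert on arbitrary tables). Group
means are taken over *all* octamers containing each core, against the
all-octamer background, with a one-sided Welch t-test for significance. The
first-position histogram bins all 65,536 octamers (no pair dedup — palindromic
octamers would otherwise carry double weight) into E-score bins of width 0.10
with a right-closed top bin; fractions across the four first-position
variants deliberately need not sum to 1 since an octamer can contain several
cores. Dual-core octamers are the 16 whose two disjoint tetramer halves are
each a core or core reverse complement, classified by content (identical vs
mixed) and orientation (inline vs reverse-complement).

TSS-proximity enrichment computes a strand-aware signed distance from each
gene's TSS to the nearest site midpoint (positive = upstream), forms the 2×2
table of "has a site within the window" (default 500 bp upstream) by gene
set, and applies Fisher's exact test (two-sided). The test choice is a
package decision — the analysis it mirrors names no test — and scipy's
implementation is verified in the suite against exhaustive hypergeometric
enumeration for every 2×2 table with n ≤ 20.

## Synthetic study conditions

The fixture generators define the conditions every desk-scale result is
computed under; they emulate the *structure* of homeodomain PBM data, not any
particular array.

**Table.** Noiseless score = baseline (−0.05) + the best core contribution
over both strands. A contribution is the core weight (AAGT 0.20, GAGT 0.18)
plus position-dependent flank bonuses (T at −1: +0.10; G at −2: +0.02; A at
+4: +0.10; C at +5: +0.02), a pairwise interdependency term (T at −1 *and* A
at +4: +0.10 — deliberately non-additive, the property PWMs cannot encode),
and a small per-start-position gradient (0 to +0.016). The favoured flanks
coincide with a tandem period-4 core repeat, so octamers tiled across a
repeated-core site all score high — the dense-window structure real binding
sites show under PBM scoring. The best octamer lands at 0.498; the
all-octamer mean is ≈ −0.03; core-containing octamers average ≈ 0.19–0.21
with a wide flank-driven spread, mirroring the magnitudes real homeodomain
arrays exhibit. Gaussian noise (default sd 0.02) is drawn once per canonical
pair and mirrored, so symmetry is exact even with noise; scores clip to
[−0.5, 0.5]. The manifest records every octamer's noiseless score and implies
the expected census at any cutoff.

**Sites and genomes.** Achievable window scores of a core-driven table are
quantized (a mutation that breaks a core moves several octamers at once), so
planted sequences are chosen from a *score ladder*: a breadth-first
enumeration of realisable peak levels reached by single-base mutations
outward from dense core tilings (~600 levels for 14 bp sites, gaps < 0.01
over the calling range). Each requested target gets the nearest rung, with an
optional side constraint keeping it strictly above or below the call
threshold; manifests always record the achieved value, never the request.
Background is order-0 sequence at GC 0.42; after assembly the genome is
rescanned and accepted only if thresholded calls correspond 1:1 with the
supra-threshold planted sites and each call's peak equals the planted
in-situ peak (the maximum over windows overlapping the planted interval —
junction windows belong to a site's call and are part of its ground truth).
Bounded retries with fresh background; unsatisfiable specs raise.

**Probes.** Regression probes are constructed whole (30 bp: site plus 8 bp
flanks) so the probe's maximum window average — exactly what the scanner
reports — lands on targets spread over [0.05, 0.44]. Occupancy `F = a·x + b`
(defaults a = 0.8, b = 0.1, z = 2.0, chosen so F stays inside (0, 1) over the
score range) generates fraction bound and Kd through the package's own
occupancy identities; multiplicative Gaussian noise perturbs the two
measurements independently. At zero noise the fits recover the generating
parameters exactly, which is the designed sanity anchor for the regression
stack.

**What passing does and does not show.** The generators share the package's
octamer machinery but none of its scanning, census or regression code paths,
and manifests are sufficient to recompute every expectation without
re-running generation. Passing shows the algorithmic pipeline is correct
under conditions with a planted, noise-perturbed ground truth. It does not
show that real PBM data satisfy the generator's assumptions: real E-score
noise is rank-correlated rather than i.i.d. Gaussian, real flank effects
extend beyond ±2 bp, real genomic background contains repeats and
compositional heterogeneity the order-0 model lacks, and real thresholds
must be calibrated per factor against binding assays.

## Numerical choices and degenerate inputs

* Rolling sums in float64; the naive-equality contract is 1e-12.
* BED scores rescale the peak linearly from [threshold, 0.5] to [0, 1000],
  rounded to nearest; ranks order by descending peak.
* PWM log-odds with zero pseudocount: zero-frequency cells score −inf for
  windows touching them; an error advising a pseudocount is raised only when
  no window attains a finite score (a pure-count consensus still scores).
* Non-strict E-score reading averages conflicting octamer/revcomp scores
  with a warning (third-party files round asymmetrically); strict mode
  raises.
* Sequences shorter than `W + 7` raise a "no scoreable window" error naming
  the minimum length; probes of 8–13 bases still get `max_escore` with the
  window score flagged undefined.
* Empty top set in the census warns and returns zero counts rather than
  raising.

## Known limitations

* Genome-scale behaviour (millions of calls, unstated merge conventions) is
  out of the desk-scale test surface; chunked scanning is tested to 5 kb
  sequences and is O(L) memory-bounded by construction.
* The Welch t-test for core-group means compares a subset against the full
  population (overlapping samples); with n = 65,536 the p-values are
  effectively 0 and serve as a sanity gate, not a calibrated test.
* `k ≠ 8` code paths exist in the encoders but only k = 8 is exercised.
* The reproduction harness embeds published reference values and compares at
  printed precision; it is opt-in and requires externally downloaded PBM
  tables.

## Problem sizes

Default test and acceptance conditions: full 65,536-octamer tables; 10 kb
genomes with 5 planted sites; 24-probe regression sets; 200 random
sequence/table draws for the scanner-equality check; 50 random parameter
draws for Kd recovery; 100–200 replicates for noise and enrichment
simulations. These sizes make the whole suite run in well under a minute per
module while keeping every statistical check comfortably powered.
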