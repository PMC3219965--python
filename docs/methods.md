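# Methods

## The polymer model

Chromatin is treated as a freely jointed chain of Kuhn statistical segments.
A segment holds `S` kb of DNA and spans `S·L` nm of fiber, where `L` is the
linear mass density of the fiber (nm of fiber per kb of DNA). The random
crosslinking (collision) frequency between two sites `s` kb apart is the
worm-like-chain interpolation

    X(s) = 0.53 · k · β^(−3/2) · exp(−1.8/β)

with `k` an arbitrary crosslinking-efficiency scale and `β` the effective
number of Kuhn segments separating the sites. `β` is tied to the mean
spatial distance `⟨R⟩` between the sites by `β = (⟨R⟩/(S·L))²`, so a chain
geometry is specified entirely by its `⟨R⟩(s)` law:

* **linear** — `⟨R⟩ = L√(sS)` (ideal-chain scaling), hence `β = s/S`;
* **circular** — a Gaussian ring of apparent size `c` kb:
  `⟨R⟩ = L√(S·s(c−s)/c)`, hence `β = s(c−s)/(Sc)`, symmetric in
  `s ↔ c−s`;
* **statistical helix** — the fiber is wound, on population average, on a
  helix of mean diameter `D` nm and mean step (pitch) `P` nm. `s` kb of DNA
  is `sL` nm of fiber path; one turn consumes `√(π²D² + P²)` nm of path, so
  the winding angle is `θ = 2π·sL/√(π²D²+P²)` and

      ⟨R⟩² = D²·sin²(θ/2) + (P·θ/2π)²

  (chord across the cylinder plus axial rise). Limits: at `P = 0` this is a
  closed circle of diameter `D`, periodic in `s` with period `πD/L`; at a
  full turn the chord vanishes and `⟨R⟩ = P`; as `P = 0` and `D → ∞`
  (finite `s`) the chord tends to the arc and the linear law is recovered
  only in scaling, not exactly — the helix is a rigid-geometry
  approximation, and at small `s` it gives `β ≈ (s/S)²` rather than the
  linear chain's `s/S`. The three `β` laws are locked to the `⟨R⟩` laws by
  property tests (substitution identity to 1e-9 relative over random
  parameter draws): any transcription error in one of the closed forms
  breaks those tests.

`X` is singular at `β = 0` (coincident sites, or an exact closed turn when
`P = 0`); all operations raise explicit domain errors there rather than
returning infinities. Units are fixed throughout: `s`, `S`, `c` in kb;
`L` in nm/kb; `D`, `P`, `⟨R⟩` in nm; densities in nm³/kb; macroscopic
volumes in μm³ (1 μm³ = 10⁹ nm³). Defaults: `L = 9.6` nm/kb (mammalian
chromatin, 6 nucleosomes per 11 nm at a 190-bp repeat), `L = 11.1` nm/kb
for yeast analyses.

The exact constants of the `X(s)` interpolation (0.53, 1.8) matter little
for anything downstream: the turn length depends only on the extrema of
`β(s)`, the volumetrics not at all, and fits absorb overall scale into `k`.

## Turn length (`Sh`)

The DNA content of one helix turn is located on the model curve, not read
from the geometry: `Sh` is the site separation at the first local maximum
of `X(s)` beyond the small-`s` mode (equivalently the first local minimum
of `⟨R⟩` near one geometric turn — the axial rise drags the minimum
slightly before the full turn, `Sh ≈ turn/(1+(P/πD)²)`). It is found by
scanning `dX/ds` on a log-spaced grid, bisecting the first downward zero
crossing, and polishing with a bounded scalar minimization; a brute-force
0.001-kb grid search serves as the independent oracle (agreement within
0.01 kb is asserted). At the best-fit mammalian helix
(`D = 292.03`, `P = 162.13`, `S = 2.709`, `L = 9.6`) this gives
`Sh = 94.091` kb.

## Volumetric density

The volumetric mass density of a folded structure is the enclosing
cylinder's cross-section times its axial extent per kb of DNA:

    V = π·(D/2)²·⟨R⟩/s.

For the reference 30-nm fiber, `D = 30` nm and 1 kb occupies
`⟨R⟩ = 9.6` nm of axial extent: `V = 6.79×10³` nm³/kb. For the statistical
helix the natural evaluation point is one full turn, where the axial extent
is the step (`⟨R⟩ = P`). The DNA content of that turn is the fiber path
length divided by `L`, with the path measured on the wound fiber of 30-nm
thickness, i.e. at diameter `D + 30`:

    s_turn = √(π²(D+30)² + P²)/L = 106.73 kb,
    Vs = π·(D/2)²·P / s_turn = 1.017×10⁵ nm³/kb.

This evaluation point was fixed by internal consistency: it reproduces the
companion arithmetic exactly (fold increase `Vs/V = 15.0`; a diploid genome
of 2×3×10⁹ bp folded this way occupies `Vs·6×10⁶ kb = 610 μm³`, versus
~524 μm³ for a 10-μm spherical nucleus), whereas measuring the turn's DNA
content on the center line (`97.05` kb/turn) yields `1.12×10⁵` nm³/kb and
breaks all three derived numbers by ~10%. The choice is a package decision
and is isolated in one function (`helix_volumetric_density`).

## Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) with free parameters `(k,S)` linear, `(k,S,c)` circular,
`(k,S,D,P)` helix; `L` is always fixed. The helix objective is multi-modal
in `(D,P)` — the oscillation can lock onto the wrong harmonic — so every
fit runs a deterministic multi-start grid (`S ∈ {1, 2.5, 5}`,
`D ∈ {100, 200, 300, 400}`, `P ∈ {50, 150, 300}`, `c ∈ {60, 110, 200}`,
`k` from a closed-form scale match at the median point) and reports the
best optimum over starts. Bounds keep parameters positive and off absurd
plateaus (`D, P ≤ 2000` nm, `S ≤ 50` kb, `c ≤ 1000` kb; for the circular
family `c` is additionally bounded below by the largest observed
separation, which the model requires). Standard errors are asymptotic
(Jacobian at the optimum, residual variance at `n − p` dof);
`R² = 1 − SSres/SStot` about the (weighted) mean. Convergence: 1e-10
relative tolerances, 5000 evaluations per start; a start that exhausts its
budget still contributes its point as an uncertified candidate.

**Weighting.** The default objective is unweighted, with a `1/sem²`
weighted option when per-point standard errors are available. Contact
frequencies span two orders of magnitude across 5–340 kb, so the unweighted
objective is dominated by the few large short-range points; under
multiplicative noise this admits a degenerate ridge `S → 0`, `k·S³`
constant (once the exponential suppression is switched off, only the
product is identified). The weighted objective removes the ridge, and the
recovery study and analysis drivers therefore use it. Even weighted, `S`
remains only weakly identified at the study's sampling design — it enters
mainly through the exponential suppression at the shortest separations —
while `D` and `P` (set by the phase and amplitude of the oscillation) are
recovered to a few percent. Replicate assays are averaged to one point per
(anchor, site) before fitting, with the sem retained.

## Modulation scan

Floating mean: half-open windows `[start, start+window)` with `start`
stepping by `shift` from 0 (defaults 20 and 10 kb; 45/22.5 kb exposed for
coarser smoothing), reported at window midpoints; empty windows are
missing, never zero. Extrema: sign changes of first differences beyond
`s_min` (default 40 kb), plateaus resolved to midpoints. Supranucleosomal
domains: half-open bins [0,35), [35,70), [70,115), [115,160), [160,205),
[205,250) kb (D.I–D.VI); points ≥ 250 kb go to an overflow bin excluded
from domain statistics. Tests are two-sided Mann-Whitney U: exact
distribution when the smaller group has ≤ 8 points and there are no ties,
tie-corrected normal approximation otherwise (the exact branch is verified
against full enumeration in the tests). Extremum windows are `[s−hw, s+hw)`
with `hw = 15` kb by default (20 kb exposed). Star convention: `*` p<0.1,
`**` p<0.05, `***` p<0.01. Raw p-values only; no multiplicity correction.

Testing extrema chosen from the same data inflates type-I error. The scan
records this caveat in its metadata and offers a split-half mode (locate on
half the anchors, test on the rest). Locus-specific peaks — sites exceeding
4× the median frequency of their ±20 kb neighborhood — are flagged, since
the random-collision analysis assumes none.

## Synthetic data

The generators are pure functions of (design, seed) and emit ground truth
alongside every table.

* **Contact profiles** — site separations drawn uniformly per anchor from
  both sides and pooled by absolute value; frequencies are `X(s)` under
  multiplicative lognormal noise with mean 1 (3C quantifications are
  positive with scale-proportional error), `cv = 0.2` by default, averaged
  over 3 assays with the sem retained. Optional spikes multiply `X` at
  chosen sites to emulate locus-specific peaks.
* **Gene-desert profiles** — a very flexible linear chain (`S = 0.2` kb)
  plus an additive floor at 0.5% of `X(1 kb)`: collision frequency falls
  below 10% of its 1-kb value by 6 kb and shows no long-range structure.
* **Co-expression fixture** — cluster gene pairs 100 kb apart with
  within-pair expression correlation ≥ 0.9 over 20 tissues (alternating
  sign to exercise the `r ≤ −0.8` branch), background genes 1 Mb apart
  with independent expression, and a housekeeping-flagged co-expressed
  decoy cluster. Conserved elements are placed around the primary gene of
  each pair at TSS distances drawn from a chosen per-domain weight vector,
  and uniformly around background genes; decoy elements inside
  transcription units and promoters exercise the filters.
* **Hi-C tag pairs** — alternating Giemsa-negative/positive 5-Mb bands
  over a 4-kb restriction tiling; intra-band fragment pairs drawn with
  per-class, per-domain separation weights; a controllable fraction of
  interactions is emitted with multiplicity ≥ 4 so the multiplicity filter
  retains a known subset. Pairs never span band boundaries.

What the generators do *not* emulate: locus-specific looping beyond simple
multiplicative spikes, distance-dependent noise structure, restriction-site
sequence bias, inter-chromosomal (trans) contacts, copy-number or
mappability artifacts, and the real genome's gene/element landscape.
Passing the closed-loop tests therefore demonstrates that the pipeline
recovers what it assumes, not that those assumptions hold in real data.

## Enrichment analyses

Gene selection: housekeeping genes are removed first; candidate pairs are
same-chromosome TSS pairs < 400 kb apart; Pearson `r` is computed over
tissues observed in both genes (≥ 15 required); pairs with `|r| ≥ 0.8`
(similar or opposite patterns) are retained. Element counting: distances
from each selected gene's TSS to element midpoints < 250 kb, after
excluding elements inside any transcription unit or within 3 kb of any
TSS; counts normalized to the total over D.I–D.VI. Baseline: 30 draws of
130 random genes (the full fixture-scale analyses use smaller draws) with
the 95% CI half-width `E = t·σ/√N`, `t = 2.04` (Student, 29 dof) kept as a
fixed constant; Shapiro-Wilk normality is checked per domain (a warning,
not a failure). Deviations are reported as `100·(obs−μ)/μ` with one-sample
t-tests of the randomization distribution against the observed value.

Hi-C: tag positions are replaced by restriction-site positions (direction
0 → the fragment's 3' end coordinate, direction 1 → the 5' start, with
0-based half-open fragments); pairs must fall entirely within one band;
bands classify as G-negative (`gneg`) or G-positive (`gpos50/75/100`),
with `acen`/`gvar`/`stalk`/`gpos25` excluded; unique fragment pairs need
multiplicity ≥ 4 (directions ignored); per-class domain fractions are
compared across experiments by unpaired t-tests (paired optional). All
filters are individually toggleable and their reject counts logged.

## Problem sizes

The shipped analyses and tests run at fixture scale, chosen to keep the
whole suite fast while leaving every statistical mechanism exercised:
contact profiles of 120–300 points, recovery studies of 50 replicates at
250 points, 20–30 randomizations over ~100-gene fixtures, and Hi-C sets of
a few thousand tag pairs over ten 5-Mb bands. All scale linearly (or, for
the pairwise gene scan, near-linearly within the 400-kb window) to
database-scale inputs.

## Known limitations

* The helix `⟨R⟩(s)` is a rigid-geometry population average; it understates
  conformational variance, so predicted spatial distances are means, not
  distributions, and the small-`s` regime (`β < ~1`) is outside the model's
  validity.
* The model is not meaningful above ~1 Mb, where territory confinement and
  globule-like organization dominate; no fractal-globule modeling is
  attempted.
* Extremum-window p-values inherit the selection bias discussed above
  unless split-half mode is used.
* Asymptotic standard errors can be optimistic near parameter bounds or on
  the weakly identified `S` direction; no bootstrap or posterior sampling
  is provided.
* Real READ/UCSC/GEO inputs are accepted by format but ship nowhere with
  the package; results on them depend on database versions and are not
  pinned by the tests.
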