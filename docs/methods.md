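# Methods

`paintqc` quantifies the *addressability* of DNA origami — whether each
designed docking site is actually there and available for hybridization —
from DNA-PAINT localization tables. This note documents the models, the
numeric choices, and what the synthetic-data generator does and does not
emulate.

## Binding-kinetics model

Imager binding at a docking site is an alternating renewal process: dark
times ~ Exp(τ_d), bright times ~ Exp(τ_b), starting dark. Defaults are
τ_d = 12.5 s and τ_b = 0.5 s. Nominally τ_d = 1/(k_on·c) with
k_on = 1.6×10⁶ M⁻¹s⁻¹ and c = 5 nM; that arithmetic gives 125 s, a
factor of ten above the 12.5 s operating point, so the simulator treats
τ_d as an explicit parameter (default 12.5 s) and derives it from k_on·c
only when it is not given. The expected number of binding events over an
acquisition of length T is T/(τ_d+τ_b) ≈ 230.8 for the default 50-minute
acquisition (15,000 frames × 200 ms).

## Localization emission

Each bright interval is discretized into camera frames. Every overlapped
frame emits one localization with

    photons = (photon rate × power density) × overlap [ms]
            = 35 × 1.5 × overlap,

i.e. 10,500 photons for a fully covered 200-ms frame, with cumulative
photons per binding event capped at the 1.5×10⁶ photon budget (at
τ_b = 0.5 s the cap essentially never binds). The localization position is
the true site position plus isotropic Gaussian error with per-axis

    σ = psf_σ / √photons,   psf_σ = FWHM / (2√(2 ln 2)) = 309 / 2.3548 ≈ 131.2 nm,

which is also the recorded precision (≈ 1.28 nm at 10,500 photons).
Localizations below 100 photons (frame overlap < 1.9 ms) are discarded,
mimicking the detection floor of spot-fitting software. A bright event
therefore produces on average 1 + τ_b/Δt ≈ 3.5 localizations, and a
present site roughly 230.8 × 3.5 ≈ 800 over a full acquisition. The two
partial frames of each event carry fewer photons and correspondingly worse
precision (up to ~13 nm); this matters downstream (see thresholding).

Tables are drift-free (they model the output of localization software
*after* drift correction), contain no background localizations by default,
and use camera-pixel coordinates with 0-based frames; all analysis happens
in nm, y-up, relative to a pick center, converted in one place (`locio`).

### What the generator does not emulate

Raw camera frames and spot fitting; drift and its residuals; non-specific
sticking and background localizations; photophysical heterogeneity between
sites; partially sequestered sites with slowed binding; day-to-day imager
concentration drift. Passing tests therefore demonstrate that the
*analysis* is unbiased under the stated kinetic model, not that real
samples behave ideally — which is exactly the role the in-silico
benchmark plays in the accompanying analyses.

## Designs

* **20-nm grid** — 12 probed sites on a 4×3 lattice at 20 nm pitch. The
  row/column split is a package choice consistent with 12 sites on the
  2D rectangle; the grid is 180°-rotation and mirror symmetric, so
  analyses of it report site-averaged efficiencies.
* **Arrowhead + line** — a 9-site asymmetric registration pattern (5-site
  chevron + 4-site collinear row) that breaks rotational and mirror
  symmetry. Its exact coordinates, the 14×13 staple lattice at 8×7 nm
  pitch, the 5 biotin-adjacent excluded cells, and the 18×12
  variant-to-staple assignment are synthetic fixtures: only asymmetry,
  uniqueness and coverage matter to the method, and the pipeline is
  geometry-generic.
* **3 BS / 6 BS** — one six-site layout probed either fully (6 BS) or on
  sites 1–3 only (3 BS); the unprobed sites of the 3 BS variant are scored
  as absent-by-design to measure false positives.
* **18-variant library** — variants v01–v14 tile the 168 addressable
  staple positions disjointly (168 = 14×12); v15–v18 re-probe 48 evenly
  spaced positions, so probed sets are pairwise distinct and the union is
  the full 168.

Templates are rendered by placing unit-amplitude Gaussians (σ = 3, 2 or
1 nm depending on the analysis) on every probed and alignment site; the
template encodes design geometry, not binding kinetics. The auto-chosen
extent covers the full site layout plus a 4σ + 10 nm margin, so all
variants of a library share one pixel grid (which also enables the fast
shared-stack classification below).

## Alignment

A picked structure is rendered as a 2D histogram on the template grid
(1–2 nm bins), blurred to the template σ, rotated stepwise through 360°
(default step 1°), and cross-correlated with the template in the frequency
domain; the peak of the correlation map provides the translation. Scores
are normalized by the image norms, corr = ⟨T, S⟩/(‖T‖‖S‖) ∈ [0, 1], so
they are comparable across templates. Ties are broken towards the smaller
angle and the non-mirrored orientation; mirror search is off by default
(structures attach by one face). The translation search is bounded
(default 50 nm — picks are centred on the localization centroid, so true
shifts are tens of nm at most), which also keeps the FFTs small. For
library classification the rotated histogram stack is computed once per
structure and correlated with every template.

The minimum-correlation cut replaces the interactive discarding of
structures without a correct alignment pattern. It defaults to 0.45 for
designs that *have* an alignment pattern — simulated structures score
≈ 0.8 against σ = 1 nm templates while uniform-noise picks score ≈ 0.1–0.25
— and to 0 for the plain grid, which has no pattern to verify (and where
sparse low-presence structures legitimately score low; discarding them
would bias efficiencies upward).

Known limitation: rotation is searched on a fixed global grid without
sub-step refinement, and translation is quantized to one bin. Both are far
below the 5+ nm feature scale of the designs.

## Counting and thresholding

Localizations are counted in closed discs (diameter 20/18/6/5 nm per
analysis preset) around the designed site positions; a localization
contributes to its nearest site only, so overlapping discs cannot
double-count. A diameter exceeding the minimum site spacing is rejected.

Detection calls use a cut-off threshold estimated from the pooled
per-site counts histogram (alignment sites excluded). Sites with zero
counts are trivially undetected and excluded from the fit. Undetected and
absent sites still accumulate a few stray counts — the wide partial-frame
localizations of neighbouring sites — so when the positive counts split
into low and high populations separated by an empty gap wider than 30% of
the count range, the fit is restricted to the high population. A single
Gaussian is then least-squares fitted to the contiguous histogram bins
within 10% of the modal height (Freedman–Diaconis binning by default).

Two threshold rules are derived from the fitted (μ, σ):

* `fwhm` — the lower half-maximum of the fitted peak, μ − σ√(2 ln 2).
  This is the textbook reading of a "half-maximum" cut, and it is what
  `fit_threshold` returns by default.
* `half_peak` — half the peak position, μ/2.

The two nearly coincide for the broad, skewed count histograms of real
measurements (they are equal at σ/μ ≈ 0.42). They diverge for the narrow
count distributions of simulated data (σ/μ ≈ 0.08), where the `fwhm` cut
sits *inside* the detected population and, by construction, classifies
Φ(−√(2 ln 2)) ≈ 12% of a homogeneous Gaussian population as undetected —
no matter how well the experiment worked. A cut intended to separate
detected from undetected populations must fall in the valley between
them, which μ/2 does whenever the populations are resolvable. The
analysis pipeline therefore defaults to `half_peak`; with it, the
in-silico 3 BS / 6 BS benchmark yields 0% false positives and 100% true
positives, and detected fractions track simulated presence probabilities
on the identity line. Both rules are exposed, and a manual override is
available for histograms the fit cannot handle.

Calls are inclusive (detected ⟺ count ≥ threshold; threshold floored at
1). Absent-by-design sites are called identically but never enter
efficiency denominators; their detected fraction is the false-positive
rate. Per-site efficiency is the detected fraction across structures;
per-structure efficiency the detected fraction across probed sites; the
grand average is the mean of per-structure values. Bootstrap errors follow
the subset scheme of the single-site analyses: 10 repetitions of 250
randomly chosen structures, std across repetitions.

## Two-color statistics

For staples carrying orthogonal 3′- and 5′-end docking sites imaged in two
channels, each site instance is tallied as both / only-3′ / only-5′ /
none. Under channel independence the chance that an incorporated staple
escapes both channels is chance_none = (f_only5+f_none)(f_only3+f_none);
when that is far below the observed f_none, the no-signal category is
attributed to missing incorporation, incorporated = 1 − f_none, and
offset = incorporated − det3′ translates measured detection (=
accessibility) into absolute incorporation, clamped to [0, 1]. The offset
is always recomputed from data; 7% (the whole-percent value the published
tally supports) is only a fallback default.

Efficiency vs staple molar excess is fitted with an unweighted
least-squares Michaelis–Menten curve E(x) = v_max·x/(K_m + x); constant
inputs drive K_m → 0 and are flagged degenerate. Heatmaps merge
per-variant site efficiencies by staple label, weighted by structure
counts; biotin-adjacent positions carry no value.

## Problem sizes and reproducibility

The acceptance script simulates 50 structures per design (3 BS and 6 BS)
at the full 15,000-frame conditions — the same population size as the
in-silico benchmark it reproduces — and runs in a few minutes on one CPU.
The test suite uses shortened acquisitions (1,500–3,000 frames) for unit
tests, full conditions for the acceptance tests, 100 structures for the
rotation-recovery check, one structure per variant for the 18-template
classification check, and 50 structures per presence level (30–100%,
step 10) for the calibration check. All randomness flows from a single
master seed through per-structure child streams, so every table is
reproducible record-for-record.
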