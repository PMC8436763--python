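# Methods

## The measurement being modeled

A patched cortical pyramidal neuron is dialysed with the Ca²⁺ indicator
OGB-1; an axonal bouton is imaged with a spiral ("tornado") line scan
that covers the bouton profile once every 1–1.5 ms, while
time-correlated single-photon counting (TCSPC) timestamps every detected
photon relative to the femtosecond excitation pulse (80 MHz repetition,
12.5 ns inter-pulse window). One trial yields a photon-count cube
*t × x × y × T*: nanosecond decay bin × scan pixels × scan cycle. All
spatial structure is discarded (summed) before analysis — the bouton is
treated as one compartment — and scan cycles are pooled into ~7 ms FLIM
time bins.

## Decay model

The emission decay at free-calcium `ca` is a mixture of two
monoexponentials, truncated and renormalized on the inter-pulse window:
the Ca-free state (lifetime τ_free) and the Ca-bound state (τ_bound).
Binding is a single-site equilibrium with dissociation constant
K_d = 240 nM, and the bound state is γ = 6 times brighter, so the
probability that a *detected* photon comes from the bound state is the
brightness-weighted bound fraction

    w(ca) = γf / (γf + 1 − f),  f = ca/(ca + K_d)
          = ca / (ca + K_d/γ).

Total fluorescence then follows F(ca) ∝ (ca + K_d/γ)/(ca + K_d) — the
same saturation law the Δ[Ca²⁺] estimator inverts, so simulator and
estimator are one self-consistent model. Excitation is a delta at the
origin bin (the laser pulse is two orders of magnitude shorter than the
decay); an optional Gaussian instrument-response blur is available for
robustness testing.

Component lifetimes are package defaults, not measured constants:
τ_free = 0.7 ns, τ_bound = 3.7 ns. They produce a strictly monotone NTC
curve spanning ≈ 14.5–68 (250 × 0.05 ns binning) with its logistic
midpoint at E₅₀ ≈ 195 nM, inside the 10–300 nM range where the readout
is validated. Both are configurable on `IndicatorModel`.

## The NTC statistic and calibration

NTC = (counts summed over 9 ns from the pulse-peak bin) / (histogram
peak). The peak and origin are located on a 3-bin moving-average
smoothed histogram (raw maximum available by flag) to reduce shot-noise
bias at low counts; the window sum always uses raw counts. Histograms
with a total below 1000 photons (no reliable decay tail) or a peak
below 10 counts are flagged, not decoded.

A useful exact property of the two-state model: NTC is a ratio of two
affine functions of w (a Möbius transform), and w is itself a Möbius
function of `ca`, so NTC(ca) is *exactly* a 4-parameter logistic in
log₁₀ ca with hill = 1. The logistic calibration

    NTC = low + (high − low) / (1 + 10^{hill (log₁₀E₅₀ − log₁₀ca)})

is therefore model-exact here (fitted hill ≈ 1 is a built-in
diagnostic); on real dyes it is an empirical sigmoid. The fit
(`scipy.optimize.curve_fit`) requires ≥ 5 distinct levels, maps nominal
zero-Ca solutions to a 1 nM floor for the log axis, refuses non-monotone
results, and stores the parameter covariance plus a hash of the TCSPC
binning — NTC is bin-width dependent, and decoding with a calibration
from a different binning is rejected. Inversion is closed-form;
NTC values outside the open asymptote interval are flagged
out-of-range, never extrapolated or clamped. Decoded uncertainties use
the delta method with the first-order shot-noise variance
Var(NTC)/NTC² ≈ 1/S + 1/P (S window sum, P peak count), which scales as
1/N as photons accumulate.

## Basal level and evoked entry

[Ca²⁺]₀ is the photon-weighted mean of the decoded timeline over the
500 ms before the action potential (≥ 10 usable bins required, else the
recording fails QC). The evoked rise equilibrates across the bouton in
1–3 ms — faster than a FLIM bin — so the peak is taken from the
per-cycle intensity trace and converted through the saturation
correction (F_max, then [Ca²⁺]_peak; equations in the README). Both
equations are ratios, so the intensity trace needs no absolute scale.

F_peak estimator: the default is the mean of the raw trace over
[AP + 3 ms, AP + 20 ms]. A max-over-window estimator (available as
`peak_method="max"`) carries a positive order-statistic bias of about
+1 nM at ~14 000 photons/cycle, enough to push the null-transient
confidence interval off zero; the window mean is unbiased under shot
noise and loses only ~2% of a transient decaying with τ = 400 ms.
Saturation guard: peaks above 0.95·F_max (or below the Ca-free floor
F_max/γ) leave Δ[Ca²⁺] missing rather than reporting a divergent value;
such boutons keep [Ca²⁺]₀ and enter only the resting-level analyses.
Trial-to-trial QC: recordings whose basal or evoked values vary by more
than 20% CV across trials are discarded. As an independent check,
`crossvalidate_decay` compares the amplitude-normalized intensity and
FLIM decays where decoded [Ca²⁺] ≤ K_d/2 (near-linear dye response) by
RMS difference, with a mismatch threshold of 0.35 chosen to separate
self-consistent simulations (scores ≈ 0.05 at realistic photon rates)
from structurally wrong traces (≥ 1).

## Statistics

Boutons are the statistical unit, nested 1–4 per cell. Branch-order
effects are tested twice: Kruskal–Wallis on branch order alone
(conservative, rank-based), and a two-way ANOVA with branch order and
cell identity, no interaction, Type II sums of squares (the design is
unbalanced and only main effects are of interest). Paired
baseline-vs-condition comparisons use a Shapiro–Wilk gate on the paired
differences at α = .05: rejected → Wilcoxon signed-rank with Pratt
handling of zero differences, otherwise paired t. Degenerate inputs
(all observations identical; all differences constant) return explicit
no-effect results instead of erroring. No multiplicity correction is
applied; p-values are raw.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical* structure the analysis
relies on: Poisson photon counts with the correct decay shape and
saturation-scaled flux; a resting level, a fast (2 ms) evoked step and
slow (400 ms default) exponential relaxation; populations of boutons
nested in cells (~2 cells per animal) with branch-order means,
between-cell and within-cell Gaussian variability truncated at zero,
and multiplicative condition effects applied to the same bouton across
conditions (paired design). Default branch-order means (31/45/34 nM
resting, 42/76/101 nM evoked) match the observed control population;
the TBOA-like condition scales evoked entry to 0.31 of control. The
paired-sample generator for power analyses uses a shared per-bouton
lognormal effect (CV 0.45) times per-condition lognormal measurement
noise (CV 0.2), giving group CVs near 0.5 with realistic within-bouton
correlation.

Not emulated: optical point-spread and pixel structure (spatial
information is discarded by the analysis anyway), dye diffusion and
buffering kinetics, bleaching, detector afterpulsing, and
instrument-response shape beyond the optional Gaussian blur. Passing
recovery tests therefore demonstrates the *decoding chain* is unbiased
and well-calibrated under shot noise — not that any particular
photophysical parameterization of a real dye is correct.

## Numerical and design choices

- Binning: 250 × 0.05 ns bins (12.5 ns window) shared by calibration
  and experiment; the calibration stores a binning hash to prevent
  mismatched reuse.
- Scan geometry: 4 equal-dwell pixels per 1 ms cycle by default; pixels
  only partition the photon flux.
- Calibration ladder default: {17, 38, 100, 150, 300, 602} nM at 10⁶
  photons per level.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`; experiment batches spawn child seeds via
  `SeedSequence`), making every pipeline product bit-reproducible.
- Validation problem sizes (chosen to characterize the estimators
  precisely at desk scale): 20 seeds per concentration level at 10⁵
  photons per 7 ms bin; a 3 × 3 (Ca₀, Δ) grid at ~14 300 photons/cycle;
  200-run power and 2000-run type-I simulations; a 16-bouton, 10-cycle
  stability run.
- Trial combination: multiple trials of one bouton are combined at the
  estimate level (mean of per-trial estimates) in the scenario runner;
  cube-level pooling is available through `collapse_cube` on summed
  cubes.

## Known limitations

- The two-state decay with delta excitation is idealized; real OGB-1
  calibrations show instrument-response convolution and minor
  multi-exponential structure, so fitted hill values off 1 on real data
  are expected and handled by the free-hill logistic.
- The shot-noise NTC variance is first order and ignores the
  sum–peak covariance; uncertainties are indicative, not exact.
- The scenario runner models one action potential per trial; train
  stimulation and use-dependent plasticity are out of scope.
- Absolute photon flux is arbitrary: only ratios enter the estimators,
  so photon_rate is a noise knob, not a radiometric quantity.
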