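# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `lipomech`. Nothing here reports an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Lipidomics profiling

Species are identified as `<class> x:y` (total acyl carbons x, total C=C
double bonds y) for the four major phospholipid classes PC, PE, PS, PI.
Diacyl-PC monoisotopic masses follow the elemental composition
C(x+8) H(2x+16−2y) N O₈ P; one double bond removes one H₂
(2.0156500638 Da), one pair of chain carbons adds C₂H₄ (28.0313 Da).
Peak annotation matches singly charged adducts ([M+H]⁺ in positive mode,
[M−H]⁻ in negative) to the nearest candidate in ppm, default tolerance
5 ppm; ppm-ties are left unassigned with a warning. Only PC masses are
computed — PE/PS/PI tables are accepted pre-annotated. Isotopologue
overlap (the M+2 isotope of an x:y+1 species falling on the M peak of x:y)
is ignored; at the 1–2 % level this inflates the less-saturated neighbour
of an abundant species.

Relative abundance is intensity normalized per lipid class (× 100), so a
species table is a set of per-class distributions. The DB index bins those
percentages by y ∈ {0}, {1}, {2}, {>2}; the DHA/AA ratio is
(PC 36:6 + 38:6 + 40:6) / (PC 36:4 + 38:4 + 40:4). PCA of DB indexes is
mean-centered and unscaled, computed by SVD; explained variances are
reported over all min(n−1, 4) components and sum to 100 %; each
component's sign is fixed by making its largest-magnitude loading
positive. Identical rows are reported as rank deficiency, not an error.

## VLD trace analysis

Traces are normalized to relative fluorescence (F − F₀)/F₀ with F₀ the
mean of the pre-shock samples (≥ 3 required); an F/F₀ mode is provided
because both conventions appear in practice, but (F − F₀)/F₀ is the
default and is what the breakage threshold refers to.

Kinetics extraction (`extract_kinetics`), defaults in `KineticsParams`:

- the trace is Savitzky–Golay smoothed (window 5 samples, order 2 — one
  window ≈ 25 s at the 5 s default sampling);
- t₀ is the first post-shock time at which the smoothed trace stays above
  3 × σ(baseline) for 3 consecutive samples (σ from the raw pre-shock
  samples). The appearance time of a sigmoidal rise has no unique
  definition; a k·σ run-length rule is the standard choice and both k and
  the run length are configurable;
- the derivative is the central difference of the smoothed trace, then
  smoothed once more (Savitzky–Golay, window 9). Vmax is the vertex of a
  parabola least-squares fitted around the derivative's argmax, t\_Vmax
  the vertex time. The two refinements exist because the raw maximum of a
  noisy, serially correlated derivative is upward-biased (measured +5–12 %
  on synthetic cohorts) and the parabola vertex is exact for the locally
  quadratic peak of a noiseless logistic derivative (−0.5 % residual
  discretization bias at k ≈ 0.05 s⁻¹);
- the plateau is the mean of the last 10 % of samples; a logistic-fit
  asymptote mode is available for truncated recordings.

On a noiseless logistic A/(1+e^(−k(t−tm))) the extractor recovers
t\_Vmax = tm within one sampling interval and Vmax = A·k/4 within 5 %
(test-enforced). Very fast events (rise time ≲ 2 sampling intervals,
k ≳ 0.3 s⁻¹) are under-resolved at 5 s sampling and their Vmax is
underestimated; at the packaged condition rates this affects ≲ 3 % of
draws.

Breakage is called on the 543 nm channel when the maximal relative
intensity reaches 10 (configurable); the crossing time is linearly
interpolated between samples. The call is monotone in the threshold.

Surface metrics treat adherent myoblasts as hemispheres, so cross-section
area is proportional to surface. The initial surface is the pre-shock mean
area; the percent increase uses the maximum of the post-shock series after
a centered 5-sample moving average (window configurable, 1 = raw). The
smoothing exists because the raw maximum of a noisy, flat-topped series
overestimates the peak and scatters its time by tens of seconds. A series
with no post-shock increase is flagged degenerate.

VLD count bins are {0}, [1,5], [6,10], (10,∞).

## VLD spot detection in image stacks

Spots of 1–3 µm diameter (≈ 8–23 px at the default 0.13 µm/px) are
detected on the final frame inside the cell mask with a
Laplacian-of-Gaussian blob detector; the response threshold is
`threshold_sigmas` (default 4) × the robust in-mask background SD / 2
(the scale-normalized LoG response of a matched Gaussian spot is about
half its amplitude). Candidates are confirmed backward over the last 3
frames (a real VLD persists once formed). Detection is deterministic given
the parameters; on synthetic stacks at SNR 10 precision and recall are
both ≥ 0.95 (test-enforced).

## Membrane post-processing

Extension series scale the membrane-plane box axes per level e by
(1 + e/100) — linear per axis, quadratic in area — with defaults 5 % steps
to 25 %. The chain tilt angle is the angle in [0°, 180°] between a chain's
first→last bead vector and +z (the membrane normal); 0°/180° is
perpendicular to the membrane plane (one lobe per leaflet), 90° in-plane.
Distributions are per-bin probability masses (default bin width 2.5°)
summing to 1, unfolded over [0°, 180°] by default with an optional fold to
[0°, 90°] by α → min(α, 180°−α). The joint (angle, first→last distance)
histogram uses the same conventions and its marginals reproduce the 1-D
distributions exactly on matching bins. Chain first/last beads are
assumed imaged together; chains longer than half the box are rejected as
wrapped rather than silently unwrapped. Distances are reported in nm
throughout.

Surface tension per frame is γ = (L_z/2)·(P_zz − (P_xx+P_yy)/2), converted
from bar·nm to mN/m (1 bar·nm = 0.1 mN/m); the factor ½ assigns the
tension to each of the bilayer's two interfaces and is stated in the
result's convention metadata because conventions differ between codes. A
stretched membrane (P_zz above the lateral pressure) has γ > 0. The
reported value is the time average over the series; the error is the SD of
5 contiguous block means / √5 (block count configurable) — a simple
substitute for an exact autocorrelation-aware estimate, adequate for the
weakly correlated synthetic series and conservative for short real ones.
γ is labelled mN/m; numerically equal values are sometimes quoted as mN/m
vs nN/m in the literature, so the unit string is explicit in the output.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); ground truth is
always attached.

**Species tables** are fixed per-organ/condition PC profiles (muscle and
heart dominated by PC 38:6/40:6; brain by PC 34:1; lung by PC 32:0;
pancreas/liver by DB = 2 species; untreated myoblasts nearly devoid of
PUFA-PC; AA/DHA supplementation shifting mass into 36:4/38:4 and
38:6/40:6 respectively), with multiplicative lognormal jitter and
per-class renormalization. Optionally a matching [M+H]⁺ peak list is
emitted. These profiles reproduce the qualitative organ signatures, not
any quantitative composition.

**Cell cohorts.** Per-condition parameters are calibrated to published
osmotic-downshock statistics of C2C12 myoblasts:

| condition | n | VLDs/cell | t\_Vmax (s) | Vmax (s⁻¹) | surface | t_surface_max |
|---|---|---|---|---|---|---|
| NT | 152 | 3.8 ± 0.3 | 622 ± 21 | 0.016 ± 0.001 | — | — |
| NT VLD-forming | 47 | — | — | — | — | 227.3 ± 14.0 s |
| NT cracked | 58 | 0 | — | — | 19.5 ± 4.0 % | — |
| AA | 103 | 4.2 ± 0.4 | 423 ± 25 | 0.018 ± 0.002 | 12.6 ± 2.8 % (n=96) | — |
| DHA | 148 | 11.4 ± 0.7 | 301 ± 10 | 0.024 ± 0.002 | — | 137.7 ± 6.6 s (n=88) |

(± values are SEMs.) Per-cell/per-VLD quantities are drawn from lognormals
with the quoted mean; the SD is SEM·√n, capped at a coefficient of
variation of 0.6. The cap matters for Vmax and the surface increase,
where SEM·√n would imply CVs above 1 — draws frequently near zero or
double the mean, unmeasurable at 5 s sampling and biologically
implausible; 0.6 keeps the spread generous while every draw stays
physical. Quantities never published were fixed once at plausible values
inside the published brackets: surface increase 15 % (NT/NT-VLD) and
17.5 % (DHA) within the published 12.6–19.5 % range; t_surface_max 180 s
for AA and NT-cracked (between the DHA and NT values); breakage
probability 0.55 for NT (the cracked/VLD-forming split of the published
surface-assay cohort), 0.15 for AA, 0.08 for DHA; breakage times 550–680 s
(after the VLD-formation window, matching the published event ordering);
plateau amplitude 2.0 ± 0.6 relative units.

VLD counts follow a hurdle law: a cell is VLD-free with the published
zero fraction (NT 34 %, AA 20 %, DHA 3 %), otherwise its count is
zero-truncated negative binomial with the mean set so the overall mean
matches the published value and dispersion r calibrated once against the
published bin fractions (AA r=4 → 48 % of cells in the 1–5 bin; DHA r=5 →
50 % above 10; NT r=2, unconstrained). A hurdle rather than a plain
zero-inflated NB because the published 34 % is the *total* zero fraction.

Each VLD's 515 nm trace is a logistic rise pinned to zero at shock onset
(A·(σ(k(t−tm)) − σ(−k·tm))/(1 − σ(−k·tm))), with tm and Vmax drawn from
the condition laws and k solved so the realized peak slope equals the
drawn Vmax; Gaussian noise of SD 0.02 relative units models the
residual noise of an ROI-averaged confocal signal. Recordings are 300
frames at 5 s with the shock at frame 10 — the standard acquisition
geometry. Breaking cells get a 543 nm step to relative ≈ 12 at the drawn
breakage time plus an exponential approach (τ = 15 s); intact cells show
sub-threshold dye entry (relative 0.5–4). Area series rise as
(t/t_peak)·e^(1−t/t_peak) to the drawn maximum and relax, with 0.3 %
multiplicative noise emulating manual outlining error.

What passing the round-trip tests shows: the analysis pipeline is an
unbiased estimator of the generating condition parameters under this
model. What it does not show: robustness to photobleaching, focus drift,
cell migration, overlapping VLDs, non-logistic kinetics or non-stationary
baselines, none of which the generator emulates.

**Image stacks** place cells as disks on a tile grid (128 px tiles, 56 px
cell radius ≈ 15 µm diameter) with non-overlapping Gaussian spots of
1.2–2.0 µm apparent diameter, amplitude SNR × the background noise floor
(Gaussian read noise plus Poisson shot noise of the background, default
SNR 10), constant across frames.

**Trajectories** build two mirrored leaflets of single-chain lipids whose
first→last vectors follow an imposed angle law (lower leaflet mirrored
through the membrane plane) and distance law, with linearly interpolated
interior beads — a geometric oracle for the angle/distance estimators, not
a physical membrane model. **Pressure series** set the tensor anisotropy
so the expected γ equals a target, with Gaussian fluctuations (default
50 bar, emulating the violent microscopic fluctuations of a small
simulation box).

## Reproduction tolerances

`scripts/acceptance.py` regenerates one cohort per condition at the
published size (child seeds derived from `--seed` via `SeedSequence`, one
independent stream per cohort) and reports the statistics recovered by the
pipeline. Because the per-cell SD is SEM·√n, the recovered mean of a
single cohort carries about one published SEM of sampling noise, so each
statistic reproduces its calibration value within 2 SEM with ≈ 95 %
probability per seed — the intended behaviour of a faithfully dispersed
cohort, not an estimator defect (large-sample sampler means are exact to
< 0.5 % and the pipeline tracks each cohort's own ground-truth mean to
1–3 %).

## Pipeline

`RunConfig` is a flat YAML-serializable schema; every module default is a
config key, unknown keys and invalid values raise errors naming the key.
Stages run in the order synth → lipidomics → vld → md; per-stage seeds are
spawned from the run seed, so re-running an identical config is
bit-identical in every CSV and in the JSON report.

## Problem sizes

Default problem sizes were chosen so the whole test suite and a full
acceptance run each complete in well under a minute of CPU: cohorts at
their published sizes (47–152 cells, ≤ ~1700 traces of 300 samples),
detection benchmarks at 100 cells of 128² px × 12 frames, trajectories of
64–400 lipids × ≤ 8 frames, pressure series of 10⁴ frames.
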