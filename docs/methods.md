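# Methods

## Coated-surface estimation from RGB images

Pellets carrying a methylene-blue-dyed film are photographed on black
glass under controlled illumination, so three colour populations are
present: blue-dominant coated film, white/grey exposed cellulose, and a
near-black background. The **threshold estimator** classifies every
pixel with simple colour rules in normalized [0, 1] units:

- background if the brightest channel < `t_bg` (default 0.16);
- coated if `B − max(R, G) ≥ t_blue` (0.08) and `B ≥ v_min` (0.25);
- uncoated if the darkest channel ≥ `t_white` (0.50) and the channel
  spread ≤ `t_gray` (0.15);
- ambiguous otherwise.

Coverage is `100·coated/(coated + uncoated)`; ambiguous pixels are
excluded from the denominator, a conservative and auditable choice (an
alternative would assign them to the nearest reference colour). The
defaults are free parameters of the method — the underlying
blue/white/black rule is qualitative — chosen to sit roughly midway
between the three paint populations so they tolerate a channel noise of
a few hundredths without migration between classes; all are
configurable per image batch.

The **reference-differential estimator** mirrors histogram-comparison
practice: quantize sample and uncoated-reference images into a
32-bins-per-channel RGB histogram (percent of non-background pixels),
form the positive excess `D(b) = max(0, f_sample(b) − f_ref(b))`, and
report the share of the excess falling in bins whose centre colour
classifies as coated. A zero total excess (sample indistinguishable
from the reference) reports 0 % with a warning rather than an error.
This estimator measures *what colour the sample gained* relative to
uncoated pellets; on synthetic images it tracks the true fraction with
a small positive bias, and it is most useful when a per-pixel rule is
hard to calibrate but an uncoated reference lot is available.

Both estimators quantify projected-area coverage only; no correction
for pellet curvature, specular highlights or instance segmentation is
attempted. Batch aggregation reports the mean ± sd over per-image
coverages and keeps the per-image results for audit; a pooled-pixel
aggregation can be had by concatenating rasters into one image.

## The coating factorial and its analysis

The experimental domain is categorical: polymer ∈ {Kollicoat Protect,
Kollidon VA64}, concentration ∈ {1.0, 2.5, 5.0 % w/v}, ratio ∈ {1:1,
2:1, 3:1 mL/g}. Although the 3-level factors look numeric, the model is
deliberately categorical — contrast columns per factor (level 1 → (1, 0),
level 2 → (0, 1), level 3 → (−1, −1); the 2-level factor ±1) — because
that coding, with main effects plus AB and BC interactions (12
parameters), reproduces the reference coefficient set on the packaged
20-run table to within the 0.01–0.03 that rounding to two decimals
allows. The model formula is fixed; there is no automatic term
selection. The fit is ordinary least squares via a QR factorisation,
which also yields the hat diagonals.

Significance uses partial (Type III) F-tests: each term group (A: 1 df,
B: 2, C: 2, AB: 2, BC: 4) is tested by the extra sum of squares of the
full model over the model with exactly that group's columns removed,
against the full-model residual mean square (8 df on the packaged
table). Exact fits report a sentinel p of 0 (positive extra SS) or 1.
We make no claim about which SS convention the original analysis
software used; on this table the significance pattern (all five groups
p < 0.05, C smallest) is insensitive to the convention, while individual
p-values are not.

Goodness of fit: `R² = 1 − SSE/SST` (SST mean-corrected),
`adj R² = 1 − (SSE/(n−p))/(SST/(n−1))`,
`PRESS = Σ(eᵢ/(1−hᵢᵢ))²`, `pred R² = 1 − PRESS/SST`. The hat-based
PRESS is validated in the tests against 20 explicit leave-one-out
refits. PRESS is undefined when any hᵢᵢ = 1; that run is named in the
error.

**Optimisation** enumerates the 18 grid points (the domain is
categorical, so this is exhaustive), keeps predictions ≥ a threshold
(default 90 %), and sorts by predicted coverage. With the cost
tie-break enabled, conditions within a band of the current group leader
are treated as operationally equivalent and reordered by lower ratio
(shorter coating time) then lower concentration (less polymer). The
band defaults to 7.5 percentage points: the two best conditions on the
packaged table (1 % Kollicoat Protect at 3:1 vs 2:1) differ by 6.75
predicted points yet deliver equivalent >90 % coverage at very
different processing cost, and the band is meant to capture exactly
that judgement. It is a parameter, not a constant.

## Powder metrics

HR = ρt/ρb and CI% = 100·(ρt − ρb)/ρt, linked by the identity
CI = 100·(1 − 1/HR). Replicate handling defaults to per-replicate
indices then mean ± sd (matching how bench replicates are reported);
a pooled mode computes one index from mean densities — published
summary tables are sometimes internally inconsistent between the two,
which is why both are exposed and ρt < ρb replicates are flagged, not
rejected. Flow classes follow a USP <1174>-style HR band table
(boundary value to the better class); the table is configurable.

Angle of repose from a binary pile silhouette: apex = highest occupied
row; base = the widest occupied row within the bottom 5 % of the pile
height (robust to baseline raggedness); angle = atan(height / base
half-width). The synthetic triangle generator recovers angles to well
within 1° including ±1 px edge jitter; real photographs need prior
binarisation, which is out of scope here.

Size moments from volume fractions vᵢ at diameters dᵢ:
D4,3 = Σvᵢdᵢ, D3,2 = 1/Σ(vᵢ/dᵢ), SSA = 6/(ρ·D3,2) (ρ in g/cm³, d in
µm → m²/g; the identity SSA·ρ·D3,2 = 6 is exact). Number-weighted
inputs are converted via vᵢ ∝ nᵢdᵢ³. These are the moments a
laser-diffraction export provides; optical inversion of scattering data
is not implemented.

Counting-chamber loading: a linear calibration (count vs µg/mL, ≥3
levels) is fitted by least squares and inverted; out-of-range
inversions warn. Load = C·V/(1000·m) in mg/g. Two load-yield
definitions exist in practice — the naive quotient measured/theoretical
and a process-yield-normalized variant crediting mass lost during
coating — and they disagree by a few points; both are provided and the
choice is the caller's.

## Dissolution and detachment

Cumulative release corrects for sampled aliquots. With medium
replacement (default, standard paddle practice) the released mass at
sample n is `Cₙ·V + Σᵢ<ₙ Cᵢ·Vₐ`; without replacement the in-vessel term
uses the shrinking volume `V − (n−1)·Vₐ`. The replacement-corrected
profile dominates the uncorrected one pointwise. Monotonicity repair
(running maximum) is available but explicit and flagged, never silent.

f2 = 50·log10(100·[1 + (1/n)Σ(Rₜ − Tₜ)²]^−½) over common time points,
rounded to two decimals (identical profiles give exactly 100.00; a
uniform 10-point offset gives 49.89). Regulatory conventions are
defaults, not hard rules: truncation after the first point at which
both profiles exceed 85 % release, a minimum of three common points,
and a similarity threshold of 50 with the boundary counted as similar.
All are parameters, because practice varies (a profile pair at f2 just
below 50 may still be judged similar in context).

Detachment profiles cumulate per-sample detached-particle counts
against the total load, capping at 100 % with a flag when counting
noise overshoots; one sample per two dips is the default schedule.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions for every estimator.

- **Pellet images**: non-overlapping discs (rejection sampling, 1000
  tries per disc, deterministic under the seed; geometric infeasibility
  is a named error) painted uncoated white (0.92, 0.92, 0.92) with a
  coated blue (0.15, 0.20, 0.75) angular sector per disc on a (0.03,
  0.03, 0.03) background — the palette mirrors methylene blue on white
  cellulose over black glass. The image-wide coated pixel count equals
  `round(fraction · pellet pixels)` exactly (per-disc quotas, residual
  assigned greedily), so the mask is a pixel-exact oracle. Per-channel
  Gaussian noise (default studies use sd 0.02, a plausible sensor/
  illumination jitter; the true magnitude is not known) is added last
  and clipped. Not emulated: pellet curvature shading, specular
  highlights, partial occlusion, colour bleed — so passing tests
  demonstrate correctness of the counting arithmetic and robustness to
  additive noise, not performance on real stereoscope photographs.
- **Design responses**: model evaluation at the run's coded levels plus
  N(0, σ²), clamped to [0, 100] after noise; σ = 3 percentage points in
  the recovery studies, commensurate with the replicate spread in the
  packaged table (runs 2/9 and 5/11 differ by ~2 points).
- **Release profiles**: burst + first-order,
  `f_burst + plateau·(1 − e^{−kt})`, noise added before the
  running-maximum repair (measurement error happens before cumulative
  reporting).
- **Size distributions**: log-normal volume weights on geometric bins
  (default ±4 geometric sd); fractions normalized to 1.
- **Pile silhouettes**: rasterised isoceles triangles with optional
  per-row half-width jitter; apex height = (base/2)·tan(angle).

All generators are bit-identical under a fixed seed.

## Numerical and scale choices

Fits use `numpy.linalg.lstsq`/QR; no regularisation. Coefficient
comparisons against the reference model use ±0.05 (two-decimal
printing), R² ±0.001, adjusted ±0.002, predicted ±0.003. The imaging
validation studies use 192×192 px images with 10 discs of radius 12 px
(~4.5k pellet pixels) and 20 images per arm; coefficient-recovery
studies use 200 replicate tables. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full suite
in seconds. Degenerate inputs (empty foreground, disconnected piles,
zero-slope calibrations, drained vessels, leverage-one runs) raise
errors naming the offending object rather than propagating NaNs.

## Known limitations

- The imaging thresholds are tuned for a dyed-blue film on white
  pellets over a dark field; other colourways need re-configuration.
- The differential estimator's attribution of excess histogram mass is
  one reasonable reading of histogram-comparison practice; it is biased
  upward when the reference is noise-free.
- The DoE module fits exactly the fixed 12-term model; it does not
  generate optimal designs (the run set is taken as given) nor test
  lack of fit against pure error (only two replicate pairs exist in the
  packaged table).
- Published summary statistics that depend on replicate-level raw data
  (per-replicate flow indices, wet-lab loads) can be checked for
  internal consistency but not recomputed; the package flags
  inconsistencies instead of matching them.
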