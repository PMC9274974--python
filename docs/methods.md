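# Methods

This note records the models, defaults, numerical choices and known
limitations behind each stage, in the order the pipeline runs them.

## Bio-heat model

The gland is an ellipsoid with full axes 5.5 × 2.2 × 2.2 mm (semi-axes
2.75/1.1/1.1 mm; the axis-length reading is configurable), wrapped in a
concentric fat shell of default thickness 0.5 mm (not reported for the
rat adrenal; configurable). Temperature obeys the Pennes equation per
tissue,

    ρ C ∂T/∂t = K ∇²T − ρ_b C_b ω_b (T − T_b) + P,

with adrenal (ρ = 1020 kg/m³, C = 3540 J/(kg·K), K = 0.52 W/(m·K)) and
fat (911, 2348, 0.21) parameters, blood ρ_b = 1000 kg/m³,
C_b = 4180 J/(kg·K), perfusion ω_b = 0.0064 s⁻¹, and T_b = T₀ = 37 °C.
Two deliberate sign/coefficient conventions: the perfusion term is a
heat **sink** for T > T_b (the standard Pennes form; a source term here
would be self-amplifying and unphysical), and the fat domain uses the
fat conductivity K_F (not the adrenal K). Perfusion acts in every
tissue. Voxels outside the fat shell but inside the simulation box are
modelled as the same perfused fat medium — anatomically the gland is
embedded in retroperitoneal fat — so the box boundary, not the shell
surface, carries the fixed-temperature condition.

Each 1 µl injection bolus is a uniform sphere of radius
(3V/4π)^{1/3} = 0.62 mm with volumetric power SLP × [Fe]
(600 W/g × 40 mg/ml = 2.4 × 10⁷ W/m³, total 24 mW per site); a Gaussian
profile of equal total power is available. Default placement is two
sites at ±1 mm on the long axis, mimicking the two-injection surgical
protocol. Overlapping spheres add; spheres truncated by the box are
renormalized to conserve power.

**Numerics.** Cell-centered isotropic grid; forward-time central-space
stepping with the stability bound dt ≤ h²/(6·max α) enforced before the
first step (default dt is 0.9 × the bound), Dirichlet T₀ on the outer
box (ghost cells at half-spacing), with an insulated (mirror) option and
an unconditionally stable backward-Euler option for coarse grids.
Temperatures are handled in °C; the PDE is offset-invariant so only the
perfusion reference T_b fixes the scale. The default acceptance-grade
resolution is 0.1 mm (≈ 2.3 × 10⁵ voxels, ≈ 5,800 steps for 60 s,
~20 s on one CPU); the orchestrated synthetic run uses 0.2 mm since it
only needs the design answer, not grid-converged fields.

**Verification.** Zero-source invariance is exact; an insulated uniform
source ramps at exactly q/(ρC); the grid-convergence check bounds the
peak shift under halved spacing at < 3 %. The single-sphere oracle
deserves a note: the often-quoted steady center rise qa²/2K (8.87 K for
these parameters) is *not* attainable at 60 s — the exact infinite-medium
transient, T_c(t) = (q/K)∫₀ᵃ r·erfc(r/√(4αt)) dr, from integrating the
point-source Green's function over the bolus, is itself 7.9 % below
steady at 60 s. The solver is therefore checked against that exact
transient (3.8 % at 0.2 mm, 2.7 % at 0.1 mm, improving under
refinement), with the steady value asserted as a strict upper bound.

The TRPV1 threshold report uses a ≥ 42 °C comparison (a voxel exactly at
threshold counts), linear interpolation between steps for probe
first-crossing times, and tissue-restricted volumes.

## SLP calorimetry

The initial-slope convention: OLS slope of the temperature trace over
the first 10 s after field-on, minus the OLS drift slope over the 10 s
before field-on; SLP = C_s m_s (dT/dt)/m_Fe in W per gram of iron.
Extrapolation between AMF conditions uses linear-response scaling
SLP ∝ f H², flagged as model-based in every output — the full dynamic
hysteresis treatment is out of scope, and the bench estimate
(880 ± 38 W/g at 515 kHz) is not itself reproducible because the
calorimeter's solution mass and heat capacity are not published. The
synthetic calorimetry model encodes a true SLP of 880 W/g, 1 g of
solution, 0.25 mg iron, 0.05 K measurement noise and a 10 Hz fiber-probe
logging rate; round-trip tests assert recovery (< 0.1 % noise-free,
mean error < 5 % noisy), not any published value.

## Heart rate

Traces are 1 Hz, 0–420 s (0–300 s pre-stimulation, 300–360 s
stimulation, 60 s post; only the stimulation window is fixed by the
protocol — the rest is configuration). Gaps are imputed by
fixed-interval smoothing under a local-level Gaussian state-space model
(random-walk level plus observation noise), the model behind "Kalman
smoothing with default parameters" in standard imputation packages. The
filter/smoother is implemented in-package with scalar recursions and
the likelihood concentrated over the signal-to-noise ratio
(bounded scalar minimization of the profile likelihood on
log q ∈ [−12, 8], diffuse initialization at the first observation);
it matches the statsmodels UnobservedComponents smoother to ~1e-10 and
runs in milliseconds, which the Monte-Carlo suites need. Traces with
more than 50 % missing or no observation in the first/last 10 s are
rejected, mirroring the study's "unable to impute" exclusions.

Scaling divides by the mean pre-stimulation rate; days 1–2 are averaged
pointwise; the AUC is the plain sum over 300–360 s with *inclusive*
endpoints (61 samples at 1 Hz — fixed so the convention is bit-stable);
conditions are compared with a gamma GLM, identity link, Pearson
dispersion, t-based Wald tests.

## Serum hormones

ELISA calibration uses the four-parameter logistic
y = d + (a−d)/(1+(x/c)^b) fitted per plate by least squares (the curve
family is the immunoassay standard; the study names only "a calibration
curve"), inverted analytically; optical densities outside the open
asymptote interval raise an error so samples are flagged, never clipped.

Baseline outlier screening maps pre-stimulation values into (0,1) by
dividing by 1.05 × max (the mapping is recorded in the output), fits a
beta by MLE and excludes two-sided tail probabilities below 5 × 10⁻⁴.
Two scoring methods exist because the rule has an inherent tension: the
**pooled** single fit (default, literal rule) keeps the false-exclusion
probability at its nominal ≈ 1 − 0.999ⁿ on clean data, but a genuinely
extreme baseline drags the MLE α below 1 — infinite density at zero —
and masks itself; **leave-one-out** scoring (each value's tail under the
beta fitted to the others) recovers such planted outliers reliably, at
the cost of flagging legitimate sample extremes more often at small n.
Both are tested; the pipeline default is pooled.

The treatment comparison averages each rat's two collection days before
forming the post/pre ratio, then t-tests the natural logs. The serum
test defaults to the pooled variant (df = n₁+n₂−2); the behavioral
endpoint test defaults to Welch — the study's reported degrees of
freedom are internally inconsistent across analyses, so the variant is
explicit in every output and configurable.

## Freezing behavior

Phases: habituation (5 trials), conditioning (7), extinction (20),
recall (3); freezing is the fraction of the 30 s tone spent immobile.
Per rat: per-phase min-max normalization; division by the baseline
(mean of *normalized* habituation trials 3–5); values above 1 (small
baselines are common) are clipped back to [0,1] with the clip count
reported; centered window-3 moving average with windows shrunk at phase
ends; boundary compression (y(n−1)+0.5)/n with n = 35 trials so exact
0/1 become admissible beta responses. A degenerate phase (max = min)
maps to a constant 0.5 and is flagged. Non-conditioners are excluded by
an explicit criterion replacing blinded visual inspection: mean raw
freezing over the last 3 conditioning trials must exceed mean
habituation freezing by ≥ 0.10 (≥ comparison; threshold configurable).

The cohort model is a beta regression (logit mean link, constant
precision, MLE from logit-scale least squares, observed-information
standard errors) on trial (numeric, restarting at 1 per phase), phase
(categorical, habituation reference), treatment, and all 2-/3-way
interactions — 16 columns. The endpoint analysis is a Welch t-test of
per-rat means over extinction trials 18–20.

**Known limitation — test size.** The normalization chain induces
strong within-rat dependence (each rat's min-max and baseline are
statistics of its own noisy trials; smoothing correlates neighbors),
and the beta regression treats all 840 observations as independent.
Under a null generator the treatment main-effect Wald test rejects at
≈ 35–37 % instead of 5 % (500-seed simulation; the acceptance suite
asserts the nominal level and fails honestly). Mixed models would
address this but are out of scope by design. Relatedly, min-max
rescaling largely removes encoded extinction-*rate* differences (a
faster exponential becomes a more convex curve spending more trials at
its floor, not a steeper line), so group differences in decay rate do
not map onto the sign of the trial × treatment coefficient — consistent
with the null behavioral findings such designs tend to produce.
Passing tests therefore demonstrate the chain and model are computed as
specified, not that the design is well-calibrated on real data.

## Histology

The tissue mask's largest connected component (holes filled) is
summarised by the ellipse with the same second central moments; pixels
get a normalized elliptical radius r (1 on the fitted boundary) and are
labeled medulla (r < 0.4), ZR (0.4–0.7), ZF (0.7–0.9), ZG (0.9–1)
from the inside out. The band fractions are not published; the defaults
are configurable and echoed in every report. Tissue pixels beyond the
fitted boundary (inevitable for a moment ellipse) are assigned to the
outermost zone so zones exactly partition the tissue. Coverage is
100 × particle pixels / zone pixels; empty zones report undefined (NaN),
not zero.

## Synthetic cohort

Defaults encode the study conditions: 14 rats per condition (28
completed animals); heart rate — baseline 360 ± 25 bpm, a logistic
stimulation-locked rise of 10 % of baseline in active rats
(pre-conditioning), blunted to 10 % of itself after conditioning,
per-rat response spread 5 % of baseline in both conditions (biological
heterogeneity; without it even a blunted response is trivially
significant), 5 bpm observation noise, 10 % dropout with protected edge
windows; hormones — log-normal baselines (CORT ~150 ng/ml scale,
epinephrine ~1.5), active post/pre multiplicative effect 0.7 vs control
1.0, log-sd 0.3, two collection days, ODs generated through latent 4PL
plate curves; freezing — beta observations (precision 30) around
saturating-exponential acquisition (rate 0.6/trial, asymptote 0.8) and
exponential extinction decay (0.15/trial, floor 0.15, treatment decay
modifier 1.0 by default, matching the null behavioral finding), 10 %
non-acquirers generated flat at habituation level so the exclusion rule
has unambiguous ground truth; histology — elliptical sections with
particle blobs placed by zone probabilities (medulla 0.35, ZR 0.40,
ZF 0.25, ZG 0 — the observed pattern), blob radii kept inside their
band. All draws come from one seeded generator; identical seeds give
byte-identical outputs, and every latent quantity is stored as ground
truth. What the generator does **not** emulate: circadian/hormonal
drift, plate effects and inter-assay variation, movement artifacts
beyond missingness, correlated freezing noise, or section-to-section
anatomical variation — so green tests certify the algorithms, not
robustness to those real-data features.

## Orchestration

Stages run thermal → calorimetry → histology → heart rate → hormones →
behavior; histology's particle-placement calls gate the active-rat
exclusions of the later stages (no medulla particles → heart rate and
epinephrine; no cortex → corticosterone; both empty → behavior). Every
exclusion carries a machine-readable reason and retained + excluded
always equals the stage input. Exclusion percentages are reported under
both denominators (of retained, and of all input animals) because the
published "21.7 % of total" matches the retained-count denominator
(5/23), not the all-animals one (5/28). Reports are
timestamp-free, so a fixed seed reproduces byte-identical output.
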