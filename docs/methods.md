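# Methods

## The marker model

For a nutrient fraction with true total-tract digestibility D (%) and an
internal marker recovered at fraction R of its intake, mass balance gives the
faecal concentrations that the concentration-ratio estimators see. The two
estimating equations (whole DM and per-nutrient, see README) then satisfy

    D̂ = 100 · (1 − (1 − D/100) / R)

exactly on any mass-balance-consistent sample. D̂ is monotone increasing in
R, equals D iff R = 1, and underestimates D for R < 1. This identity is the
package's core oracle: the simulator constructs samples on which it holds to
machine precision, and the estimators are tested against it and against
brute-force recomputation from raw intake/excretion masses.

## The synthetic trial

The generator emulates a total-collection digestibility trial in dairy small
ruminants: 8 sheep + 4 goats, three forage:concentrate phases (40:60, 50:50,
60:40 alfalfa hay : concentrate), five collection days per phase — 180
animal-days by default.

**Ingredient profiles.** The forage and concentrate compositions (% DM) are
back-solved linearly from the trial's calculated diet chemistry at the two
extreme ratios (F = 3·d₆₀:₄₀ − 2·d₄₀:₆₀ per fraction), so all three blends
reproduce the diet table by construction. Two values the trial does not
print are set here: diet uNDF = uNDFom × 1.06 (≈ 6 % residual ash in the
240-h fermentation residue) and AIA of 1.2 / 0.6 % DM for forage /
concentrate (forage carries most soil-derived silica). The by-difference
identities (soluble CP = CP − NDICP, hemicellulose = NDF − ADF,
cellulose = ADF − ADL, pdNDF = NDF − uNDF) are enforced exactly; where a
printed table disagrees with its own by-difference arithmetic, the identity
wins.

**Per-sample draws.** Each animal-day draws: DM intake ~ Normal(2.0, 0.3) kg
truncated positive; a forage-fraction jitter (sd 0.01) on the phase ratio; a
shared "animal effect" scalar (sd 2.0 %-points) added to all digestibility
draws to induce cross-trait correlation; independent truncated-normal
digestibilities for the directly measured fractions (DM 71.6, CP 68.8,
soluble fractions via identities, ash 33.1, NDF 50.4, ADF 48.3, NDICP 52.2,
ADICP 84.5 %, trait sd 3.0 by default — the trial prints only means and a
pooled SEM, so the sds are a package choice); and marker recoveries ~
Normal(0.795 ± 0.165, 0.749 ± 0.149, 0.725 ± 0.279 for uNDF, uNDFom, AIA)
truncated to (0.30, 1.20). The upper truncation admits > 100 % recovery
noise, which AIA's printed sd implies; the lower bound keeps the estimator
finite. A trait whose sd is set to 0 is held exactly at its mean (the animal
effect is not added), which is what "fixing" a digestibility means in the
exact-identity checks.

**Mass balance.** Faecal DM = DMI · (1 − DMD/100); each drawn fraction's
faecal mass = intake mass · (1 − D/100); each marker's faecal mass = intake
mass · R. By-difference fractions are derived from the faecal identities and
their *implied* digestibility is stored, so intake − excretion matches the
stored digestibility to 1e−9 for all eleven traits. Draws are rejected and
redrawn when any faecal concentration exceeds 100 % DM, the top-level
component sum (ash + CP + EE + aNDFom + starch − NDICP, the overlap counted
once) exceeds 100, or a derived non-marker fraction goes negative; a budget
of 100 redraws then fails loudly naming the offending fraction. At the
60:40 phase the component sum sits near 97 % of faecal DM, so the
feasibility rule truncates the joint distribution noticeably there — a
consequence of combining the printed diet chemistry with the printed
digestibility means, documented rather than hidden.

Faecal pdNDF (= NDF − uNDF) is allowed to go negative: marker measurement
noise can place faecal uNDF above faecal NDF, exactly as independent wet
chemistry assays can. Such samples produce out-of-range pdNDF
digestibilities that the estimators exclude (below). Because recovery noise
enters pdNDF twice, the generator's pdNDF dispersion is wider than a real
trial's, where uNDF and NDF measurement errors are correlated — passing
tests therefore say less about pdNDF statistics on real data than for the
other traits.

**Exclusion rule.** Estimates outside [0, 100], or with non-positive marker
or diet concentrations, are flagged with a machine-readable reason and
excluded from descriptive statistics — reproducing the trait-specific n of
marker-based reporting. Total collection rows use the same rule, so TC and
marker tables are directly comparable.

## The spectra generator

Per sample: a(λ) = gain · Σⱼ wⱼ cⱼ Kⱼ(λ) + tilt·(λ − λ̄) + offset + ε(λ),
where cⱼ are faecal concentrations (% DM) of eight constituents, Kⱼ are
seed-fixed sums of 6 Gaussian bands (widths 30–150 nm) shared across
samples, gain = exp(N(0, 0.02)), tilt ~ N(0, 2·10⁻⁵ abs/nm), offset ~
N(0, 0.02) and ε is white noise (sd 0.002 abs). The default grid is
1100–2498 nm at 2 nm (700 points); the instrument-resolution grid
(400–2500 at 0.5 nm) is available by config.

The generator's contract is that its exported *signal fraction* is truthful:
`make_synthetic_trait(..., theoretical_r2=r)` returns y = t + noise with
var(t)/var(y) = r, where t = Σ wⱼ cⱼ is the scalar signal each spectrum
carries, and an oracle linear fit on the generator's own low-dimensional
basis recovers r to ±0.05 at n ≈ 500. The multiplicative-scatter sd (0.02)
is chosen so this contract holds: the gain perturbation must stay small
against the latent signal's coefficient of variation (≈ 0.12), because no
scatter correction can restore the absolute intensity a large random gain
destroys. What the generator does **not** emulate: nonlinear
particle-size/moisture effects, wavelength-dependent scattering, band shifts
— so passing calibration tests demonstrate correctness of the chemometric
machinery, not NIRS feasibility on real faeces.

## Chemometrics

**mPLS.** NIPALS PLS1 on column-centred X and centred y, with the
Shenk–Westerhaus modification: after each extracted factor, the X-residual
columns and the y-residuals are divided by their standard deviations before
the next factor. All per-factor scale vectors are stored, so prediction
reproduces training fitted values exactly; zero-sd residual columns clamp
their scale to 1. With no scaling the algorithm is plain PLS1, which at
saturating factor count equals OLS (tested to 1e−8) and is available via
config. SEC uses n − k − 1 degrees of freedom.

**Protocol** (`calibrate_trait`), in order: (1) Global-H spectral culling on
the untreated spectra — GH = squared Mahalanobis distance in the score space
of a 10-factor principal decomposition, divided by the factor count;
GH > 3.0 is removed; (2) mean/SD-matched 75/25 split chosen as the best of
100 seeded random splits (the split precedes all treatment so validation
samples never influence centring, MSC references, culling, factor choice or
pretreatment choice); (3) per grid cell (5 scatter modes × 5 derivative
codes): up to 3 T-statistic culling iterations (T = |y − ŷ|/SEC > 3) on the
calibration set, then 5-fold cross-validation choosing the factor count that
minimises RMSECV (ties toward fewer factors, max 10); (4) the cell with the
highest cross-validated R² wins; (5) external statistics on the untouched
validation set.

**Conventions** (each configurable, stated because the field uses several):
scatter correction is applied before the derivative; detrend is the classic
degree-2 polynomial; the gap derivative uses forward differences with
valid-region trimming (no edge padding) and centred moving-average smoothing
(even widths weighted one point to the right); SE_ExV is bias-corrected
(SEP(C), n − 1); SE_CrV is the uncorrected RMSE of CV predictions (n − 1);
the slope is reference-on-predicted; RPD divides the *validation-set*
reference sd by SE_ExV (the whole-set pool is available by config);
R² bands are < 0.66 inadequate, < 0.82 approximate, ≤ 0.90 good, above
excellent; RPD bands are < 1.0 very poor, < 1.4 poor, < 1.8 fair, < 2.0
good, ≤ 2.5 very good, above excellent.

## Method comparison

Per trait, the four methods (TC, uNDF, uNDFom, AIA) are compared with
Kruskal–Wallis, then Dunn's pairwise z on pooled midranks with tie
correction, Bonferroni-adjusted over the 6 pairs (Holm by config), letters
at α = 0.05 by insert-and-absorb. The pooled SEM is
sqrt(pooled within-group variance / harmonic-mean n). Samples are treated as
independent observations; no repeated-measures correction per animal is
applied, which mirrors the flat trial design and is a known caveat. Note
that Dunn's test on fully separated groups of n = 10 cannot reject adjacent
pairs after Bonferroni (z ≈ 1.9): full letter separation needs roughly
n ≥ 30 per group.

## Reproducibility

Everything is driven by integer seeds through `numpy` seed sequences; the
CLI fans a master seed out to per-stage children, records them in a
manifest together with a config snapshot and SHA-256 checksums of all
outputs, and identical seeds reproduce identical files. Problem sizes used
in the shipped checks — 180-sample default cohorts, ~500-sample cohorts for
distributional properties, ~2000 for recovery re-estimation, 700-point
spectra — keep the whole suite and the acceptance script within a few
minutes on one CPU while leaving sampling error well inside the asserted
tolerances.

## Known limitations

* The generator draws digestibilities independently across (non-derived)
  traits apart from one shared animal-effect scalar; real cross-trait
  covariance structure is richer.
* Recovery noise is independent of everything else; in real assays uNDF
  measurement error correlates between diet and faeces and with NDF itself.
* The spectra are a linear latent mixture; conclusions about real faecal
  NIRS accuracy cannot be drawn from them.
* The WinISI software whose protocol this package mirrors has proprietary
  smoothing and scaling kernels; the definitions above are this package's
  contracts, not claims about WinISI internals.
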