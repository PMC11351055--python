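# Methods

## Model

The package implements target-phase narcosis models. For an inert
(baseline, nonpolar narcotic) chemical, acute toxicity to fish is assumed
to be driven entirely by equilibrium partitioning into a reference phase.
With K = C_phase/C_water (L/kg) and the observation that the phase-bound
concentration at death — the critical burden C^crit (mol/kg) — is roughly
constant across chemicals of the same mode of action, toxicity obeys

    −log LC50 = −log C^crit + m · log K_phase–water,

with m = 1 in the idealized derivation. The reference phase may be a
membrane lipid (the classical target lipid model) or, because amorphous
polymers take up the freely dissolved fraction the way biomembranes do, a
polymer such as PDMS, PA, POM, LDPE or PU (the target plastic model).
Units are fixed package-wide: LC50 in mol/L, phase concentrations in
mol/kg, K in L/kg, all logarithms base 10. Toxicity is stored as
log LC50; the sign flip to −log LC50 happens only inside `burden_model`.

Assumptions inherited from the framework: equilibrium partitioning
(absorption, not surface adsorption), neutral persistent chemicals, no
metabolism or ionization, acute lethality via narcosis only. Reactive
chemicals violate the last assumption by design; the package represents
them so that their failure mode (systematic underprediction of toxicity
by partition-only models) is visible in fit statistics.

## Partitioning (pp-LFER engine)

log K is evaluated as c + e·E + s·S + a·A + b·B + v·V (+ l·L). System
coefficients live in a user-editable registry (TSV/JSON); the package
ships no literature values, only a template, because coefficient sets are
licensed/curated data the user must take from primary sources. Registries
may contain water–air rows; the loader normalizes them to air–water by
negating all coefficients and noting the inversion in the provenance
field. Phases calibrated only against air (PU in practice) reach the
water side through the thermodynamic cycle
log K_phase–water = log K_phase–air + log K_air–water, with K_air–water
oriented as C_air/C_water; cycle-derived columns are flagged in the
partition table's metadata sidecar. A record lacking the gas-phase L
descriptor fails loudly on any l-bearing system rather than being
imputed; table construction collects and reports *all* failing
(chemical, phase) cells before aborting. Both the L-based and the
V-based descriptor sets are supported; the registry decides which a
system uses.

## Burden calibration

Three methods, selectable per (phase, group):

- **fixed_100mmol** — −log C^crit = 1 exactly (100 mmol/kg), the
  literature lipid value; slope 1 by definition.
- **median** — −log C^crit = −median_i(log K_i + log LC50_i); slope 1.
  Even-n medians use the midpoint convention.
- **intercept** — unweighted OLS of y = −log LC50 on x = log K
  (statsmodels); the intercept is −log C^crit, the slope m measures the
  phase's partitioning sensitivity. Standard errors are the usual OLS
  ones; RMSE is √(SSR/n) (no degrees-of-freedom correction, matching how
  prediction RMSEs are reported); R² is the ordinary coefficient of
  determination. No errors-in-variables correction is applied.

Non-finite log K or missing LC50 entries abort calibration by default;
an explicit `drop_nonfinite=True` drops them and records the count.

Prediction inverts the model: log LC50 = −(−log C^crit + m·log K), with
`slope_mode="unity"` (m = 1, the model as derived) or `"fitted"` (the OLS
slope). The default is unity for fixed/median estimates and fitted for
intercept estimates; the choice is surfaced as a flag because either
convention is defensible and they differ measurably for phases whose
fitted slope is far from 1. Prediction reports carry RMSE, mean residual
(bias), R², and within-factor-N fractions for N ∈ {2, 3, 5} with the
inclusive convention |residual| ≤ log10 N.

The per-chemical burden distribution (the plastic sensitivity
distribution, by analogy to species sensitivity distributions) is
summarized by min/quartiles/median/mean/max in log units.

## Phase similarity

PCA is run on standardized (mean 0, sample sd 1) system coefficients with
phases as observations, via SVD. Components are ordered by decreasing
explained variance; signs follow a deterministic convention (the
largest-magnitude loading of each component is positive) so scores,
biplots and distances are reproducible. cos2 — the share of a phase's
squared distance to the origin captured by each component — quantifies
representation quality; rows sum to 1. Euclidean distances between
phases default to the first two components, the plane of the usual
biplot. The constant term c is included as a column by default (flag to
exclude), since nothing in the coefficient table marks it as special.
Pairwise Pearson correlations among per-chemical log K columns and
−log LC50 require ≥3 chemicals and no constant column.

## Mixture risk

TU_water = C_w/LC50 and TU_plastic = C_plastic/C^crit coincide exactly at
partition equilibrium; the package computes either. TU sums are
arithmetic; summing across modes of action emits a warning (additivity is
established for same-mode, baseline mixtures) but does not block. The
risk quotient is RQ = AF · ΣTU — equivalent to C/PNEC with
PNEC = acute/AF — controlled by a single module constant, with presets
AF = 1000 (freshwater) and 10 000 (marine). The multiplicative
orientation is a documented convention, not a silent guess.

## Synthetic data

The generator emulates the study conditions the model assumes, so the
whole pipeline is testable without external downloads:

- group sizes 115 (baseline), 73 (less-inert), 75 (reactive);
- residual scatter 0.32 log units around the burden line (the
  phospholipid-level fit quality for baseline narcotics);
- hydrophobicity log K uniform over (1, 7) — six orders of magnitude;
- true burdens −log C^crit = 0.96 (≈110 mmol/kg) for baseline and 1.33
  (≈47 mmol/kg) for less-inert chemicals, slope 1;
- reactive chemicals: the baseline burden plus a nonnegative
  excess-toxicity offset drawn from N(2.0, 0.7) clipped at 0 — roughly
  two orders of magnitude of extra toxicity — so partition-only fits
  degrade exactly as they should for covalently acting chemicals.

Descriptors are sampled and log K is then computed *through the LFER
engine* (the McGowan volume is solved from the target log K, with
resampling when the implied volume is unphysical), so generated sets
exercise the same code path as real data. One root seed drives
everything; sub-generators derive child seeds via `numpy` SeedSequence
spawning. Mixtures sample each component's bound concentration as a
fraction of its own critical burden, making the true ΣTU the sum of the
fractions by construction.

What the generator does **not** emulate: real descriptor covariance
within chemical families, heteroscedastic experimental LC50 error,
inter-species variability, and curvature at the hydrophilic end of the
hydrophobicity range. Passing recovery tests therefore demonstrate the
estimators are correct under the model's own assumptions, not that the
model holds for any particular real polymer or species.

## Numerical choices

- OLS via statsmodels; verified in tests against an independent
  brute-force grid-refinement least-squares search (agreement ≤ 1e−6).
- PCA via `numpy.linalg.svd`; cross-checked against scikit-learn's PCA
  in tests. Reconstruction error of the standardized matrix ≤ 1e−8.
- CSV round trips write floats with `repr`, so load→write→load is the
  identity bit-for-bit.
- Degenerate inputs fail with named errors: constant columns
  (standardization, correlation), n < 3 (intercept method, correlation),
  empty sets, duplicate ids/systems.
- Monte-Carlo sizes: 200 replicate seeds at n = 115 for parameter
  recovery — large enough that the ±2·SE coverage estimate has a
  standard error of ~1.7 percentage points.

## Reference data

The published narcosis-regression table (11 phases × 3 groups:
intercept ± SE, slope ± SE, RMSE, R², n) ships as package data. Two
transcription notes: one standard-error cell is printed with a corrupted
decimal (read as 0.150), and the reactive-group PU row prints identically
to the less-inert PU row; both are transcribed as printed. Derived
arithmetic on the intercepts (e.g. the factor ≈3.6 by which a
storage-lipid calibration overestimates the phospholipid critical burden,
10^(1.627−1.071)) is computed, never hard-coded.

## Known limitations

Weathering, biofouling and sorption kinetics are out of scope, as are
ionizable or metabolically labile chemicals, receptor-mediated chronic
toxicity, and HC5/species-sensitivity extensions. The CLI's `predict`
requires experimental LC50 values to score against; prediction-only
output for unscored chemicals is available through the library API.
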