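# Methods

## The circuit model behind the synthetic data

The generator (`stripenet.simulate`) models the three-node network as an
algebraic steady state built from Hill terms. Writing S, R, O for the
sensor, regulator and output expression levels (arbitrary units) and *a*
for the arabinose concentration (% w/v):

    S(a) = β_S · [b_S + (1−b_S) · aⁿ/(K_aⁿ + aⁿ)]
    R(S) = β_R · [b_R + (1−b_R) · K_SRⁿ/(K_SRⁿ + Sⁿ)]
    O(S,R) = β_O · [b_O + (1−b_O) · K_SOⁿ/(K_SOⁿ + Sⁿ) · K_ROⁿ/(K_ROⁿ + Rⁿ)]

with per-node maximal promoter rates β, basal fractions b, and repression
(or activation) constants K with Hill coefficients n. The incoherent
feedforward logic — K_SR ≪ K_SO, so rising sensor first silences the
regulator (freeing the output) and only later silences the output directly
— produces the stripe. The defaults (β_S = 100, b_S = 0.01, K_a = 0.005%,
n_a = 1; β_R = 50, b_R = 0.02, K_SR = 2, n = 2; β_O = 1000, b_O = 0.01,
K_SO = 30, K_RO = 5, n = 2) give wild-type output 25.1 / 270.3 / 92.1 a.u.
at 0 / 0.0002 / 0.2% arabinose — a stripe with the medium level strictly
brightest, which is the package's working definition of the stripe
phenotype at three levels. These values were fixed once when the model was
built and every downstream default derives from them.

Mutations are cis-regulatory: a mutant allele multiplies its own node's β
(promoter) and the K of each repression (for the sensor, the inducer
constant K_a) acting at that node's cis-region (operator), and nothing
else. Alleles are drawn log-uniformly from bounded ranges (β multiplier
0.4–2.5, operator multipliers 1/3–3) and rejected unless the resulting
single mutant still forms a stripe, mirroring how the assayed mutants were
selected for phenotypic neutrality. Allele indices are opaque labels.

Replicate noise is multiplicative log-normal with mean 1 and configurable
CV (default 0.10). No replicate noise magnitude is published for this
assay; 10% is a typical plate-reader replicate CV and the value is a
package default, not a measured quantity. Three generation modes exist:
`mechanistic` (combinations evaluated through the circuit, so epistasis
emerges from the Hill nonlinearities), `multiplicative_null` (combinations
constructed as exact products of their singles' fold changes — the null
hypothesis realized without error) and `multiplicative_plus_interactions`
(the null with chosen combinations scaled by 10^δ at chosen levels, so a
known epistasis coefficient can be injected and recovered).

The raw-plate emulator adds the assay's measurement structure: logistic
OD600 growth (capacity ≈ 0.55 above a 0.04 blank), GFP proportional to
biomass times a shared rise-peak-decay time profile, media blanks, three
WT control wells per plate and condition, a metabolic-load control
condition (carried through QC only), and small additive instrument noise.

What the generator does **not** emulate: intrinsic (single-cell) expression
noise, growth–expression coupling beyond a scale factor, plate-position
effects, instrument drift, or ODE transients. Passing tests therefore
demonstrate the correctness of the analysis pipeline and its calibration
under clean multiplicative or Hill-model data — not that real measurements
satisfy the multiplicative model.

## Plate processing

All wells are read at the time the wild type peaks at the medium level
(argmax of the pooled WT series; ties break to the earliest time, a series
still rising at the end is flagged). Correction is
(GFP − mean blank GFP)/(OD − mean blank OD); subtracting the blank OD is a
package choice and can be disabled, since the published protocol does not
specify the OD handling. Wells with non-positive corrected OD are marked
unusable. Plates are scaled so WT wells average exactly 1 per plate and
condition; the protocol's second cross-plate WT scaling is applied and is
idempotent after the first. A replicate is excluded when its OD deviates
from the plate's WT mean by more than 0.2 in any condition; genotypes left
with fewer than two replicates are flagged needs-repeat but keep their
surviving replicate. Summary statistics use the sample SD (n−1): replicates
are a sample, not a population.

## Epistasis statistics

Log fold changes are computed per replicate against the level-matched WT
mean and then averaged; the WT row is the reference and carries G = 0 by
definition. Non-positive fluorescence is excluded before logs (with a
logged reason) rather than floored, to avoid silent bias.

Error propagation offers two modes. The default `as_printed` follows the
study's formulas literally: σ_exp = |x̄|·√(Σσᵢ²) with x̄ the expected value
itself, and σ_eps = |ε|·√(σ_obs² + σ_exp²). These are dimensionally unusual
(the error vanishes as the propagated quantity approaches zero), so a
conventional `sum_of_variances` mode (√ of the summed variances) is also
provided; which one is statistically preferable is left to the user, and
the default preserves fidelity to the published procedure.

Significance of eps uses a pooled two-sample t test of observed vs expected
G from summary statistics (n = 3 each, df = 4), two-sided. Mean differences
at or below 1e-12 are treated as exact nulls (t = 0, p = 1): this absorbs
the ~1e-16 float residue of noiseless null data, where tiny-over-tiny
ratios would otherwise fabricate certainty. Zero variance with a real
difference yields p = 0 with a warning.

FDR control: Storey q-values (default for eps calls, threshold 0.05) with
π₀ estimated on the λ grid 0.05…0.95 (step 0.05) and smoothed by a cubic
least-squares fit evaluated at λ = 0.95, clamped to (0, 1] — a
deterministic stand-in for the reference smoothing-spline smoother, which
it matches in the π₀ = 1 limit where the q-values reduce to
Benjamini–Hochberg. BH and the two-stage Benjamini–Krieger–Yekutieli
step-up (used for inducer dependence, threshold 0.1) come from statsmodels.
Pairwise and triplet records form separate FDR families by default (the
published analysis does not state whether families are pooled; pooling is
available via an option).

## Classification rules

A constituent single is *crossed* when the combined expression falls on the
WT-ward side of that single's level (for Gᵢ > 0: combined < Gᵢ; mirrored
for Gᵢ < 0). Crossing none of the singles is magnitude epistasis, some but
not all is sign epistasis, all is reciprocal sign epistasis; the
positive/negative label is the sign of eps, and eps = 0 exactly yields a
"none" class. The same per-single rule extends the published pairwise
definitions to triplets and to mixed-direction singles (flagged via the
direction group: all_lower / all_higher / mixed).

Categories A–D come from the position of the medium-level eps: A if
strictly maximal, D if strictly minimal, otherwise B (eps_low < eps_high)
or C. Exact ties break toward the medium-extremum categories A/D and raise
a `tie` flag — measured values are almost surely distinct, so the flag
preserves auditability on synthetic exact inputs. Trajectories use point
estimates regardless of significance. Dependence calls are made for all
combinations and carried alongside the categories.

## Phenotype projection

G in the (Mx, My) projection is absolute log10 normalized fluorescence, not
fold change vs WT: only then do the wild type and its stripe-preserving
singles land in the stripe quadrant. Distances to the WT point are
invariant to that choice (per-level constants cancel in the differences),
which the tests assert. Boundary points (an axis exactly 0) follow a
half-open convention (strict positive tests) and are flagged; the flat
radius defaults to 0 (strict quadrants) because no near-origin threshold is
published. The diversity comparison reports each source's distance to the
WT point and a paired two-sided Wilcoxon signed-rank test; the literal
observed-expected displacement ‖M_obs − M_exp‖ is also emitted as a
supplementary column.

## Problem sizes and determinism

The default study scale is M = 10 mutants per node (1 + 30 + 300 + 1000
genotypes; 900 pairwise and 3000 triplet tests), which the full pipeline
processes in seconds. Calibration checks in the tests use the full M = 10
panel; injected-effect recovery uses M = 2 panels over 50 seeds, which
gives the same per-estimate sampling distribution at a fraction of the
cost. All randomness flows through one seeded generator per run; rerunning
any command with the same seed reproduces every output byte for byte.

## Known limitations

- The circuit equations are a modeling choice; the published work gives no
  functional forms, so mechanistic-mode epistasis magnitudes are
  illustrative, not calibrated to the real network.
- The as-printed error propagation makes significance anticonservative or
  conservative depending on |x̄|; both modes are exposed but no attempt is
  made to decide the ambiguity.
- Because every fold change at a level shares the same WT reference, tests
  across combinations are weakly correlated; the FDR calibration check
  accounts for this only through its binomial tolerance.
- The metabolic-load condition is carried as a pass-through QC column; no
  decision rule is applied because none is published.
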