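# Methods

## Elemental and electron bookkeeping

Formulas are real-valued per element so the per-C-mol biomass composition
CH₁.₈O₀.₅N₀.₂ (24.63 g/C-mol ash-free; ash is not modelled) is handled like
any other species. The degree of reduction γ uses the Roels convention —
reference species CO₂, H₂O, NH₃, hence γ = 4C + H − 2O − 3N (+5P + 6S):
galacturonate 20, glucose 24, lactate 12, acetate 8, biomass 4.2 per C-mol.
The nitrogen reference matters only for the biomass term; had the authors
of a given dataset used a different N reference (biomass γ between 4.2 and
5.0 per C-mol), electron recoveries would shift by well under 2 % at the
biomass fractions typical of anaerobic chemostats. Atomic masses are
CODATA standard values; organic acids are represented as neutral,
fully protonated species because molar yields are protonation-invariant.

## Reaction networks

Each pathway variant is a list of enzyme reactions with signed rational
stoichiometry. Cofactor pairs (ATP/ADP, NAD⁺/NADH, NADP⁺/NADPH) are signed
*deltas* per reaction rather than species, so steady-state solutions need
no regeneration pseudo-reactions. Acetyl-CoA is the exception: it carries
carbon between pyruvate dehydrogenase and phosphotransacetylase and must
couple their fluxes, so it is an internal species whose formula is the
acetyl moiety (C₂H₂O; γ = 8, matching acetate) with the CoA handle
implicit. H₂O, H⁺ and inorganic phosphate are closure species, solved per
reaction and excluded from steady-state constraints; after adding the
elemental content of the cofactor deltas (2 H and 2 e⁻ per NAD(P)H, one
HPO₃ group per ATP), the binding balance checks are carbon, nitrogen,
sulfur and γ, each at an absolute tolerance of 10⁻⁶. Every shipped
reaction passes; a deliberately corrupted decarboxylation (CO₂ dropped)
shows a carbon residual of 1.

Direction conventions: kinases, the aldolase, dehydrogenases, the
phosphoketolase, acetate kinase and lactate dehydrogenase are irreversible
in the drawn (fermentative) direction; isomerases, epimerases, the mutase
and enolase are reversible. The ribulose-5-P → xylulose-5-P step is encoded
as a 3-epimerase because that is the interconversion the phosphoketolase
requires, although the annotated candidate gene (*araD*) carries the
EC number of an L-ribulose-5-P 4-epimerase; which epimerase physiologically
feeds the phosphoketolase is an open biological question that does not
affect any balance. The tagaturonate 3-epimerase is labelled UxuE with
*uxaE* accepted as an alias in evidence keys.

Fructuronate reductase's cofactor is a build option (`uxub_cofactor`):
NADH for the canonical variants (the textbook cofactor) and NADPH for the
hybrid, where it matches the NADP⁺-linked 6-phosphogluconate dehydrogenase
and closes both nicotinamide pools individually. Toggling it never changes
carbon stoichiometry, only the NADH/NADPH split.

## Net conversions and feasibility

The unit-uptake steady state (S·v = 0 on internal species, substrate
uptake = 1, irreversible fluxes ≥ 0) is solved exactly over the rationals
(sympy nullspace). If no nullspace vector carries substrate the pathway is
reported disconnected; if the solution set retains a free direction the
error names the free reactions rather than resolving the branch silently —
the canonical + PDH variant is deliberately underdetermined at the
pyruvate node until target yields pin it. Headline identities obtained
this way: canonical route to 2 pyruvate nets exactly +1 ATP and 0 NAD(P)H;
its upper half to pyruvate + GAP requires 1 ATP and 1 NAD(P)H; the hybrid
route nets 1 lactate + 1 acetate + 1 CO₂ with +2 ATP and 0 NAD(P)H, and
its upper half is redox-neutral to ribulose-5-P + CO₂.

Product-profile questions are linear feasibility problems solved with
`scipy.optimize.linprog` (HiGHS): steady state, unit uptake,
irreversibility, each target yield within a tolerance (default 0.05
mol/mol — the operational meaning of "near-equimolar", which has no
standard numeric definition), optionally net NAD(P)H = 0. Targets naming
registered compounds the variant cannot touch are treated as achievable
only at yield 0 and marked unreachable in the infeasibility certificate.

## Chemostat reconciliation

Yields are `q_i/|q_s|`, reported at 2 decimals by default (the precision
of conventional chemostat tables); recoveries at 3 decimals. The biomass
term uses the steady-state identity μ = D: `q_x = D/24.63 × 10³`
mC-mol g⁻¹ h⁻¹; an explicit measured biomass rate overrides it. The
biomass yield is recomputed as `D/(|q_s|·M_s)` with the free-acid molar
mass (194.14 g/mol); for the packaged rate table this gives 0.097 g/g,
slightly above the conventionally rounded 0.09 — the package reports the
computed value. Batch growth rates are the least-squares slope of ln(OD)
against time over a *user-chosen* window; automatic exponential-phase
detection is deliberately not attempted. No measurement-error-weighted
data reconciliation or gross-error detection is performed.

## Proteome evidence

Detection is binary: the input table is already peptide-filtered upstream,
so spectral-count thresholds are not re-applied. A reaction is covered if
any mapped paralog is detected. Completeness = detected/(detected +
not-detected). The two novel activities (mannonate kinase,
6-phosphomannonate 2-epimerase) map to candidate proteins only
(gluconate-kinase homologs; an aldose-1-epimerase homolog); they are
reported in a separate candidate tier and never counted in the fraction,
since their gene identity is unresolved. Percentile ranks use the
strictly-below convention with mean tie-handling, which is invariant under
monotone transformations of the counts.

## Enzyme kinetics

Rate laws: MM `v = V·S/(K_M+S)`; substrate inhibition
`v = V·S/(K_M+S+S²/K_i)` with its single interior maximum at
S* = √(K_M·K_i). Fits are direct nonlinear least squares on the
untransformed equation (never Lineweaver–Burk, whose error structure is
biased), with positivity bounds and starting values V = max observed rate,
K_M = S nearest half of it, K_i = 10 × max S. A 2-parameter fit needs ≥ 4
points, a 3-parameter fit ≥ 5. Fitting plain MM to inhibited data sets a
model-mismatch flag when the upper-concentration residuals sit
systematically below the curve (beyond a machine-precision floor).
Datasets from assays without demonstrated coupling-enzyme excess carry an
`apparent` tag that survives into the fitted parameters.

## Synthetic data generators

All generators are pure functions of a seeded config
(`numpy.random.default_rng`, a version-stable generator; seeds are written
into every output file header). Defaults are the study-scale conditions:
D = 0.13 h⁻¹, biomass yield 0.09 g/g, rate CV 2 % (multiplicative Gaussian,
matching percent-level replicate mean deviations), μ_max = 0.20 h⁻¹ on
3.3 g/L substrate with K_S = 0.2 mM, and MM truth V_max = 0.24
μmol mg⁻¹ min⁻¹ with K_M = 10 mM plus additive Gaussian noise of
σ = 0.012 (5 % of V_max).

**Chemostat.** Substrate uptake follows from D and the true biomass yield.
The uptake is split into an electron-balanced catabolic fraction (routed
through the variant's redox-neutral net conversion) and assimilation.
Because biomass (γ 4.2/C-mol) is more reduced than galacturonate
(γ 20/6 ≈ 3.33/C-mol), electron-balanced assimilation necessarily releases
part of the assimilated carbon as CO₂. Noise-free tables therefore close
*both* the carbon and the electron balance to machine precision, keep
lactate and acetate exactly equimolar, and show a CO₂ yield above the acid
yields — the same qualitative pattern as measured chemostat data. Variants
whose net conversion is not redox-neutral are rejected, as is a biomass
yield whose carbon demand exceeds the uptake.

**Batch.** Monod kinetics dX/dt = μ(S)X, dS/dt = −μX/Y integrated with
RK45 at rtol 10⁻¹⁰ and a terminal substrate-depletion event; product
concentrations follow consumed substrate through the same yield split, so
carbon is conserved at every output time. Noise is multiplicative
log-normal (CV 5 %) on all series.

**Proteome.** Background proteins draw log-normal counts (median 20,
σ_ln = 1, n = 400); expressed pathway proteins draw from above the 75th
percentile of the realized background, so their percentile ranks always
exceed 75. The `canonical-lower-absent` scenario omits rows for the lower
canonical reactions; `all-present` covers every mapped reaction.

**Kinetics.** The substrate grid is a 12-point geometric series from 3 to
150 mM (≈0.3–15 × the default K_M), a standard saturation-curve design:
concentrations far below K_M produce rates under the additive noise floor
and carry almost no information about either parameter.

What the generators do *not* emulate: correlated measurement errors,
drifts or systematic HPLC/off-gas biases, unequal acid yields (real data
show acetate > lactate), maintenance energy, product inhibition, or any
population heterogeneity. Passing recovery tests on synthetic data
therefore demonstrates estimator correctness under the assumed noise
structure, not robustness to structural misspecification of real
measurements.

## Numerical choices and problem sizes

Per-element balance tolerance 10⁻⁶ (absolute); LP feasibility via HiGHS
defaults; exact rational arithmetic for all net conversions; recovery
tests use 100 seeds for the stochastic estimators (batch μ window 2–14 h,
10+ points). These sizes make the whole suite run in a few seconds while
keeping binomial uncertainty on the 95 %-recovery checks small.

## Known limitations

- No genome-scale modelling: no SBML import, thermodynamics, FBA
  objectives or elementary-mode enumeration beyond the unique-ray check.
- Charge and proton balancing are excluded by design; pH effects on
  yields are outside scope.
- The proteome module does not attempt homology searches to resolve the
  novel genes; the candidate tier simply records the published candidates.
- Wet-lab absolute quantities (specific activities, genome statistics)
  are transcription fixtures, not reproducible computations.
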