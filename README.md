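# galuferm

Quantitative analysis of anaerobic **D-galacturonate fermentation pathways**
— for microbial physiologists and metabolic engineers who want the
stoichiometric, proteomic and kinetic reasoning behind pathway
discrimination in heterofermentative lactic acid bacteria as tested,
reusable code.

D-galacturonate (galUA, C₆H₁₀O₇) is the main monomer of pectin. In the
canonical isomerase (adapted Entner–Doudoroff) pathway it is converted to
two pyruvate via KDPG; redox-cofactor neutrality then constrains the
fermentation products essentially to acetate. A heterofermentative
alternative joins the upper isomerase reactions (to mannonate) to the
phosphoketolase pathway through two novel activities — a mannonate kinase
and a 6-phosphomannonate 2-epimerase — and converts galUA redox-neutrally
to ribulose-5-P + CO₂, and onward to equimolar lactate, acetate and CO₂.

The package provides:

- **Balanced reaction networks** for four pathway variants (canonical
  isomerase, canonical + PDH/PTA/AckA branch, phosphoketolase, hybrid
  isomerase–PK), with explicit ATP/NADH/NADPH deltas and per-reaction
  element and electron (degree-of-reduction, γ) balance checks.
- **Exact net conversions**: steady-state flux rays solved over the
  rationals; ATP yields, NAD(P)H deltas, and LP-based feasibility of
  product profiles (e.g. "can this variant make lactate:acetate = 1:1?").
- **Chemostat reconciliation**: molar yields `q_i/|q_s|`, biomass yield
  `D/(|q_s|·M_s)`, and carbon/electron recoveries using the biomass
  composition CH₁.₈O₀.₅N₀.₂ (γ = 4.2 per C-mol, Roels convention);
  batch growth-rate estimation from ln-linear regression.
- **Proteome evidence mapping**: reaction-level presence/absence scoring
  with paralog support and a candidate tier for enzymes of unresolved gene
  identity; spectral-count percentile ranks.
- **Enzyme kinetics**: direct nonlinear least-squares fits of
  Michaelis–Menten `v = V·S/(K_M+S)` and substrate-inhibition
  `v = V·S/(K_M+S+S²/K_i)` models.
- **Seeded synthetic data** for every input type (chemostat rate tables,
  Monod batch time courses, proteome tables, kinetics assays), constructed
  so noise-free outputs satisfy all conservation laws exactly.

## Worked example

Net conversion of the hybrid isomerase–phosphoketolase route:

```sh
galuferm pathway net --variant hybrid_isomerase_pk
```

prints (abridged):

```json
{
  "net_stoichiometry": {"galua": -1.0, "lactate": 1.0, "acetate": 1.0, "co2": 1.0},
  "atp_delta": 2.0,
  "nadh_delta": 0.0,
  "nadph_delta": 0.0,
  "nad_p_h_combined": 0.0
}
```

One mole of galacturonate yields one lactate, one acetate and one CO₂ with
**+2 ATP** and **zero net NAD(P)H** — the redox-cofactor-neutral property
that lets the route run fermentatively. With the NADPH-linked fructuronate
reductase option, the NADH and NADPH pools each close individually (no
transhydrogenase needed).

Reconciling the packaged chemostat rate table (D = 0.13 h⁻¹; rates in
mmol g⁻¹ h⁻¹: galUA −6.9, acetate 6.0, lactate 5.2, CO₂ 7.2):

```sh
galuferm fixtures copy chemostat_rates rates.csv
galuferm fixtures copy chemostat_config chemostat.yml
galuferm reconcile --rates rates.csv --config chemostat.yml
```

```json
{
  "yields": {"acetate": 0.87, "lactate": 0.75, "co2": 1.04},
  "biomass_yield": 0.0970,
  "carbon_recovery": 0.968,
  "electron_recovery": 0.961
}
```

Yields are mol per mol galacturonate; recoveries are the fractions of
substrate carbon and electrons found in products plus biomass — both close
within a few percent, as expected for clean anaerobic steady states.

Proteome evidence against the full canonical route:

```sh
galuferm evidence completeness --variant canonical_isomerase
```

reports completeness 0.75 with exactly `UxuA`, `KdgK`, `KdgA` missing —
the lower half of the isomerase pathway is absent while every
phosphoketolase-pathway reaction is covered, which is the discrimination
argument for the hybrid route.

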