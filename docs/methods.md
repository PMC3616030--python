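# Model and methods

`reservesim` simulates the value of a coastal fishery and of dive tourism
before and after part of the coastline is closed to fishing. This note
records the model, its assumptions, the parameter choices behind the
bundled Medes Islands example, and the numerical decisions a maintainer
would want to know about.

## Population dynamics

Each species is simulated independently with a Deriso–Schnute
delay-difference model on a linear coastline of `n_patches` equal patches
(default 100). The model collapses age structure into recruits and adults
and tracks per-patch biomass `B` (grams) with a one-year lag:

    B[i, t+1] = (1+ρ) s[t] B[i, t] − ρ s[t] s[t−1] B[i, t−1]
                − ρ s[t] w_{k−1} R[i, t] + w_k R[i, t+1]

where `B` is biomass *after adult movement*, `s = s_nat (1 − u)` is total
annual survival under harvest rate `u`, `ρ` is the Brody growth
coefficient, `w_k` and `w_{k−1}` the mean weights of adults and recruits,
and `R` recruitment in numbers. With recruitment held at its unfished level
`R0` the recursion has the closed-form fixed point

    B0 = (w_k − ρ s_nat w_{k−1}) R0 / ((1 − s_nat)(1 − ρ s_nat)),

used to initialize every patch. Simulations start at this unfished
equilibrium and run a 100-year fished burn-in, so the pre-reserve state the
policy change is compared against is the *fished* equilibrium; the
initialization choice is then immaterial (the burn-in converges
geometrically at rate ≈ `s`).

Transient negative biomass, possible in the lagged recursion under extreme
parameters, is clamped to zero and logged; extinction is absorbing.

## Dispersal and recruitment

Egg production equals start-of-year spawning biomass (grams). Larvae and
adults move with Gaussian kernels in center-to-center patch distance,
`w_ij ∝ exp(−d²/2σ²)` with separate ranges `σ_L` (larvae) and `σ_A`
(adults), each row-normalized so movement proportions sum to one. Row
normalization makes both kernels conserve the coastline total (nothing is
lost off the ends); there is no wraparound, so patches within a few `σ` of
an end deviate slightly from the interior profile. Larval advection,
density-dependent movement, and 2-D domains are out of scope.

Recruitment is Beverton–Holt in the steepness parameterization,

    R = 4 h R0 E / ((1−h) E0 + (5h−1) E),

with `E` the settled eggs in the patch and `E0` the per-patch settlement at
the unfished equilibrium, computed once per species at setup (after passing
the unfished biomass through both kernels, so the anchor includes edge
effects). By construction `R(E0) = R0` and `R(0.2 E0) = h R0`. `E` and `E0`
share gram units, keeping the ratio form consistent without an explicit
egg-to-gram conversion.

## Within-year operation order

Each simulated year applies, in this fixed order: (1) adult movement;
(2) catch `C_i = u_i B̃_i` and survival; (3) egg production from
start-of-year (post-movement, pre-harvest) biomass, larval dispersal,
settlement; (4) Beverton–Holt recruitment entering the next year;
(5) the delay-difference update and lag rotation. The order is a modeling
choice: spawning before harvest is the conservative reading of "eggs equal
spawning biomass at the beginning of the year".

## Reserve geometry and harvest rules

Zone fractions `(no-take, partial, open)` are turned into patch counts by
largest-remainder rounding. The no-take block is centered on the coastline
(avoiding the confound between reserve effects and edge renormalization)
with the partial zone split symmetrically around it, the odd patch going
shoreward of the block's right edge. At year 0 the harvest rate drops to
zero in the no-take zone, is multiplied by `1 − partial_reduction`
(default 0.5) in the partial zone, and is unchanged outside.

## Economics

Fishery profit is `FV = Σ_i (price · C_i − cost_i · u_i)`; effort is
identified with the harvest rate (one unit of effort per unit `u`), the
simplest consistent reading since only the product `cost · effort` enters.

Dive demand is linear in dives and in reserve biomass: the marginal value
of the q-th dive is `MV = α + β q + γ B`, `β < 0`, `γ ≥ 0`, with `B` the
tourism species' post-movement biomass summed over no-take patches
(optionally including the partial zone). Annual fee revenue is `fee · q`;
consumer surplus is the area under the demand line above the fee,
`(α + γB − fee) q + β q²/2`. Three fee policies: `fixed` (demand at a fixed
fee), `optimal` (the revenue-maximizing fee `(α + γB)/2` each year), and
`capped` (fixed fee with `q = min(cap, demand)`; surplus is that of the
capped dives at the fixed fee). A `cap_dives` management event switches the
policy to `capped` in a given post-reserve year, with the cap set to that
year's demand.

Because site-specific demand parameters are rarely published, a
deterministic calibration recovers `(α, β, γ)` from interpretable inputs:
the dives observed at a known fee, the ratio of the choke price to that fee
(`choke_multiple`, default 2), and the share of the choke price attributed
to biomass (`biomass_share`, default 0.5), all anchored at a reference
biomass.

## The Medes Islands example

The bundled fixture reconstructs the two-species case study: striped red
mullet (*Mullus surmuletus*) for the fished stocks (s = 0.66, w_k = 53.93 g,
ρ = 0.77, R0 = 52 000, σ_L = 2, σ_A = 1) and European seabass
(*Dicentrarchus labrax*) for the species divers want to see (s = 0.9,
w_k = 384.9 g, ρ = 0.85, R0 = 6 100, σ_L = 2, σ_A = 0.01); both have
w_{k−1} = 0 and h = 0.75. Coastline zoning is 1% no-take / 12% partial /
87% open on 100 patches; 100 burn-in + 100 post years; the dive-cap variant
fires at post-reserve year 8 (reserve created 1983, cap effective 1991) at
the 3.5 fee.

Values the source case study does not publish are set once as follows:

- **Mullet pre-reserve harvest**: 1.5× its MSY harvest rate, located by the
  bundled grid search (coarse grid of 96 rates on [0, 0.95], one 10× local
  refinement, 500-year equilibration per rate). This encodes "overfished
  beyond MSY"; the search finds u_MSY ≈ 0.44, so u_pre ≈ 0.66.
- **Seabass bycatch**: u = 0.1 everywhere pre-reserve.
- **Price and cost**: 0.01 currency/g for mullet and a uniform cost of
  5 000 per unit effort per patch, making costs absorb roughly 15% of
  landed revenue at the fished equilibrium — a low-cost artisanal fleet.
- **Demand calibration**: 67 000 dives demanded at the 3.5 fee when the
  reserve seabass biomass is at its fully protected (unfished) equilibrium.
  67 000 is the reserve's reported dive count two decades after protection,
  used as the long-run anchor; with `choke_multiple = 2` and
  `biomass_share = 0.5` this gives α = 3.5, β ≈ −5.22e−5, γ ≈ 3.5e−8.

## What the synthetic generator does and does not emulate

`generate_synthetic_scenario(seed)` draws valid random configurations
(survivals 0.4–0.95, ρ 0.5–0.9, steepness 0.3–0.95, dispersal ranges,
harvest rates, calibrated demand, 20–60 patches, 20–60 years each side of
the policy change) for property-based testing. It emulates the *structure*
of real scenarios — parameter ranges a fisheries scientist would call
plausible — but not real covariances between traits (e.g. longevity vs.
growth), environmental stochasticity, or observation error; passing
property tests on these draws demonstrates internal consistency
(non-negativity, conservation, determinism), not predictive skill on any
real reserve.

## Numerical choices and limitations

- Equilibria are detected by fixed iteration (500 years), not root-finding;
  adequate because convergence is geometric in `s`.
- Kernel rows are normalized in double precision; row sums are within
  1e−12 of one and both kernels conserve totals to better than 1e−9.
- Demand, dives, and fees are truncated at zero; no negative prices.
- The simulator itself contains no randomness; all stochasticity lives in
  the synthetic-scenario generator, keyed by a single integer seed.
- Species interact only through shared geometry — no trophic coupling, no
  technical interaction in the fleet beyond the shared harvest-rate map.
- Tourism quality is reduced to one species' biomass; diversity, fish size
  structure, and congestion externalities beyond the linear demand slope
  are not modeled, and the multiplier effects of tourism spending on the
  wider economy are deliberately excluded from the value accounting.
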