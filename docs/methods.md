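# Methods

## Scope

`minibloom` packages the computational backbone of a nano-diatom spring-bloom
analysis: a 0-D trait-based community simulator used to ask whether bottom-up
(nutrients, light) or top-down (selective mortality) control best explains the
dominance of a *Minidiscus*-like nano-diatom over larger bloom diatoms; the
bloom-accounting arithmetic applied to a 32-station survey of the
northwestern Mediterranean deep-convection region (April 2013); and the
genus-level summaries used for global 18S-V9 metabarcoding context. All
external inputs (station surveys, ribotype tables, nutrient profiles) have
synthetic generators with planted ground truth, so the full pipeline is
testable offline.

## Community model

### State and strategists

Four strategists follow Reynolds' C-S-R scheme: `SS` (stress-tolerant
*Synechococcus*-like picocyanobacteria), `C1` (colonist nanoflagellates and
cryptophytes), `C2` (the colonist nano-diatom), `R` (ruderal large bloom
diatoms, e.g. *Chaetoceros*). Each carries five pools — C, N, P, Si (diatoms
only) and Chl — so internal stoichiometry floats freely (non-Redfieldian).
The environment holds dissolved inorganic NO₃, PO₄ and Si(OH)₄, dissolved
organic C/N/P, detrital biogenic silica, and a bacterial compartment
(BC/BN/BP). The system is closed and zero-dimensional: no physical loss
terms, no temperature dependence (the simulated period spans < 1 °C of
observed variation).

### Process formulations

The qualitative process set (quota physiology, mixotrophy, exudation,
implicit mortality, bacterial recycling) is fixed; the functional forms are
the standard quota-model closures:

* **Growth (Droop, Liebig minimum).** The nutrient-set growth ceiling is
  `cap = mu_max · min_X droop(Q_X)` over the elements the strategist uses,
  with the normalised Droop term
  `droop(Q) = min(1, (1 − Qmin/Q) / (1 − Qmin/Qmax))`. The normalisation
  makes `mu_max` the growth rate at full quota — the conventional reading of
  a maximum growth rate, and the one under which the saturated-growth
  analytic test is exact. The diagnostic `quota_status` deliberately returns
  the *raw* term `1 − Qmin/Q` (the textbook Droop limitation), which the
  growth cap then rescales.
* **Photosynthesis (Geider).** C-specific fixation
  `P^C = cap · (1 − exp(−α_chl θ E / cap))`, with `θ` the Chl:C ratio (g:g)
  and `α_chl` the product of maximum quantum yield and Chl-specific
  absorption. Chlorophyll synthesis is down-regulated at saturating light via
  `ρ_chl = θ_max · P^C / (α_chl θ E)`, and shut off once `θ ≥ θ_max`.
* **Uptake (Michaelis–Menten × linear headroom).**
  `V_X = mu_max · Qmax_X · S/(K_X + S) · headroom_X · C` with
  `headroom = clip((Qmax − Q)/(Qmax − Qmin), 0, 1)`. The sufficiency closure
  `Vmax_X = mu_max · Qmax_X` guarantees quota adequacy at balanced growth
  without extra free parameters. Dissolved organic N and P are taken up
  through a common mixotrophy half-saturation `K_DOM` for all strategists.
* **Exudation.** A fixed fraction of gross fixation leaves as DOC; any quota
  above `Qmax` is vented to the matching DOM pool at 1 d⁻¹.
* **Mortality.** Grazers/viruses are implicit: every pool of strategist *s*
  decays at `m_s`; C/N/P losses route to DOM, Si to detrital biogenic
  silica, so the element budgets stay closed (no permanent detrital sink).
* **Bacteria.** Michaelis–Menten uptake of DOC/DON/DOP scaled by bacterial
  biomass; a growth efficiency of 0.3 builds biomass, the remaining C is
  respired (the only C sink of the model) and the remaining N and P are
  remineralised directly to NO₃ and PO₄ (no separate ammonium pool, matching
  the three-nutrient inorganic compartment). Detrital biogenic silica
  redissolves at 0.05 d⁻¹.

### Experiments and forcing

The factorial design crosses two initial nutrient fields — HCNC
(8.40 µM NO₃, 0.39 µM PO₄, 7.72 µM Si(OH)₄, after deep winter convection)
and LCNC (2.66, 0.09, 2.10 µM, weak convection) — with two top-down control
levels applied to the R strategist only: LCC 10 % d⁻¹ and HCC 25 % d⁻¹
biomass loss. Forcing is a square-wave 300 W m⁻² irradiance on a 12 h/12 h
cycle; integration is forward Euler at `dt = 300 s` for 40 days (11,520
steps). `r_mortality_override` exposes the mortality axis continuously for
threshold sweeps.

### Numerics

A proportional flux limiter rescales *all* sinks of a pool by a common
factor whenever they would overdraw it within one step; because each scaled
sink is added to its destination with the same factor, the limiter preserves
the N, P and Si budgets exactly while guaranteeing non-negativity at any
step size (verified by property tests at a 1800 s step with randomised
traits). Round-off residues a few ulp below zero are clamped; anything below
−10⁻⁶ µM raises an instability error. Observed budget drift over 40-day runs
is ~10⁻¹⁴ relative, against a 10⁻⁹ requirement. Forward Euler biases the
realised exponential growth rate by `μ²·dt/2 ≈ 0.002 d⁻¹` at `μ = 1 d⁻¹`,
well inside the 1 % tolerance of the analytic growth check.

### Default traits and calibration

The per-strategist parameter values are this package's own construction (the
contract is behaviour, not a specific published table): they satisfy the
allometric orderings — `K_NO3` increasing and `α_chl` decreasing with cell
size (SS < C1 ≤ C2 < R), maximum quotas decreasing with cell volume, and
`m(C2) > m(C1)` because a homogeneous single-genus group is more exposed to
any one pathogen or grazer than a heterogeneous nanoflagellate mix — and
they reproduce the qualitative experiment contrast: with default traits the
R strategist holds the largest carbon biomass at day 40 under LCC while C2
dominates under HCC, with a single monotone dominance switch at
~0.11 d⁻¹ R-mortality, strictly inside the (0.10, 0.25) d⁻¹ factorial
bracket. Every value is overridable from the YAML config. Raw biomass
magnitudes are not calibration targets; only the dominance ordering and the
existence of the interior threshold are.

Initial conditions (unobserved, config-overridable): 0.05 µmol C L⁻¹ per
strategist and for bacteria, quotas at the admissible midpoint, Chl:C at
θ_max/2, DOM at 1.0/0.15/0.01 µmol L⁻¹ (C/N/P), no detrital silica.

## Bloom accounting

* `net_growth_rate(n0, n, Δt) = ln(n/n0)/Δt`. The canonical example pins the
  seed population at 10 cells L⁻¹ and the bloom window at 40 days, giving
  0.28 ≈ 0.3 d⁻¹ for the 805,000 cells L⁻¹ bloom average; the stated seed
  range 10–100 cells L⁻¹ over the early-March-to-mid-April bracket spans
  0.22–0.28 d⁻¹, and a one-week reading gives ~1.9 d⁻¹.
* `min_sinking_rate = depth/lag`; the "about one month" lag is fixed at 30 d
  so a 2400 m trap yields exactly 80 m d⁻¹.
* `cells_to_biomass` converts counts with per-cell quotas (defaults 0.8 pmol
  C, 0.08 pmol Si for an 18 µm³ cell; Si:C = 0.10, inside the observed
  0.07–0.10 band). `percent_contribution` caps quota-estimate overshoots at
  100 % with a warning (the packaged table brushes 99.4 %).
* `counted_volume` implements the Utermöhl two-diameter transect (1/33 of
  chamber area): 3 mL of a 100 mL chamber, 1.5 mL of 50 mL.
* `summarize_survey` reports presence counts, the mean % contribution to
  diatom abundance over *present* stations only (rows with missing
  contributions excluded — on the packaged table: 17 of 32 present, mean
  92.4 %, rounding to 92 %), the peak station, and abundance classes with
  edges 5×10³/10⁵/10⁶ cells L⁻¹. The mean of the nonzero counts in the
  packaged table is 805,586 cells L⁻¹, matching the 805,000 bloom average
  used in the growth-rate example, which identifies the averaging set as the
  occupied stations.

## Metabarcoding summaries

Relative abundance divides a genus's reads by either total diatom reads
(Bacillariophyta) or total reads of the nine photosynthetic groups, per
sample; zero-denominator samples are missing, not zero. Diversity is the
exponentiated Shannon–Wiener index with natural log (base cancels on
exponentiation only when matched; natural log is fixed and documented).
Genus ranks pool reads over all samples in the depth selection (photic =
SRF ∪ DCM) before ranking — the per-sample-mean alternative is exposed as
`pooling="mean"` but not asserted as canonical, since the source analysis
does not state which was used. Ties share the smaller rank (competition
ranking). Taxonomic transfers between genera are handled by an alias map
applied at load time.

## Synthetic generators

* **Survey**: Bernoulli presence (default 17/32) with truncated-lognormal
  abundances on [5×10³, 6×10⁶] cells L⁻¹ (meanlog 11.7, sdlog 2.4, fit to
  the packaged table's occupied stations); Beta-distributed contribution to
  diatom abundance (mean 0.92); lognormal POC/BSi backgrounds so planted
  percentage contributions are exact arithmetic identities. The abundance
  law is a modelling choice — the source gives only the three abundance
  classes — chosen to span all three.
* **Ribotypes**: per-sample genus proportions are Dirichlet around a
  layer-specific concentration vector (geometric weight decay 0.82,
  concentration 400) with the target genus planted at a chosen rank (default
  8th among diatoms in MESO, 21st in the photic zone); read depths are
  negative-binomial (mean 2000, dispersion 5 — overdispersed, parameters
  free since only totals are reported in the source); genus reads subdivide
  over per-genus ribotype pools with guaranteed coverage when reads ≥
  ribotypes, making planted richness exactly recoverable on deep tables.
  Planted ranks are verified on the realised table, resampling up to 50
  times before declaring the spec infeasible.
* **Nutrient profiles**: the deeply convective cluster is vertically uniform
  at its surface values (7.7 µM Si, 8.4 µM N — fully mixed); the low/no
  convection clusters start at 2.1/2.7 µM with a linear nutricline between
  50 and 150 m toward the deep values. The NC cluster reuses the LC surface
  values, as no separate NC observation exists. The observed concentrations
  imply a surface Si:N uplift of 17.9 % for HC over LC; setting
  `si_n_uplift` plants an exact uplift (e.g. the nominal 15 %) instead. The
  uplift is planted, not emergent — the generator tests the ratio
  computation, it does not model convection.

### What passing tests do and do not show

The generators emulate schema, marginal distributions and planted
summaries; they do not reproduce spatial autocorrelation between stations,
taxonomic mis-assignment, PCR/primer bias, or any covariance between
abundance and contribution. Recovery tests therefore validate the summary
arithmetic and the generator contract, not field-data fidelity. Likewise
the simulator's dominance contrast demonstrates that the implemented trait
structure can reproduce the qualitative experimental outcome, not that the
default parameter values match any particular measured community.

## Problem sizes

Default test and acceptance workloads: four 40-day runs at 300 s (11,520
steps each), a 7-step bisection for the mortality threshold, 100 randomised
2-day stability runs at 1800 s, 200 survey replicates of 32 stations and
500 noisy nutrient-profile replicates. These sizes keep the whole suite
under a minute on a laptop core while leaving Monte-Carlo standard errors
well below the tolerances they are compared against.

## Known limitations

* No physical forcing, advection or sinking inside the model; biomass
  magnitudes are not comparable to field concentrations (no dilution or
  export losses).
* Chlorophyll is diagnostic: its mortality losses leave the modelled
  budgets (Chl is not an element) and no photoinhibition term is included.
* Bacterial stoichiometry is unconstrained (no quota bounds on BN:BC).
* The survey reader accepts only the documented CSV schema; dates in
  DD/MM/YY are assumed to be 2000-era.
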