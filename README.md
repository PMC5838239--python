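# minibloom

Tools for analysing spring blooms of nanoplanktonic diatoms (*Minidiscus*,
2–5 µm): a trait-based C-S-R phytoplankton community simulator with quota
physiology and top-down mortality experiments, the bloom-accounting
arithmetic for station surveys (growth rates, sinking rates, cell-quota
biomass conversions, contribution percentages), genus-level 18S-V9
metabarcoding summaries, and synthetic-data generators with planted ground
truth for every input.

It is aimed at plankton ecologists and biogeochemical modellers who want a
small, fully tested reference implementation of the "why did the tiny diatom
win the bloom?" analysis: competition between four strategists — `SS`
(*Synechococcus*-like stress tolerators), `C1` (nanoflagellate colonists),
`C2` (the nano-diatom colonist) and `R` (large ruderal bloom diatoms) — under
factorial nutrient × mortality conditions.

## The model in brief

Each strategist *s* carries C, N, P, Si and Chl pools. Growth is capped by a
Liebig minimum of normalised Droop quota terms,

```
cap_s = mu_max,s · min_X [ (1 − Qmin_X/Q_X) / (1 − Qmin_X/Qmax_X) ] ,
```

carbon fixation saturates with light through the Chl:C ratio θ (Geider),

```
P^C_s = cap_s · (1 − exp(−α_chl θ E / cap_s)) ,
```

nutrient uptake is Michaelis–Menten with linear quota-headroom
down-regulation and the sufficiency closure `Vmax_X = mu_max · Qmax_X`, and
every pool decays at a specific mortality rate standing in for grazing and
lysis. For the R strategist that rate is the experimental knob: 10 % d⁻¹
(LCC) versus 25 % d⁻¹ (HCC). Bacteria recycle dissolved organic matter back
to NO₃ and PO₄; detrital biogenic silica redissolves. The 0-D system is
integrated by forward Euler at 300 s with a proportional flux limiter, so N,
P and Si budgets are conserved to machine precision and no pool ever goes
negative. See `docs/methods.md` for the full formulation and parameter
rationale.

## Worked example

```python
import minibloom as mb

# --- bloom accounting on the packaged 32-station survey -------------------
table = mb.load_table1()
s = mb.summarize_survey(table)
print(s.n_present, round(s.mean_pct_diatom_abundance, 1), s.max_cells)
# 17 92.4 5819040.0

# 10 cells/L seed growing to the 805,000 cells/L bloom average in 40 days
print(round(mb.net_growth_rate(10, 805_000, 40), 2))   # 0.28  (d^-1)
print(mb.min_sinking_rate(2400, 30))                   # 80.0  (m d^-1)

# --- the mortality-control experiment -------------------------------------
from minibloom import ecomodel as em
lcc = em.run(em.ExperimentSpec("HCNC", "LCC"))
hcc = em.run(em.ExperimentSpec("HCNC", "HCC"))
print(lcc.final_dominant(), hcc.final_dominant())      # R C2
print(max(lcc.budget_drift().values()) < 1e-9)         # True
```

The survey summary says the nano-diatom was present at 17 of the 32
stations, made up 92 % of diatom cells where present, and peaked at
5.8 million cells L⁻¹; filling that bloom from a 10 cells L⁻¹ seed in 40
days requires a net growth rate of ~0.3 d⁻¹, and reaching a 2400 m sediment
trap within a month implies sinking at ≥ 80 m d⁻¹. The simulation pair shows
the dominance flip: with baseline mortality the large ruderal diatom `R`
wins the post-convection bloom; raising only the R mortality to 25 % d⁻¹
hands dominance to the nano-diatom `C2`.

A command-line interface mirrors the library:

```
minibloom simulate --experiment hcnc_x_hcc --out run1
minibloom survey --out summary.json
minibloom synth survey --seed 1 --out synthetic_survey.csv
minibloom barcode --table ribotypes.tsv --genus Minidiscus --out fractions.csv
```

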