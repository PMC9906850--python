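# owlmove

Movement predictability analysis for high-frequency wildlife tracking
data, built around the barn-owl question: do individuals differ not only
in *how far* they move each night (their spatial behavioral type) but in
*how consistently* they do so — and does that predictability matter for
home-range size and survival?

The package takes raw localization fixes (tag id, timestamp, planar x/y
in meters, per-fix accuracy) through:

1. **Quality control** — accuracy filter (STD > 50 m), 15 m/s speed
   filter, segmentation into nights (17:00–06:00 local), four-month
   period labels, and inclusion rules (> 1000 fixes/night, ≥ 25
   nights/individual-period).
2. **Movement indices** — move/stop segmentation (running-centroid rule)
   and the nightly **max-displacement** (bee-line from the night's first
   fix to its farthest fix, km) plus move-only total distance.
3. **Predictability** — a double-hierarchical Gaussian model

       d_ij ~ N(x'β + u_i, σ_ij²),   log σ_ij = w'λ + v_i,
       (u_i, v_i) ~ BVN(0; τ_u, τ_v, ρ)

   fitted by MCMC (Gibbs + adaptive Metropolis, written in-package),
   yielding each individual's behavioral type u_i and its **rIIV** — the
   posterior mean residual SD in km.  Low rIIV = predictable.
4. **Repeatability** — Rp (intraclass correlation from a profiled-REML
   mixed model) and CVi with parametric-bootstrap CIs, for movement
   indices and for period-wise rIIV (is predictability itself stable?).
5. **Home ranges** — autocorrelation-adjusted kernel isopleths from
   10-min-thinned stop locations (effective sample size
   N_eff = min(n, 1 + T/(2τ_pos)) sets the bandwidth), plus a nest-box
   density index (occupied boxes within 1.7 km of the HR center).
6. **Survival** — Cox proportional hazards by Newton–Raphson on the
   Breslow partial likelihood, with age-transition individuals split
   into juvenile and adult records.
7. **Model comparison** — all-subsets ML mixed models, AICc ranking,
   Akaike weights, and full model averaging with unconditional SEs.

A first-class **synthetic-data module** generates cohorts with known
ground truth (individual effects, planted filter artifacts, survival
outcomes), so every inference stage is verified by parameter recovery —
no external download needed.

## Worked example

Run the numbered analysis scripts (a scaled-down cohort of 20
individuals × 40 nights, ~4 minutes total), or the same pipeline in one
call via `owlmove run-all`:

```bash
python analysis/01_simulate_cohort.py 7
python analysis/02_preprocess.py
python analysis/03_movement_indices.py
python analysis/04_predictability_dhglm.py 7
python analysis/05_repeatability.py 7
```

which prints (abridged):

```
cohort: 20 individuals, 4680000 fixes (32884 planted artifacts), deaths: 2
input fixes: 4680000
removed by accuracy filter: 23525, by speed filter: 9359
nights retained: 689/800 (9 individual-period cells dropped)
689 nights; cohort mean max-displacement 2.74 km, mean nightly distance 5.03 km
rIIV range: 0.48 - 3.05 km (most to least predictable of 19 individuals)
Rp = 0.272 [0.135, 0.406]  CVi = 0.341 [0.222, 0.499]
```

Reading this: the accuracy and speed filters removed exactly the planted
artifact classes; the cohort's mean nightly max-displacement (2.74 km)
sits near the generator's 2.45 km preset; individuals span a ~6-fold
range of rIIV (0.48 km for the most predictable to 3.05 km for the
least); and about 27% of the variance in nightly max-displacement is
among-individual (Rp), i.e. owls are individually repeatable in how far
they range.  Scripts 06–08 then estimate home ranges, fit the Cox model
(at this demo scale only 2 deaths occur, so hazard ratios are mostly
uninformative), and run the AICc model comparison — on this cohort the
top model for log home-range size contains mean max-displacement and
rIIV, both with positive averaged coefficients, and age is the dominant
predictor of rIIV (juveniles less predictable).

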