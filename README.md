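# avivuln

Tools for asking whether added mortality — for example collisions at wind
and solar energy facilities — threatens bird populations, and *which*
populations: the birds breeding near a facility, or distant subpopulations
that only pass through on migration.

The package implements a five-step analysis pipeline for biologists working
with carcass-derived tissue samples, regional population estimates and
long-run abundance indices:

1. **Origin assignment.** Feather stable-hydrogen isotope ratios (δ²H, ‰)
   are compared against a calibrated precipitation isoscape.  Each bird gets
   a normalized origin-probability surface; cells whose origin odds beat a
   uniform null by at least 5:1 form its plausible-origin region, and the
   bird is *local* when that region covers the collection facility.
2. **Catchment populations.** Per-individual origin regions are averaged
   into local and non-local catchment areas (local = within the facility's
   Bird Conservation Region; non-local = other flyway BCRs; regions without
   population estimates are excluded).  Regional population estimates,
   weighted by the stressor-affected proportion of each catchment, give the
   subpopulation size N_p with 95% bounds; species without regional
   estimates fall back to continental totals with bounds 0.5×/2×.
3. **Demography.** A Bayesian multi-age matrix model (2×2 up to 5×5; Φ₁,
   Φ₂, Φa survival, fecundity f) is fit to an annual abundance-index series
   through a log-normal observation model, with literature-informed priors
   at three nested constraint levels.  Convergence is judged by
   Gelman–Rubin R̂ < 1.1 and candidates are compared by DIC.  The dominant
   eigenvalue λ of the projection matrix is the annual growth rate.
4. **Vulnerability.** Current fatalities are D = N_p (1 − Φa).  Adding ΔD
   fatalities per year (all adults, additive) lowers adult survival to
   Φa − ΔD/N_p; projecting 48 years under posterior draws yields λ_s and
   the counterfactual ratio CIU = λ_s / λ_original.  A subpopulation is
   *moderately vulnerable* when vulnerability (1 − CIU) reaches 0.2 within
   5000 added fatalities and *highly vulnerable* within 1000.  Relative
   risk RR = (x_l/N_l)/(x_n/N_n) compares local and non-local per-capita
   fatality rates.
5. **Correlates.** Vulnerability is summarized descriptively by guild,
   migration strategy, habitat and population-size bin.

Every input can be generated by the bundled synthetic world
(`avivuln.synthetic_world`) with known ground truth — true origin cells,
true vital rates — so the whole pipeline is testable without external data.

## Worked example

Run the bundled two-species demonstration cohort (one species engineered
with a small local catchment population, one with huge ones):

```bash
avivuln run --demo --seed 0 --out demo_out
# smallpop: complete (highly vulnerable)
# bigpop: complete (not vulnerable)
```

`demo_out/results/classifications.csv` then holds, per subpopulation:

```
species   origin_class  classification         np_mean   d_current  lambda_original
smallpop  local         highly vulnerable       2500.0       454.2           0.9995
smallpop  non-local     moderately vulnerable  17777.8      3229.6           0.9995
bigpop    local         not vulnerable       6000000.0   1212384.3           1.0000
bigpop    non-local     not vulnerable       5000000.0   1010320.3           1.0000
```

Read: the small species has ~2500 individuals in its local catchment and a
stable growth rate (λ ≈ 1.0).  Adding 1000 fatalities per year drives adult
survival from 0.8 to 0.4 and cuts λ by ~31%, far past the 0.2 threshold —
highly vulnerable.  The large species absorbs even 5000 added fatalities
with a <0.1% growth-rate change.  `results/rr.csv` reports, for example,
RR = 8.69 (95% CI 3.61–20.95) for the small species: local birds die at
~9× the per-capita rate of non-local birds.

The same stages are available programmatically
(`assignment_surface`, `subpopulation_size`, `fit_demographic_model`,
`vulnerability_curve`, …) and as individual CLI subcommands
(`avivuln assign|fit|run|report`).

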