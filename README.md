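# artbia — budget impact of pre-conception lifestyle interventions in ART

`artbia` is a deterministic cohort budget-impact model for pre-conception
lifestyle interventions offered to subfertile couples before assisted
reproductive technology (ART) treatment — IVF, ICSI, or IUI. It is written
for health-economics and reproductive-medicine researchers who want to
reproduce, stress-test, or re-parameterize this class of "business case"
calculation.

The model answers: *if a lifestyle program (online lifestyle coaching, a
structured weight-loss program for obese women, their combination, smoking
cessation in men, or mindfulness support) were offered to its target group,
how many spontaneous pregnancies would be gained, how many ART cycles and
pregnancy complications avoided, and what would the annual saving be?*

For an intervention with target group of size *G*, effect rates *r* expressed
as proportions of *G*, unit costs *c*, and program cost *p* per couple:

    Δ_outcome   = r_outcome · G                      (outcome deltas)
    benefit     = (Σ_m Δ_cycles[m]·c_cycle[m]
                   + Σ_k Δ_comp[k]·c_comp[k])/G − p  (per-couple benefit, EUR)
    saving      = benefit · G                        (annual total, EUR)

Each uncertain quantity carries (least, central, most) scenario bounds that
propagate through the chain, and an optional Monte Carlo sensitivity analysis
samples per-couple benefits on [least, most]. The shipped `netherlands_2016`
fixture encodes the published Dutch model population (46,000 subfertile
women; 5400 obese women, 3200 smoking men, 13,700 first-cycle women; ART mix
24% IVF / 16% ICSI / 60% IUI at 1.5 / 1.5 / 3.0 mean cycles) together with
the published result-table cells, and an audit recomputes every cell at its
printed precision — reporting, rather than patching, the source tables'
internal inconsistencies.

## Worked example

```python
from artbia import netherlands_2016, run_scenarios, render_tables, audit_against_printed

config = netherlands_2016()
results = run_scenarios(config)          # least/central/most for all 5 programs

sp = results.interventions["smarter_pregnancy"]
print(sp.cost.per_couple_benefit["central"])   # 513.0   EUR per couple per year
print(sp.cost.total_saving["central"])         # 23598000.0  -> displays €24 M
print(sp.cost.total_saving["most"])            # 101200000.0 -> displays €101.2 M

print(render_tables(results, config.display, format="markdown")["table2"])
```

The table-2 row for the online coaching program prints as

```
| smarter_pregnancy | +6,000 (+13.0) | -2,200 (-4.7) | -1,400 (-3.1) | -10,800 (-23.4) |
```

i.e. a 13.0% uplift in spontaneous pregnancies (5980 unrounded, printed to
the nearest 100) and 4.7% / 3.1% / 23.4% fewer IVF / ICSI / IUI treatments
across the 46,000-couple cohort. The audit then checks every published cell:

```python
report = audit_against_printed(results, config)
print(report.n_match, report.n_flagged, len(report.unexplained_mismatches))
# 40 4 0
```

The four flags are the source tables' known internal inconsistencies (two
smoking-cessation percentages, the €36-vs-€360 mindfulness per-couple cell,
and a €101 M ART-only bound exceeding its own €8.6 M overall bound); see
`docs/methods.md`.

The same pipeline is available from a shell:

```bash
artbia fixture --out nl.yaml
artbia run   --config nl.yaml --format markdown --out results/
artbia audit --config nl.yaml --out audit.json       # exit 1 on any unexplained mismatch
artbia psa   --config nl.yaml --draws 100000 --seed 7 --out psa.json
artbia synth --seed 42 --out synthetic.yaml          # random valid parameter set
```

## Layout

| module | role |
| --- | --- |
| `artbia.config_io` | parameter schema, validation, YAML I/O, the `netherlands_2016` fixture |
| `artbia.cohort_model` | baseline annual ART volumes |
| `artbia.effects` | effect rates → outcome deltas; display rounding |
| `artbia.costing` | per-couple benefit, totals, currency conversion |
| `artbia.scenarios` | least/central/most propagation, Monte Carlo PSA |
| `artbia.reporting_audit` | table rendering, printed-cell audit |
| `artbia.synthetic_params` | seeded random parameter sets, single-field perturbation |
| `artbia.cli` | `artbia` command-line entry point |
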