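# Methods

## The model

`artbia` implements a deterministic, single-year cohort budget-impact model
for pre-conception lifestyle interventions offered to subfertile couples who
would otherwise proceed to assisted reproductive technology (ART: IVF, ICSI,
or IUI). The model is arithmetic over a closed parameter set; there is no
simulation of individual couples, no time dynamics, and no stochastic
component outside the optional probabilistic sensitivity analysis.

The pipeline has four stages.

**1. Baseline volumes.** The prevalent target population is `n_couples`
subfertile couples per year. A treatment mix assigns each couple to exactly
one modality (shares sum to one) with a mean number of cycles per treated
couple, so baseline annual activity is

    couples[m] = share[m] · n_couples
    cycles[m]  = couples[m] · mean_cycles[m]

These are kept as exact real numbers. This matters: several published
percentage/count pairs only reconcile when intermediates are unrounded (e.g.
0.044 · 5400 = 237.6 prints as 200 at a grain of 100).

**2. Outcome deltas.** Each intervention carries effect rates expressed as
proportions of its *target-group* size: an uplift in spontaneous ongoing
pregnancies, per-modality reductions in ART treatments, and per-type
reductions in pregnancy complications (growth restriction, gestational
diabetes, hypertensive complications, preterm birth). A delta is the exact
product `rate · denominator`. Rates are stored as positive magnitudes; the
direction (gain vs. reduction) is fixed by the outcome's semantics and signs
are applied only when printing. An outcome absent from the rate maps means
"no published evidence" and renders as an em-dash, which is distinct from an
explicit zero rate.

Two structural wrinkles, both driven by how the source tables reconcile:

- *Combined program.* The combined online-coaching + weight-loss program is
  parameterized by its own published rates rather than composed from the two
  single programs, because naive addition double-counts the obese subset.
  Its ART and growth-restriction effects apply to the whole cohort while the
  maternal-complication effects apply to the obese subgroup only, so the
  effect spec supports a per-complication denominator override.
- *Smoking cessation.* The published counts (−300 IVF, −100 ICSI) and
  percentages (−0.8, −0.4) are mutually inconsistent under every denominator
  constructible from the stated population. The fixture treats the counts as
  authoritative (rates = count / 3200 smoking men) and the audit flags the
  percentage cells; no guess is made about the intended denominator.

**3. Costing.** The business case per couple is

    benefit = (Σ_m cycles_avoided[m] · c_cycle[m]
               + Σ_k complications_avoided[k] · c_comp[k]) / group
              − program_cost_per_couple

and the annual population saving is the exact product `benefit · group`.
Negative benefits are legal and occur (the least-favorable smoking bound).
Two benefit sources coexist:

- *printed-benefit mode* (the reconciliation surface): published per-couple
  triples (least, central, most) are primitive inputs, multiplied out to
  totals. The ART-only column is likewise taken from the published table.
- *computed-from-deltas mode* (the research surface): benefits derive from
  unit costs. The source publishes no unit costs in its main analysis, so
  the shipped fixture uses round assumption-tagged placeholders (IVF €3000,
  ICSI €3500, IUI €800 per cycle; €20,000 / €2,000 / €10,000 / €30,000 per
  avoided IUGR / gestational-diabetes / hypertensive / preterm case, 2016
  price level) with per-program costs back-fitted so this mode reproduces
  the published central per-couple benefits. These placeholders are clearly
  tagged and are never used as reconciliation evidence.

Money is carried in double-precision EUR. The amounts involved (products of
integer-valued EUR figures and group sizes) are exactly representable, so the
ledger identity `total / group == benefit` holds to machine precision; USD is
display-only via a configurable rate (default 1.1867, back-fitted by
inverting the five published EUR/USD pairs; the source states only ≈1.19).

**4. Scenario bounds and PSA.** The least/central/most propagation treats
each intervention's per-couple triple as primitive and independent across
interventions, mirroring the published per-row bounds; how the source moved
its underlying parameters to construct the bounds is not stated, so no joint
construction is attempted. The optional Monte Carlo analysis draws per-couple
benefits from a uniform or triangular distribution on [least, most]
(triangular mode at central), independently per intervention, each
intervention on its own SHA-256-keyed child stream of the root seed so that
adding or removing an intervention never perturbs another's draws. Summaries
are the empirical mean, SD (ddof = 1), and 2.5/97.5 percentiles of the total
annual saving.

## Display conventions and the audit

Counts print at a grain of 100 (nearest multiple, ties away from zero);
money totals print in millions of EUR with a per-magnitude-band grain
(≥ €10 M → €1 M; €1–10 M → €0.1 M; < €1 M → €0.001 M). Rendering is
deterministic and locale-independent.

The audit recomputes every non-dash published cell and compares at the
precision the cell was printed at: match iff |printed − recomputed| ≤ half
the printed grain (plus a ~1e-9 relative float guard). Per-cell grains are
stored with the printed values because the source's precision is mixed even
within a row; trailing zeros ("0.130 M") are read as padding (grain 0.01 M).
Published percentages carry one decimal (tolerance 0.05).

The source contains four internally inconsistent cells, recorded in the
fixture's anomaly list and reported as `flagged-inconsistency` with notes
rather than silently corrected:

1–2. the smoking-cessation IVF and ICSI percentages (see above);
3. the mindfulness per-couple benefit, printed €36 where €360 is the value
   consistent with both the printed total (€4.9 M / 13,700) and the abstract
   — the fixture adopts 360;
4. the most-favorable ART-only bound of the weight-loss program, €101 M,
   which exceeds its own overall bound of €8.6 M (a plausible typo for
   €10.1 M or a transposition) — stored verbatim, excluded from
   reconciliation.

Any other failed comparison is an *unexplained mismatch* and fails the audit
(non-zero exit from the CLI). On the shipped fixture the audit yields 40
matches, 4 flags, 5 non-recomputable cells (the annual-incidence column,
which is stored but plays no role in any computation — the published tables'
own arithmetic uses the prevalent groups), and 0 mismatches.

## The synthetic generator

`synthetic_params.generate_config` draws random parameter sets with the
structure the analysis assumes — subgroups bounded by the cohort, shares
summing to one exactly, ordered effect triples, reduction rates capped by
baseline volumes so avoided cycles never exceed performed cycles — with all
cardinalities (interventions, modalities, complication types) as parameters.
Per-couple triples and the "printed" table block are produced by running the
model itself, so generated configs are self-consistent and a self-audit
matches every cell; this is what lets every pipeline stage be
property-tested without external data. Boundary cases appear with positive
probability: zero-effect programs, degenerate (collapsed) scenario triples,
and program costs exceeding gross savings. The generator emulates structure,
not Dutch cost distributions; its ranges are test scaffolding.

Passing property tests therefore demonstrate internal coherence of the
arithmetic (ordering, linearity, round-trip identity, audit self-consistency),
not external validity of any particular effect estimate — the effect rates
remain inputs from published trials and expert opinion, with all the caveats
that implies.

## Numerical choices and problem sizes

- Rounding is half-away-from-zero everywhere a grain is applied; it is
  idempotent and applied only at display/audit time.
- Share sum tolerance 1e-9; triple ordering is exact (no tolerance).
- Validation collects all violations rather than failing fast, so a bad
  config file reports every offending field at once.
- The property battery runs the scenario-ordering theorem over 1000
  generated configs (full render + self-audit on a 1-in-50 subsample) and
  the PSA calibration uses 100,000 draws; both complete in seconds.

## Known limitations

- Single-year snapshot: no discounting, no multi-year horizon, no QALYs.
- Ovulation-induction costs, indirect/societal savings, and derivation of
  effect rates from trial microdata are out of scope; rates are inputs.
- The per-cycle attrition process is not modelled (mean cycles only).
- Unit costs in computed-from-deltas mode are assumptions; conclusions
  should rest on printed-benefit mode, which is what the audit exercises.
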