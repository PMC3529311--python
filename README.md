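# equiscale

Equity-stratified cost-effectiveness modelling of community case management
(CCM) scale-up for childhood pneumonia in low- and middle-income countries.

A country is described by five wealth quintiles (Q1 = wealthiest, Q5 =
poorest), each with an under-five mortality rate (U5MR), current CCM
coverage, annual births, a pneumonia case-fatality rate (CFR) and
cause-of-death proportions. The pipeline:

1. **Cost model** — the unit cost per child treated is a constant antibiotic
   cost (US$ 0.27) plus a non-antibiotic component linear in U5MR,
   calibrated by OLS against a bundled 30-cell reference table.
2. **Effectiveness model** — CCM effectiveness declines linearly with U5MR,
   fitted to ten bundled historical study rows; the default form is
   constrained through the (U5MR 0, 100%) anchor. Quintile estimates are
   adjusted upward by 50% of the remaining gap to 100%, then converted into
   a potential impact fraction (PIF) for a coverage change:
   `pif = e·(c1−c0)/(1−c0·e)`.
3. **Burden model** — quintile deaths are `u5mr/1000 × births`; logit-linear
   cause trends (softmax-renormalized) give the pneumonia share, and
   dividing pneumonia deaths by a modelled CFR gives episodes.
4. **Scale-up engine** — four strategies allocate the same number of newly
   covered episodes (default 10% of the national uncovered pool):
   `inequity_promoting` (wealthiest first), `equity_neutral` (median band),
   `equity_promoting` (poorest first) and `mainstream` (proportional to the
   current covered distribution). Each is scored by total cost, lives
   saved, cost per life saved, and lives saved for a fixed budget.

Coverage curves, CFR curves and cause-proportion trends are not available as
published tables, so a seeded synthetic generator
(`equiscale.synthetic`) supplies them, including a five-country demo
scenario whose quintile U5MRs match the published table exactly and whose
remaining fields are plausible synthetic stand-ins.

## CLI

```sh
equiscale fit-costs --out cost_model.json              # bundled table
equiscale fit-costs --pairs my_pairs.csv --out m.json  # columns u5mr,cost
equiscale fit-effectiveness --form anchored-line --out eff.json
equiscale synth --demo Nigeria --out nigeria.csv       # demo dataset CSV
equiscale synth --config gen.yaml --out synth.csv      # GeneratorConfig YAML
equiscale compare --country Peru --step 0.1 --budget 1000000
equiscale run --config run.yaml --outdir results/      # full pipeline
```

`equiscale run` executes fit-costs → fit-effectiveness → burden →
strategy comparison for each configured country and writes
`strategy_results.csv/.json`, `burden.csv`, the fitted model JSONs and a
`manifest.json` from which the run can be repeated exactly. Config keys
(YAML) mirror `equiscale.cli.RunConfig`; CLI flags override them. Custom
country tables are CSVs with header
`country,quintile,u5mr,coverage,births,cfr,cause:<label>...`.

## Layout

- `src/equiscale/data_model.py` — quintile/country types, validation, CSV
  I/O, quintile ratio, bundled reference tables
- `src/equiscale/cost_model.py` — cost line fit and per-child/quintile costs
- `src/equiscale/effectiveness_model.py` — trendline fits, gap adjustment, PIF
- `src/equiscale/burden_model.py` — deaths, cause trends, CFR, episodes
- `src/equiscale/scaleup.py` — allocation strategies and comparison engine
- `src/equiscale/synthetic.py` — seeded generator and demo scenario
- `src/equiscale/cli.py` — click CLI, run config, pipeline and manifests
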