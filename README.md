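# tandemdose

Dosimetry-driven design and efficacy analysis for preclinical tandem
radionuclide therapy with ¹⁷⁷Lu- and ²²⁵Ac-labeled ligands: from ex vivo
biodistribution counts to time–activity-curve fits, decay-chain dose
constants, tumor absorbed dose per injected activity, equal-dose activity
matching, tandem prescriptions, and longitudinal tumor-burden / survival
statistics — with a seeded synthetic-cohort generator standing in for animal
data, so every stage is testable end to end.

## Modules

| Module | What it does |
|---|---|
| `tandemdose.nuclear_data` | Decay data model, branched Bateman chain kinetics, equilibrium times, dose constants in Gy·g/(μCi·h) |
| `tandemdose.biodistribution` | γ-counting samples → %IA and %IA/g tables, Welch group comparisons |
| `tandemdose.tac_fitting` | Mono/bi-exponential TAC fitting, AICc model selection, cumulated activity |
| `tandemdose.dosimetry` | Tumor self-dose per injected activity, equal-dose matching, tandem prescriptions |
| `tandemdose.efficacy` | Radiance summaries with minimum-survivor masking, ANOVA + Bonferroni, Kaplan–Meier, log-rank |
| `tandemdose.synthetic` | Deterministic synthetic biodistribution cohorts and 4-arm trials |

Decay data ship as a plain CSV (`src/tandemdose/data/decay_data.csv`)
compiled from evaluated nuclear data (NNDC/ENSDF, ICRP-107-style values):
one decay branch or one emission per row, beta rows carrying mean (not
endpoint) energies. The ²²⁵Ac chain covers all eight members including the
²¹³Bi branch point (β via ²¹³Po, α via ²⁰⁹Tl) down to stable ²⁰⁹Bi.

## CLI

A single entry point `tandemdose` with subcommands:

```bash
tandemdose doseconst --nuclide 225Ac --mode reference --cutoff 0.01
tandemdose bateman --chain 225Ac --t 0:240:0.5 --out activities.csv
tandemdose biodist summarize --in samples.csv --nuclide 177Lu --out uptake.csv
tandemdose biodist compare --in1 lu_uptake.csv --in2 ac_uptake.csv --organ tumor --time 168
tandemdose fit-tac --in tumor_tac.csv --nuclide 177Lu --models mono,bi --out fit.json
tandemdose dose --fit fit.json --delta-mode reference --mass 0.3 --injected 30MBq
tandemdose match --ref 177Lu:35MBq --ref-dose-rate 0.0075 --target-dose-rate 6.4
tandemdose tandem --components 177Lu:35MBq,225Ac:40kBq
tandemdose efficacy --bli bli.csv --survival surv.csv --week 5 --contrasts tandem:Lu,Ac:Lu,Ac:tandem
tandemdose simulate --out fixtures/ --seed 1        # or --show-defaults
```

All tables are delimited text; `fit-tac`/`dose` reports are JSON.

## Conventions worth knowing

* **Dose constants.** `reference` mode sums alphas plus mean beta energies
  (yield ≥ 1%) with photons excluded — the locally-absorbed self-dose
  convention for mm-scale tumors (absorbed fraction 1.0 for charged
  radiation, ~0 for photons). `charged_all` additionally counts conversion
  and Auger electrons and deliberately deviates from the reference values.
* **%IA.** Activities are decay-corrected to injection time; the denominator
  is the injected activity stated at injection. ²²⁵Ac samples are expected
  to be counted ≥ 24 h after collection (chain equilibrium for daughter-
  window counting — every chain member reaches its asymptotic activity ratio
  within 24 h, the slowest being ²⁰⁹Pb at ≈ 23 h); earlier counts are
  flagged, not silently accepted.
* **Fitting.** %IA curves are treated as decay-corrected, so physical decay
  is added back to the fitted biological rates before integrating to the
  cumulated activity (Ã = Σ Aᵢ/λᵢ,eff).
* **Prescription reporting.** Activities round half-down to integer MBq
  (≥ 1 MBq) or integer kBq, so halving {35 MBq, 40 kBq} reports
  {17 MBq, 20 kBq}.

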