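# tkisim

An integrated drug–disease simulator for **EGFR-mutated lung
adenocarcinoma** under tyrosine-kinase-inhibitor (TKI) therapy. It is
aimed at modelers and pharmacometricians who want to run in-silico
clinical trials comparing EGFR TKIs — here gefitinib (first-generation,
reversible) and osimertinib (third-generation, irreversible, with the
active metabolite AZ5104) — on the same virtual patients, and at
statisticians who need the accompanying survival machinery (weighted
log-rank / MaxCombo tests, bootstrapped curve-similarity, paired effect
models).

## The model in brief

Four coupled layers:

1. **PBPK** (`tkisim.pbpk`) — a 15-compartment perfusion-limited
   whole-body model, dA_t/dt = Q_t(C_art − C_t·BP/Kp_t), with first-order
   oral absorption, well-stirred hepatic clearance, liver formation of the
   active metabolite, and mouse/human physiologies sharing one set of
   equations. A lesion's effective exposure is proportional to the unbound
   concentration of drug in its host organ.
2. **Signaling** (`tkisim.signaling`) — EGFR/MET/VEGFR drive RAS and PI3K
   activation cycles; the TKI competes with ATP at the kinase domain:

   pf = [ATP] / ([ATP] + Km_ATP·(1 + [TKI]/K_i)),

   with the (drug × mutation) K_i table covering exon-19 deletion,
   exon-21 insertion, exon-20 variants, wild type, and the T790M
   gatekeeper rows (K_i/Km_ATP ≈ 1000-fold worse for gefitinib under
   T790M — the mechanism of first-generation resistance).
3. **Tumor** (`tkisim.tumor`) — each lesion is a set of subclones,
   dV/dt = λSV(1 − V_tot/K) − δ(1−S)V − κ_eff·V, where S is the
   normalized pathway output. A near-zero-size resistant subclone
   (T790M, C797S, MET amplification, KRAS/PIK3CA, …) produces the
   classic decline-then-regrowth trajectory.
4. **Trial engine** (`tkisim.population`, `tkisim.trial`) — virtual
   patients sampled from descriptor distributions (including a 1020-patient
   effect-model cohort and the 102-patient retrospective
   gefitinib-vs-osimertinib cohort at 10×), simulated under daily dosing
   and assessed by RECIST 1.1 (progression at ≥20% SLD growth over nadir
   plus ≥5 mm, or a new lesion) every 6 weeks for 24 months.

`tkisim.stats` implements Kaplan–Meier estimation (via lifelines),
Fleming–Harrington G(ρ,γ) weighted log-rank tests, MaxCombo, a
bootstrapped curve-similarity ratio (5000 subsamples of a tenth of the
population; 80% non-significance threshold) and the paired effect model.
`tkisim.calibration` provides CMA-ES parameter fitting with
parameter-recovery-tested synthetic fixtures. See `docs/methods.md` for
equations, defaults and limitations.

## Worked example

Paired in-silico trial on 300 patients mirroring the retrospective
cohort's characteristics, both drugs given to the *same* patients:

```python
import pandas as pd
from tkisim.population import make_li_cohort_spec, sample_population
from tkisim.trial import TrialDesign, run_arm
from tkisim.stats import effect_model, km_median

patients = sample_population(make_li_cohort_spec(n_patients=300), master_seed=31)
arms = {drug: run_arm(patients, TrialDesign(drug=drug))
        for drug in ("osimertinib", "gefitinib")}
for drug, tab in arms.items():
    med = km_median(pd.DataFrame({"time": tab.ttp_months,
                                  "event": tab.event, "group": drug}))
    print(f"{drug}: {int(tab.event.sum())}/{len(tab)} progressed, "
          f"median TTP = {med:.2f} months")
em = effect_model(arms["osimertinib"], arms["gefitinib"], horizon=24.0)
print(f"paired progressors: {em['n_paired']}, median benefit = "
      f"{em['median_benefit']:.2f} months, Pearson r = {em['pearson']:.2f}")
```

prints

```
osimertinib: 100/300 progressed, median TTP = inf months
gefitinib: 225/300 progressed, median TTP = 11.04 months
paired progressors: 96, median benefit = 2.76 months, Pearson r = 0.54
```

Read: under gefitinib three quarters of the cohort progress within the
24-month horizon (median 11 months — driven mostly by regrowth of
T790M-bearing resistant subclones), while under osimertinib two thirds are
still progression-free at 24 months, so the Kaplan–Meier median is not
reached (`inf`). Among the 96 patients progressing under both drugs,
osimertinib buys a median 2.8 extra months. The absolute month values
depend on the shipped default parameterization (see `docs/methods.md`);
the osimertinib-over-gefitinib ordering is the robust output.

The same pipeline is scriptable from the shell:

```bash
tkisim generate-population --spec li_cohort --n 300 --seed 31 --out pop.csv
tkisim simulate-trial --drug gefitinib --spec li_cohort --n 300 --seed 31 --out gef.csv
tkisim simulate-pk --drug osimertinib --dose 80 --n-doses 5 --horizon 120 --out pk.csv
tkisim run scenario.yaml          # full paired scenario from a YAML config
```

## Layout

```
src/tkisim/
  signaling.py    EGFR→RAS/PI3K activation + competitive inhibition
  pbpk.py         whole-body PK, physiologies, drug presets
  tumor.py        subclonal growth law, resistance effects
  population.py   virtual-patient sampling, cohort specs
  trial.py        exposure coupling, RECIST 1.1, arm runner
  stats.py        KM, weighted log-rank, MaxCombo, similarity, effect model
  calibration.py  step-wise fitting; optim.py: CMA-ES / Nelder–Mead
  fixtures.py     seeded synthetic data generators
  config.py       validated run configs + shipped parameter YAML
  scenario.py     end-to-end runner; cli.py: command-line interface
```
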