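# Methods

`tkisim` couples four mechanistic layers — whole-body pharmacokinetics,
EGFR-pathway signaling, subclonal tumor dynamics, and a virtual-population
trial engine — to simulate first-line treatment of EGFR-mutated lung
adenocarcinoma with two tyrosine-kinase inhibitors (TKIs): gefitinib
(first-generation, reversible) and osimertinib (third-generation,
irreversible, with the active metabolite AZ5104). On top of the simulator
sit the survival statistics used to compare arms and a CMA-ES calibration
layer. This note records the model equations, the parameter choices and
their rationale, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Pharmacokinetics (`tkisim.pbpk`)

A 15-compartment perfusion-limited PBPK model: gut lumen, eleven perfused
tissues (gut, liver, spleen, kidney, brain, heart, muscle, adipose, skin,
bone, rest-of-body), lung, and arterial/venous blood. Each tissue obeys

    dA_t/dt = Q_t (C_art − C_t · BP / Kp_t),

with amounts in mg, flows Q_t in L/h, Kp_t the tissue:plasma partition
coefficient and BP the blood:plasma ratio. Gut and spleen drain through the
liver (portal inflow); the lung carries the whole cardiac output and closes
the venous → lung → arterial loop. Oral dosing places `F·dose` in the gut
lumen (first-order transfer `ka` into gut tissue); the bypass `(1−F)·dose`
is tracked in an unabsorbed bin so the mass balance closes identically.
Hepatic elimination is well-stirred on the unbound liver concentration
(rate = CLint · fu · C_liver/Kp_liver); a fraction `fm` of it forms the
metabolite in the metabolite's own liver compartment, converted by the
molar-mass ratio (osimertinib → AZ5104, `fm` default 0.10). Renal
elimination acts on the unbound kidney concentration.

Integration uses LSODA with rtol 1e−8 / atol 1e−10 mg and an output grid of
0.1 h by default; doses are handled as discrete events between integration
segments, and the state recorded at a dose time is the post-dose state.
Three structural checks hold by construction and are enforced in tests:
exact mass balance at every output point (≤1e−6 relative), convergence to
the closed-form one-compartment oral solution when all Kp = BP = 1 and
flows are made very large (≤1% everywhere), and strict dose linearity.

Mouse and human settings share every equation; only the `Physiology` values
change (approximate standard reference flows/volumes for a 70 kg adult and
a 25 g mouse, scaled linearly with body mass). The shipped drug parameter
sets (ka, F, fu, Kp, CLint, fm) are plausible starting values chosen to
land in the reported human plasma-exposure range for 250 mg gefitinib and
80 mg osimertinib daily; they are meant to be re-fitted with the
calibration layer against plasma profiles and are not claimed literature
values.

Tumor exposure: the effective (unbound intracellular) TKI concentration at
a lesion is proportional to the unbound concentration in the host organ,

    C_eff [nM] = s_tumor · fu · C_organ / MW,

with `s_tumor` a dimensionless scaling factor (default 3.0, a calibration
target). AZ5104 shares osimertinib's inhibition constants, so its effective
concentration is simply added to the parent's.

## Signaling (`tkisim.signaling`)

The growth-factor signal is reduced to two downstream hubs. With `pf` the
fraction of active EGFR that is phosphorylated,

    dRas*/dt  = (RasT − Ras*)(ka_met·MET* + ka_vegfr·VEGFR* + ka_egfr·EGFR*·pf) − kda_ras·Ras*
    dPI3K*/dt = (PI3KT − PI3K*)(… + ka_ras·Ras*) − kda_pi3k·PI3K*,

a closed two-state pool per hub (inactive = total − active), which is the
conservation the activation terms imply. Rate constants default to the
published MAPK-cascade-derived values; the pool totals (1e−5 mol/L each)
and the active-receptor baselines (EGFR* 2e−7, MET* and VEGFR* 1e−9 mol/L,
ATP 1 mmol/L) are not published and are configuration, chosen so the EGFR
drive sits near the half-saturation of the activation cycle (maximal
dynamic range of the drug effect).

Competitive ATP-site inhibition:

    pf = [ATP] / ([ATP] + Km_ATP · (1 + [TKI]/Ki)).

The published form of this expression carries a doubled constant term
("1+1+"); we read that as a typesetting artifact and default to the classic
competitive form, but expose `formula_variant="as_printed"` so either
reading is reproducible. The (drug × mutation) Ki table is stored exactly
as published (nmol/L), including both T790M gatekeeper rows. `Km_ATP` is a
property of the mutant kinase, not of the drug; it is back-derived as
Ki / (Ki/Km_ATP) from the osimertinib rows, which are mutually consistent
with the gefitinib rows for every mutation except exon-19-del, where the
printed gefitinib ratio implies Km_ATP ≈ 1.3e7 nmol/L versus ≈1.3e5 from
the osimertinib row. Both printed cells are preserved in the shipped table;
the derived per-mutation Km_ATP uses the osimertinib value, and the
inconsistent cell takes no part in any numeric check.

For constant receptor inputs both cycles have unique closed-form fixed
points (Ras* = RasT·A/(A+kda)); `steady_state` returns them exactly and is
verified against long-horizon integration to 1e−6 relative on random
draws. The scalar growth drive is

    S = w · PI3K*/PI3K*₀ + (1−w) · Ras*/Ras*₀,  clipped to [0, 1],

normalized by the same subclone's untreated steady state (w = 0.5 by
default), so S = 1 without drug.

## Tumor dynamics (`tkisim.tumor`)

The original growth equations are not published; we use an explicit
replacement with the fewest free parameters that reproduces the behaviors
the integrated model needs:

    dV/dt = λ·S·V·(1 − V_tot/K) − δ·(1−S)·V − κ_eff·V,

per subclone, with λ the proliferation rate, δ the signal-deprivation death
rate, κ immune clearance (κ_eff = κ·attenuation in metastases, attenuation
0.5), and K a carrying capacity (5e5 mm³). Subclone volumes are advanced
with a per-step exponential update (exact for a constant rate, never
negative); volumes below 1e−6 mm³ clamp to zero. Lesion diameter is the
equivalent-sphere diameter d = (6V/π)^(1/3); the cell-count↔volume
conversion, where needed, is 1e9 cells/cm³.

Resistance mechanisms act where biology puts them: T790M selects the
gatekeeper Ki row (≈1000-fold worse Ki/Km_ATP for gefitinib, nearly
unchanged for osimertinib); C797S multiplies the irreversible drug's Ki by
200 (covalent anchoring lost); MET amplification scales the MET bypass
input 200-fold (enough to re-drive the pathway when EGFR is silenced);
EGFR amplification scales EGFR* 3-fold; KRAS and PIK3CA alterations impose
constitutive floors of 0.85 on S. Because S is normalized by the same
subclone's untreated state, receptor amplification is a weak resistance
mechanism in this formulation (the gain largely cancels); the
osimertinib-resistance category "EGFR alteration" is therefore represented
mostly through C797S (see population defaults below). This is a known
modeling limitation, not a bug.

Growth-law scale: λ = 1.2 /month and δ = 2.1 /month were set by a coarse
manual calibration so that (i) fully sensitive disease regresses under
either drug at its default exposure, (ii) a T790M subclone under gefitinib
regrows fast enough to produce progression within the 24-month horizon
from a 1e−4 initial fraction, and (iii) the paired retrospective-cohort
simulation reproduces the published qualitative ordering (gefitinib median
TTP ≈ 11 months; osimertinib arm mostly censored at 24 months). Exact
published month values depend on the original authors' calibration and are
asserted nowhere.

## Virtual population (`tkisim.population`)

Patients are sampled from marginal descriptor distributions; a master seed
spawns one child seed per patient (bit-reproducible, order-independent).
Two shipped specifications:

* **Effect-model population** (n = 10 × 102 = 1020): sex M:F = 1:2, age
  N(67, 11²) truncated to [18, 100], smoking never/former/current =
  28/34/38%, ethnicity Asian/other = 55/45%, EGFR exon 19/20/21 =
  51.6/13.2/35.2%. The stage split is not part of that published table and
  reuses the pooled retrospective split (IIIb 65/102).
* **Retrospective (Li) cohort** (arms 49 osimertinib / 53 gefitinib,
  10× multiplier): pooled printed marginals — male 50/102, under-65 52/102
  (mapped to N(65, 10²)), smokers 73/102, stage IIIb 65/102, all-Asian.

Exon 19 maps to the ex19del inhibition row and exon 21 to ex21ins; exon 20
is split 50/50 between the sensitive and resistant exon-20 rows (the
descriptor table does not distinguish them).

Each lesion holds a sensitive subclone and one resistant subclone
initialized at 1e−4 of the lesion volume ("negligible size", a calibration
unknown). Resistance mechanisms are Bernoulli draws per patient. The
published model cites prevalence literature without printing values; our
defaults — T790M 0.55, MET amplification 0.10, C797S 0.07, EGFR
amplification 0.03, PIK3CA 0.07, KRAS 0.04 — keep the stated
decreasing-frequency ordering per drug context and are flattened into a
single per-mechanism table because paired arms need one shared profile per
patient (T790M only degrades gefitinib, C797S only osimertinib, bypass
mechanisms both). All prevalences are config-overridable. Metastases copy
the primary's resistance profile with probability 0.70 (concordance) and
are redrawn independently otherwise.

Geometry: primary lung tumor diameter log-normal (median 30 mm, σ 0.35, a
calibration target); stage IV patients get 1 + Poisson(1) detectable
metastases (capped at 4, truncated above the 10 mm detectability
threshold); every patient carries two micrometastases (median 2 mm) that
can later surface as "new lesions"; stage IIIb patients have no detectable
metastasis at baseline. Inter-patient heterogeneity of aggressiveness is a
log-normal multiplier (σ 0.4) on λ.

## Trial engine (`tkisim.trial`)

Daily dosing reaches periodic steady state within days while tumor
evolution spans months, so the engine integrates the PBPK model to steady
state once per arm (20 settling doses) and reuses the interval-averaged
organ concentrations as constant exposure — per-subclone signals are then
time-invariant and the time-scale separation is exact for the growth law
used. Tests bound the approximation two ways: the signal at the averaged
concentration is bracketed by the trough and peak signals (monotonicity of
S in concentration), and the Jensen gap — signal-of-average versus
time-average-of-signal over the full daily profile — stays below 0.05 at
the default gefitinib steady state.

RECIST 1.1 is evaluated every 6 weeks (standard schedule; configurable) up
to a 24-month horizon: target lesions are up to 5 baseline-detectable
lesions, at most 2 per site, largest first; progression when the sum of
longest diameters reaches ≥1.2× its nadir with an absolute increase of
≥5 mm, or when any non-baseline lesion first exceeds the 10 mm
detectability threshold (new lesion). Time to progression is the first
qualifying assessment time; otherwise the patient is censored at the
horizon. Time units: hours inside PK, months at trial level; the boundary
conversion (weeks → months via 30.4375-day months) is owned by the trial
module.

## Survival statistics (`tkisim.stats`)

Kaplan–Meier estimation wraps lifelines (product-limit and risk-set
bookkeeping) and assembles the Greenwood variance from its event table.
The two-sample machinery implements the Fleming–Harrington G(ρ,γ) weighted
log-rank family with weights Ŝ(t−)^ρ(1−Ŝ(t−))^γ on the left-continuous
pooled KM; (0,0) is the standard log-rank (cross-checked against lifelines
and against an independent brute-force oracle in tests). MaxCombo takes
max |Z| over the weight set {(0,0),(1,0),(0,1),(1,1)} (the standard family;
the published description does not list its set). P-values: permutation
(exhaustive when the group assignment count is small — exact at small n) or
a multivariate-normal integral over the estimated correlation of the
component scores (Genz quasi-Monte Carlo at 1e−4 absolute accuracy, used
where speed matters).

Curve similarity follows the bootstrapped subsampling scheme: 5000
replicates by default, each drawing ⌊n/10⌋ simulated subjects *without*
replacement ("samples, each containing a tenth" reads as subsampling),
MaxCombo-tested against the full comparator at α = 0.05; the similarity
ratio is the fraction of non-significant replicates, declared similar at
the 80% threshold. The effect model pairs each patient's TTP under both
drugs, keeps only patients progressing under both within the horizon,
tallies non-progressors per arm, and reports medians, per-patient absolute
benefit, the Pearson correlation and the 1-SD covariance-ellipse
parameters.

## Calibration (`tkisim.calibration`, `tkisim.optim`)

Step-wise weighted-SSE minimization (PK step first, downstream steps
freezing earlier results). The default optimizer is a compact in-package
(μ/μ_w, λ) CMA-ES (cumulative step-size adaptation, rank-one + rank-μ
covariance updates, box constraints by projection) with scipy Nelder–Mead
as the fallback for tiny smooth tasks. PK residuals are taken on
log-concentrations (profiles span decades); volumes/outcomes on the linear
scale. Parameter recovery on the shipped one-compartment fixtures: all
three parameters (ka, CL, V) within 1% on noiseless data and within 10%
at 5% multiplicative noise, with a geometric sampling grid that covers the
absorption phase (uniform late-only grids leave ka unidentifiable).
Visual predictive checks report the fraction of simulated points inside
the observed mean ± sd band.

## Synthetic-data generators and what passing tests show

`tkisim.fixtures` provides seeded one-compartment plasma profiles with
known truth, Weibull/exponential event tables with administrative
censoring, and small descriptor tables. They emulate the *shape* of the
calibration inputs (sparse noisy concentration series; censored
time-to-event tables), not real data: no inter-individual PK variability,
no assay limits of quantification, no informative censoring, no real
digitized trial curves. Consequently, passing the recovery and similarity
tests demonstrates that the machinery is correct and self-consistent — not
that the shipped parameterization reproduces any specific clinical
dataset, which would require the original individual-level calibration
data.

## Numerical choices and degenerate inputs

* Signaling fixed points are closed-form; no iteration, no tolerance.
* PK integration: LSODA, rtol 1e−8, atol 1e−10 mg; zero-dose regimens are
  legal and yield identically zero concentrations.
* Tumor stepping: exponential per-subclone update, dt = 0.05 month
  (≈1.5 days; halving dt changes 24-month volumes by <0.1%); extinction
  clamp at 1e−6 mm³.
* Weighted log-rank with no events returns statistic 0; one-group or
  empty-group tables raise.
* KM on all-censored data is the constant 1 curve.
* Ties in event times are handled by the hypergeometric variance with the
  standard (n−d)/(n−1) correction.
* Permutation tests enumerate exhaustively whenever C(n, n₁) does not
  exceed the requested permutation count, making small-table p-values
  exact and deterministic.

## Problem sizes used by the shipped checks

The test suite and the acceptance script are sized for a laptop-class
single-core run: descriptor-recovery checks at n = 10,000 patients,
similarity bootstraps at 500 replicates (the full 5000 default remains
available), the paired directional trial at n = 300 patients, and the null
calibration of the log-rank at 2000 replicates of n = 100. These sizes are
the package's own verification choices; all defaults used in production
runs are larger where the published methodology says so (e.g. 5000
bootstrap replicates).

## Known limitations

* Adverse effects, overall survival, death and treatment discontinuation
  are out of scope by design.
* No covalent-occupancy state for the irreversible inhibitors: Ki values
  carry the entire drug-receptor difference.
* No acquired (during-treatment) resistance: all resistance is
  pre-existing in the resistant subclone, selected by therapy.
* Receptor-amplification resistance is structurally weak under the
  own-reference signal normalization (see above).
* No metastasis seeding during treatment; "new lesions" arise only from
  baseline micrometastases.
* PK has no inter-patient variability and no covariate effects (renal
  function, weight); all patients in an arm share one exposure.
* The immune system is a scalar clearance with a metastasis attenuation
  factor, not a cell-population model.
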