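# abmps — patient-specific airway branching model for mechanical ventilation

`abmps` estimates how much pressure is lost between the ventilator and the
alveoli of a mechanically ventilated patient, and condenses a patient's
airway state into a single identifiable number.

The airway is modelled as a symmetric bifurcating tree: an endotracheal
tube (generation −1), the trachea (generation 0) and bronchial generations
1–23, each generation `n ≥ 1` holding `2^n` identical parallel branches.
Flow halves at every bifurcation, and each generation contributes two
laminar pressure-drop terms at its per-branch flow `Q_n`:

```
ΔP_n     = 128 μ L_n Q_n / (π D_n⁴)          (Poiseuille / major loss)
ΔP_minor = (8 K_L ρ / π²) · Q_n |Q_n| / D_n⁴ (bifurcation / minor loss)
```

with μ = 1.9·10⁻⁵ Pa·s, ρ = 1.25 kg/m³, K_L = 2. The population-average
tree badly underestimates the drops seen in ARDS patients, so all
diameters are rescaled by one patient-specific multiplier **α ∈ [0.45,
1.50]** (α < 1: narrower, more resistive airways). Because every summand
carries `D⁻⁴`, the whole-tree drop obeys `ΔP(α) = ΔP(α=1)/α⁴` exactly.

α is identified against the **dynostatic algorithm (DSA)**, the accepted
bedside surrogate for alveolar pressure. At an *isovolume* — a lung volume
visited by both limbs of a breath — assuming equal inspiratory and
expiratory resistance gives the dynostatic pressure

```
P_dyn = (P_insp·Q_exp − P_exp·Q_insp) / (Q_exp − Q_insp),
```

and the inspiratory airway drop `ΔP_DSA = P_insp − P_dyn`. Matching the
areas under the two drop-vs-time curves over one inspiration (AUC, in
cmH₂O·s) then has the closed form

```
α = (AUC_ABM(α=1) / AUC_DSA)^(1/4),
```

clamped to the physiological bounds. The package also ships a synthetic
volume-control SIMV breath generator (decreasing inspiratory flow, passive
expiration through the same tree — the ground-truth substrate for testing
identifiability), and cohort statistics over a packaged 10-patient ARDS
cohort (α per PEEP level of 5/10/15 cmH₂O, diagnoses, auto-PEEP).

Intended users: researchers in respiratory mechanics and model-based
ventilation who want a transparent, testable reference implementation of
tree-resistance modelling, dynostatic pressure estimation and α
identification.

## Worked example

Simulate one noiseless breath from a "patient" whose airways are 0.57× the
reference diameters (PEEP 15 cmH₂O, tidal volume 0.5 L, elastance
30 cmH₂O/L), then identify α from that breath alone:

```python
from abmps import SynthConfig, generate_breath, fit_alpha

cfg = SynthConfig(peep=15.0, tidal_volume=0.5, elastance=30.0,
                  alpha_true=0.57, seed=7)
breath = generate_breath(cfg)
res = fit_alpha(breath)      # AirwayBranchingModel(breath).fit()
print(res.summary())
```

```
Patient-specific airway branching model fit
===============================================
diameter multiplier alpha             0.5782
alpha dispersion (pointwise SE)       0.0030
clamped at bound                       False
AUC general tree (cmH2O*s)            1.5566
AUC dynostatic drop (cmH2O*s)        13.9318
AUC fitted model (cmH2O*s)           13.9318
APE model vs DSA (%)                  0.0000
isovolume points excluded              0.00%
===============================================
```

Reading the output: the general (α = 1) tree predicts an inspiratory
drop-AUC of only 1.56 cmH₂O·s while the dynostatic estimate is
13.93 cmH₂O·s — a ninefold shortfall; rescaling diameters by α = 0.578
closes it exactly (APE 0%). The fitted α sits within 1.5% of the generating
value 0.57; the residual comes from the dynostatic equal-resistance
assumption interacting with the flow-squared minor-loss term (with K_L = 0
the recovery is exact to ~1e-7). The pointwise dispersion (0.003) says a
single multiplier explains the whole breath.

The same workflow from the shell:

```sh
abmps simulate --peep 15 --alpha-true 0.57 --seed 7 -o breath.csv
abmps fit breath.csv -o fit.csv        # prints the median alpha: 0.5782
abmps profile --flow 0.5 --alpha 0.57  # per-generation resistance table
abmps report                           # packaged cohort summary
```

`abmps report` reproduces the published cohort numbers from the packaged
fixture: mean α 0.58, IQR [0.54, 0.63], range [0.45, 0.66] over 30 fits,
COPD vs non-COPD rank-sum p = 1.1·10⁻⁴, and per-diagnosis α ranges
(COPD 0.45–0.62, Aspiration 0.56–0.63, Trauma 0.63–0.64,
Legionnaires 0.59–0.66).

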