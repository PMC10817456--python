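# tmseegdx

Resting-state EEG and single-pulse TMS-EEG biomarkers for depression
discrimination, as a tested, fully synthetic-reproducible pipeline.

## What this is for

Major depressive disorder is still diagnosed from symptoms; there is no
accepted physiological marker. One candidate readout combines eyes-closed
resting EEG with EEG responses to single transcranial magnetic stimulation
(TMS) pulses over the left dorsolateral prefrontal cortex: band power,
phase synchronization and cross-frequency coupling over frontal electrodes,
fed to cross-validated classifiers. This package implements that analysis
end to end for methodologists who want to study the pipeline itself —
its feature definitions, its screening and validation protocol, and the
conditions under which it recovers group effects — on synthetic cohorts
with known ground truth, and it reads real BrainVision/EDF recordings for
application work.

The core quantities, over 17 frontal 10-10 electrodes and the bands
θ (4–7), α (8–13), β (14–30), γ (30–45 Hz):

* **Band power** — Welch PSD (500 ms Hann segments, 50 % overlap)
  integrated over each band, per electrode.
* **wPLI** — weighted phase lag index of the analytic cross-term
  `X_t = x̃_t conj(ỹ_t)`:
  `wPLI = |Σ_t Im X_t| / Σ_t |Im X_t|`, per electrode pair and band;
  insensitive to zero-lag (volume-conduction) coupling.
* **MI** — Tort modulation index of phase–amplitude coupling: with p the
  phase-binned mean amplitude distribution over N = 18 bins,
  `MI = (log N + Σ p_j log p_j) / log N` for θ–γ and α–γ coupling over the
  left-DLPFC electrodes (F3, F5, AF3).

Features are assembled into four modality sets — RST (resting), PRE and PST
(pre-/post-stimulus windows of the TMS-evoked average, −1550…−50 ms and
50…550 ms) and DIF = PST − PRE (614 features each, 2456 in all) — screened
with a two-sided Mann–Whitney U test at p < 0.01, and evaluated with nested
double cross-validation (stratified 5-fold outer, 10-fold inner random grid
search) of nine classifiers (LR, LDA, SVM, KNN, NB, DT, RF, ET, lightGBM)
over all 15 feature-set combinations, with vertically averaged ROC curves
and mean AUC ± SD, followed by held-out permutation importance and post hoc
ANCOVA/Spearman statistics.

## Worked example

```python
from tmseegdx.cohort import generate_cohort
from tmseegdx.config import reduced_cohort
from tmseegdx.experiment import build_feature_table
from tmseegdx.modeling import CVConfig, default_model_registry, nested_cv_evaluate
from tmseegdx.preprocess import PreprocConfig
from tmseegdx.selection import select_features

# a 60/60 cohort with the five planted group effects (d = 1.2), at the
# reduced recording lengths used for simulation studies
records = generate_cohort(reduced_cohort(seed=0))
table = build_feature_table(records, PreprocConfig(run_ica=False))
print(table.values.shape)

sel = select_features(table, alpha=0.01, placement="global")
print(sel.n_selected, "features pass the p < 0.01 screen")
print(sel.table.loc["RST_power_AFz_beta"])

lda = default_model_registry(budget=6)["LDA"]
res = nested_cv_evaluate(table, ("DIF", "PRE", "PST", "RST"), lda,
                         CVConfig(outer_k=5, inner_k=3, seed=0))
print(f"LDA, all four sets: AUC {res.roc.mean_auc:.3f} +- {res.roc.sd_auc:.3f}")
```

prints

```
(120, 2456)
32 features pass the p < 0.01 screen
U           2812.0
p              0.0
selected      True
Name: RST_power_AFz_beta, dtype: object
LDA, all four sets: AUC 0.864 +- 0.090
```

The 2456-column table holds the four 614-feature modality sets for the 120
subjects. Of them, 32 pass the screen: the five planted effects (resting
AFz β power and F4–F6 γ wPLI raised in the patient group; the pre-to-post
changes in F5–AF3 α, AFz–F5 α and AF3–F8 θ synchronization lowered) plus
incidental correlates and the expected ~1 % of chance survivors. The
planted AFz β-power effect separates the groups with U = 2812 of a possible
3600 (p below the displayed precision), and the linear discriminant on all
four sets reaches a mean held-out AUC of 0.864 ± 0.090 at this effect
size and recording length.

There is also a CLI over the same functions:

```bash
tmseegdx run-all --profile fast --seed 1 --out runs/demo
tmseegdx simulate --profile fast --seed 1 --out runs/cohort
```

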