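# cortflow

Analyses of **localized vs. distributed cortical processing** on
parcellated fMRI time series: regional task-activation magnitudes,
task-state functional connectivity (FC) change, intrinsic neural
timescales, myelin-map associations, activity flow mapping error, and
spatial-autocorrelation-aware permutation statistics — plus a
synthetic-data generator that plants all of these relationships with
known ground truth, so the full pipeline is testable end to end without
any imaging data.

## Who this is for

Researchers working with parcellated BOLD data (e.g. a 360-parcel
cortical atlas) who want to quantify, per region,

- how strongly it activates across task conditions (a *localized*
  processing signature),
- how much its background FC to the rest of cortex changes from rest to
  task (a *distributed* signature),
- how slowly its spontaneous activity decorrelates (intrinsic
  timescale), and
- how well its task activations are explained by activity flowing in
  from other regions,

and then to relate those maps to each other and to structural proxies
(T1w/T2w myelin content, a hierarchy score) with statistics that respect
the spatial autocorrelation of brain maps.

## The core quantities

**Task activation magnitude.** Per condition, block timing is convolved
with the canonical double-gamma HRF and regressed against each parcel's
time series; the per-parcel map is the mean over conditions of the
absolute group *t*-statistic of the betas.

**Task-state FC change (ΔGBC).** Task FC is the Pearson correlation of
FIR residuals (one indicator regressor per peri-block TR per condition,
lags extending 25 TRs past block offset) over in-block TRs only. Rest FC
applies the *identical* FIR design and block intervals to resting data.
Each region's weighted degree centrality (GBC = mean off-diagonal FC) is
differenced **task − rest**, so FC reductions are negative.

**Block-peak alternative.** With no task regression at all: each block
contributes each parcel's largest-|value| sample (sign kept) after
baselining to the inter-block rest mean. Peaks are averaged across
blocks for activation, and correlated block-to-block across parcels for
FC; rest uses the same "pseudo-block" machinery.

**Intrinsic timescale.** Each parcel's sample autocorrelation function
R(kΔ) (Δ = TR, lags to 100) is fitted with a bounded nonlinear least
squares model

    R(kΔ) = A [exp(−kΔ/τ) + B],   A ≥ 0, τ ≥ 0, B free,

and τ (seconds) is the timescale. For AR(1) data with coefficient φ the
ground truth is τ = −Δ/ln φ.

**Activity flow mapping.** FC weights to a target are the multiple
regression of its rest series on all other parcels; a target's
activation for condition *i* is predicted as ŷᵢ = Σ_{n≠target} βₙ xₙ,ᵢ
(never using the target's own activation), and per-region prediction
quality is the mean absolute error across the task conditions
(activity flow MAE).

**Statistics.** Map-to-map Spearman correlations are tested against
nulls from variogram-matched surrogate maps (permute → distance-kernel
smooth → rank-remap to the source value distribution), with percentile
bootstrap CIs over parcels, paired transmodal-vs-unimodal contrasts, and
Benjamini–Hochberg FDR.

## Worked example

```python
from cortflow.pipeline import AnalysisConfig, run_pipeline

out = run_pipeline(AnalysisConfig(
    n_parcels=120, n_subjects=10, n_conditions=12, rest_n_tr=1600,
    acf_max_lag=50, n_surrogates=200, n_boot=200, seed=2,
))
glm = out.association_tables["glm"]
print(glm[glm.var_a == "activation"][["var_b", "rho", "p"]].to_string(index=False))
print("tau contrast (transmodal - unimodal):",
      tuple(round(v, 3) for v in out.contrasts["glm"]["timescale"]))
```

prints (seed 2):

```
      var_b       rho        p
  fc_change -0.412369 0.004975
  timescale -0.317022 0.009950
     myelin  0.216348 0.099502
actflow_mae  0.193034 0.109453
tau contrast (transmodal - unimodal): (0.452, 26.432, 0.0)
```

Reading this: regions that activate strongly during tasks *reduce* their
background FC (ρ = −0.41) and sit at fast intrinsic timescales
(ρ = −0.32); transmodal regions have slower timescales than unimodal
ones (mean τ difference 0.45 s, t₉ = 26.4). On the default 360-parcel,
20-subject cohort the planted sign pattern is recovered for every pair
under both the GLM and the block-peak approaches.

The same analyses are scriptable stage by stage from the shell:

```bash
cortflow simulate --out sim/ --seed 1 --n-parcels 60
cortflow timescale --ts sim/rest.tsv --tr 0.72 --out ts/
cortflow run-all --config configs/tiny.json --seed 1 --out results/
```

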