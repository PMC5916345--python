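# petkin

Reference-region kinetic modelling and cohort statistics for multi-tracer
striatal dopamine PET.

Within-subject comparison of dopamine PET markers requires three distinct
quantities from three dynamic scans: dopamine **synthesis capacity** from an
irreversibly trapped AADC substrate (net influx rate K<sub>i</sub>),
**baseline D2/3 receptor binding** from a reversible antagonist
(non-displaceable binding potential BP<sub>ND</sub>), and **dopamine
release** from a repeat scan after a challenge drug raises synaptic dopamine
and displaces the radioligand. `petkin` implements that full workflow for
researchers studying pre-/postsynaptic dopamine regulation, and pairs it
with synthetic-data generators so every estimator is validated by parameter
recovery against known ground truth — no scan data required.

## Models

All quantification is reference-region based (no arterial sampling), using
cerebellar-gray-like kinetics as the comparison tissue.

**Patlak graphical analysis** (irreversible tracer). For frames with
midpoint ≥ t\*, the transformed data

&nbsp;&nbsp;C<sub>T</sub>(t)/C<sub>R</sub>(t) = K<sub>i</sub> · [∫₀ᵗ C<sub>R</sub> dτ / C<sub>R</sub>(t)] + V

become linear; the slope is the net trapping rate
K<sub>i</sub> = k₂k₃/(k₂+k₃) scaled to the reference distribution volume
(default t\* = 25 min on a 25-frame, 90-min schedule).

**Basis-function SRTM** (reversible tracer). The simplified reference
tissue model's operational equation

&nbsp;&nbsp;C<sub>T</sub>(t) = R₁·C<sub>R</sub>(t) + (k₂ − R₁k₂ₐ)·(C<sub>R</sub> ⊗ e<sup>−k₂ₐt</sup>)

is linear given θ₃ = k₂ₐ, so the fit is a grid search over 128 log-spaced
θ₃ values in [0.006, 0.6] min⁻¹ with a weighted least-squares solve per
basis; BP<sub>ND</sub> = k₂/θ₃ − 1 = f<sub>ND</sub>·B<sub>avail</sub>/K<sub>D</sub>.

**Release statistic.** 100·(BP<sub>ND</sub><sup>placebo</sup> −
BP<sub>ND</sub><sup>drug</sup>)/BP<sub>ND</sub><sup>placebo</sup>, computed
per subject and then averaged.

Around the kinetic core: voxelwise parametric maps, group t-maps with
cluster-extent thresholding (including a Monte-Carlo extent calibration),
mask algebra and reference-region construction, Rousset-style geometric
transfer matrix (GTM) partial-volume correction, and a statistics layer
(Pearson/Spearman with seeded 1000-sample bootstrap CIs, Shapiro–Wilk
gating, body-weight partial correlation, paired t with d<sub>z</sub>,
multiple regression, Bonferroni, Fisher-z correlation power, ICC(2,1),
Dice).

## Worked example

Fit both tracers for a scalar TAC, statsmodels-style:

```python
from petkin import (FengInput, PatlakModel, SRTMModel, SRTMTruth,
                    make_frame_schedule, simulate_reference_tac,
                    simulate_irreversible_tac, simulate_srtm_tac)

ref = simulate_reference_tac(FengInput(), 0.1, 0.1, make_frame_schedule("FMT"))
tissue = simulate_irreversible_tac(ref, ki=0.015, v=0.5)
print(PatlakModel(tissue, ref).fit(t_star=25.0).summary())
```

```
Patlak graphical analysis (reference-tissue input)
  Ki (slope)      0.015000 1/min
  intercept       0.500000
  r-squared       1.000000
  frames used    13 (midpoint >= 25 min)
```

The slope returns the simulated synthesis-capacity index exactly (the
graphical-exact simulator is Patlak-linear by construction); an intercept of
0.5 is the apparent distribution-volume offset that the plot absorbs.

A full study — simulate a 40-subject cohort, fit every scan, and run the
statistics battery:

```python
from petkin.pipeline import StudyConfig, run_study
print(run_study(StudyConfig(), seed=1).summary())
```

```
PET signal by region (mean±SD)
     whole_striatum  Ki 0.015±0.002  BP 2.18±0.16 -> 2.00±0.17  release 8.04±3.94%
     dorsal_caudate  Ki 0.019±0.002  BP 3.00±0.24 -> 2.80±0.25  release 6.72±3.50%
     dorsal_putamen  Ki 0.024±0.002  BP 3.83±0.24 -> 3.51±0.30  release 8.49±5.19%
   ventral_striatum  Ki 0.018±0.002  BP 2.60±0.19 -> 2.40±0.21  release 7.42±3.75%
Cross-measure correlations (r [95% CI], p)
     whole_striatum  ki_vs_bp_placebo       pearson  r= 0.53 [ 0.18,  0.75] p=0.0005*
     whole_striatum  bp_placebo_vs_bp_drug  spearman r= 0.83 [ 0.69,  0.91] p=2.22e-11*
     whole_striatum  ki_vs_release          partial_ r=-0.27 [-0.54,  0.03] p=0.102
     ...
```

The descriptive block recovers the generator's population values (striatal
Ki ≈ 0.015 min⁻¹, baseline BP<sub>ND</sub> ≈ 2.2 reduced to ≈ 2.0 by an
8–9 % drug-induced release); the correlation block shows the induced
Ki × BP<sub>ND</sub> association in every region (one cohort's sample r
scatters around the population value of 0.46), an inherently strong
placebo × post-drug correlation, and no Ki × release association, with the
release comparison corrected for body weight. A `*` marks p-values
surviving the familywise criterion (Bonferroni across the three subregions).

The same pipeline is scriptable from the shell:

```sh
petkin simulate --seed 1 --n-subjects 40 --out scratch/cohort
petkin run-study --seed 1 --out scratch/reports
petkin fit-srtm scratch/cohort/tacs/sub000_whole_striatum_rac_placebo.csv \
                scratch/cohort/reference_rac.csv
```

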