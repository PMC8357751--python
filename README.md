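# rsnet

Resting-state EEG functional network analysis: epoch-wise weighted
phase-lag-index (wPLI) connectivity, weighted small-world graph metrics,
and repeated-measures statistics — together with a synthetic
coupled-oscillator EEG generator that provides network ground truth, so
every stage of the pipeline can be validated end to end.

## Who this is for

Researchers analysing multichannel resting-state EEG recorded across
repeated within-subject conditions (e.g. before/after interventions such
as exercise bouts), who want to quantify changes in brain *network
efficiency* rather than regional power, and who need a fully scripted,
reproducible alternative to GUI toolboxes.

## The model and statistics

**Connectivity.** For two sensor signals with analytic representations
`z_i(t)`, `z_j(t)` in a frequency band, the weighted phase lag index of
one epoch is

    wPLI_ij = | Σ_t Im(z_i z_j*) | / Σ_t | Im(z_i z_j*) |      (0/0 := 0)

wPLI ∈ [0, 1]; it is 1 for a persistent asymmetric phase lag, 0 for
zero-lag relations, and is invariant to amplitude scaling — so volume
conduction (instantaneous mixing of one source into many electrodes)
cannot produce spurious connections. Each 8-s epoch yields one
channels × channels matrix per band; a 5-minute recording processed with
the default configuration yields 50 matrices per band per subject and
condition. Matrices are min–max normalized to [0, 1] using the range of
each subject-condition stack.

**Graph metrics.** Treating the wPLI matrix as a weighted undirected
graph (no binary threshold), the pipeline computes the weighted
clustering coefficient `CC` (geometric-mean triangle form, network
segregation), the characteristic path length `PL` (edge length = 1/weight,
network integration), and the small-world index `SWI = CC_norm / PL_norm`
(network efficiency). `CC` and `PL` are normalized per subject by
dividing each (condition, band) value by the mean of all the subject's
other values, so normalized metrics hover near 1 and condition effects
appear as departures from 1. A drop in SWI is read as *network
randomization* — a loss of efficient small-world organization.

**Statistics.** One-way repeated-measures ANOVA over the condition
factor per outcome (SWI/PL/CC × band), with Mauchly's sphericity test,
Greenhouse–Geisser correction, partial η², and Bonferroni–Holm-corrected
pairwise post-hoc t-tests on significant main effects.

**Synthetic cohorts.** Each frequency band is driven by phase oscillators
(Kuramoto dynamics with a fixed nonzero locking offset) coupled on a
Watts–Strogatz graph, superposed on 1/f noise, with optional zero-lag
channel mixing and line noise. Condition effects are injected by swapping
topology parameters per condition — by default the theta-band network is
randomized and weakened at the exhaustion-analog condition (ACUTE3),
leaving a known ground truth that the pipeline should recover.

## Worked example

```python
from rsnet import run_pipeline
from rsnet.pipeline import fast_demo_config
from rsnet.stats import format_results

cfg = fast_demo_config(seed=0)          # 16 subjects x 6 conditions,
result = run_pipeline(cfg)              # reduced 32-channel fast mode
print(result.metrics[result.metrics.band == "theta"]
      .groupby("condition", sort=False)["swi"].mean().round(3))
print(format_results({"swi:theta": result.stats["swi:theta"]}))
```

prints (seed 0):

```
condition
PRE       0.853
ACUTE1    0.885
ACUTE2    0.877
ACUTE3    0.634
REG1      0.886
REG2      0.925
Name: swi, dtype: float64
swi:theta: F(5, 75) = 7.07, p = 1.842e-05 (GG p = 0.0004991), partial eta^2 = 0.320, Mauchly W = 0.136 (p = 0.0271)
    PRE vs ACUTE3: t(15) = 6.90, Holm p = 7.614e-05 *
    ACUTE1 vs ACUTE3: t(15) = 6.12, Holm p = 0.0002739 *
    ACUTE2 vs ACUTE3: t(15) = 5.38, Holm p = 0.0009172 *
    ACUTE3 vs REG1: t(15) = -4.55, Holm p = 0.004222 *
    ACUTE3 vs REG2: t(15) = -5.79, Holm p = 0.0004661 *
```

Normalized theta SWI dips at the exhaustion condition (where the
generator randomized and weakened the theta network) and recovers
afterwards; the condition main effect is significant and every post-hoc
contrast involving ACUTE3 survives Holm correction. The same pipeline on
the alpha-2 band, where nothing was injected, stays null.

The command-line interface exposes each stage (`rsnet simulate`,
`preprocess`, `power`, `connectivity`, `graph`, `stats`) and the
end-to-end `rsnet run --fast --seed 0 --out results/`.

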