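# arcpipe

Analysis pipeline for characterising leptin-receptor-positive (LepR⁺) neuron
populations in the arcuate nucleus (ARC) of the hypothalamus, built around
two experimental readouts:

1. **Single-nucleus RNA-seq screening.** Droplet count matrices are QC
   filtered (feature, count and mitochondrial-fraction gates), demultiplexed
   from antibody-hashtag counts (CLR transform, background-quantile
   thresholding), log-normalised (`ln(1 + 10⁴·c/total)`), profiled per
   cluster, and screened for populations that are LepR⁺ but negative for the
   classical feeding markers *Agrp*/*Npy*/*Pomc* and for the
   ventromedial-hypothalamus marker *Nr5a1* — the signature of the
   *Bnc2*⁺ GABAergic population.
2. **Fibre photometry.** Two-channel GCaMP recordings (465 nm
   calcium-dependent, 405 nm isosbestic) are corrected by a polynomial
   least-squares fit of the 405 nm signal to the 465 nm trace, converted to
   `%ΔF/F = 100·(F465 − F405_fitted)/F405_fitted`, smoothed with a moving
   average, decimated by a factor of 20, time-locked to behavioural events
   (food presentation, eating onset, removal) and summarised as window
   means aggregated per animal.

Supporting modules provide UMI-threshold expression calls with exact
two-tailed Fisher co-expression tests (rational arithmetic, point-probability
rule), co-localization percentages, and a Shapiro–Wilk-gated selector that
chooses between parametric (paired/unpaired *t*, repeated-measures ANOVA)
and rank-based (Wilcoxon, Mann–Whitney, Friedman) two-tailed comparisons.

A synthetic-data generator (`arcpipe.synthetic`) produces droplet count
matrices with planted marker programs, hashtag doublets/negatives and
mitochondrial content, plus photometry sessions with double-exponential
calcium transients, per-channel bleaching, shared motion artifacts and
Gaussian noise — all with known ground truth, so every stage is testable
without any external dataset.

## Worked example

```python
from arcpipe.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(
    out_dir="demo",
    counts={"enabled": True, "seed": 0},
    screen={"enabled": True},
    coexpress={"enabled": True},
    photometry={"enabled": True, "seed": 0, "n_animals": 4, "duration": 420.0},
    align={"enabled": True, "post_s": 300.0, "windows": [(0.0, 300.0)]},
    stats={"enabled": True},
)
print(run_all(cfg)["summary"])
```

prints (seed 0):

```
{'candidates': ['Bnc2_Lepr'],
 'coloc_percent': {'Lepr': 72.7, 'Pomc': 0.0, 'Agrp': 3.4, 'Slc32a1': 81.8},
 'fisher_p': 2.044919758549094e-10,
 'window_means': [0.1051],
 'stat_test': 'paired_t',
 'stat_p': 2.1285855821431487e-05}
```

Reading: the screen recovered the planted *Bnc2*/*Lepr* population as the
unique candidate cluster; among *Bnc2*⁺ cells, 72.7% carry a *Lepr* call
(≥ 2 UMIs) and 81.8% the GABAergic marker *Slc32a1*, while *Agrp*/*Pomc*
co-localization is near zero, and the *Bnc2*–*Lepr* association is highly
significant by the exact test. On the photometry branch, the mean %ΔF/F in
the 0–300 s window after food presentation is positive, and the gated
comparison of cue-epoch vs consumption-epoch means selected a paired
*t*-test with p ≈ 2·10⁻⁵.

The same stages are available as CLI subcommands
(`arcpipe simulate|screen|coexpress|photometry|align|stats|run-all|make-fixtures`).

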