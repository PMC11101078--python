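# pentrace

Exact ¹³C carbon-transition simulation and isotopologue analysis for
glycolysis and the pentose phosphate pathway (PPP).

When cells are fed a ¹³C-labeled hexose (glucose-¹³C₆, or trehalose-¹³C₁₂
cleaved to two labeled glucosyl units), the positions and counts of heavy
carbons in downstream sugar phosphates encode which route the carbon took.
Direct glycolysis keeps hexoses at m+6/m+0; a single oxidative-PPP pass
removes C1 and leaves m+5 pentoses; **cyclic PPP** (re-oxidation of hexoses
regenerated by transketolase/transaldolase) produces characteristic partially
labeled hexoses (m+2, m+3); the **nonoxidative PPP** builds pentoses from F6P
and GAP, giving m+2 ribulose-5P and m+4 sedoheptulose-7P, which never arise
from the oxidative routes. `pentrace` turns this qualitative scheme — the kind
drawn with red/gray carbon balls in tracing studies of *Drosophila* hemocyte
immunometabolism — into an exact, testable calculator, plus the measurement
pipeline around it. It is aimed at metabolomics analysts who have LC-HRMS peak
areas per (sample, metabolite, mass shift) and want pathway-level answers.

## What is inside

| module | contents |
| --- | --- |
| `pentrace.carbon_atlas` | metabolite/reaction universe with explicit atom maps (trehalase, glycolysis, oxidative + nonoxidative PPP); validation; plain-text serialization |
| `pentrace.label_engine` | exact propagation of positional labeling states; one-round cyclic recycling (6 pentoses → 4 hexoses + 2 trioses); first-round tracer-placement enumeration; template mass-isotopologue distributions (MIDs) for four labeling regimes |
| `pentrace.isotope_correction` | binomial natural-abundance matrices; forward convolution; NNLS deconvolution ("compensation" of M+1..M+3 satellites) |
| `pentrace.quantify` | peak-area tables; reference-sample normalization factors (mean of per-metabolite m+0 ratios); isotopologue fractions |
| `pentrace.infer_stats` | Welch and paired *t* tests, step-down Holm–Šidák adjustment, PPP marker scores, pathway-mixture deconvolution (nonnegative least squares on the simplex) |
| `pentrace.synthetic_data` | ground-truthed synthetic experiments (two groups × 5 replicates, log-normal scale factors and peak noise) and an end-to-end recovery harness |
| `pentrace.cli` | `pentrace` command with `generate / normalize / fractions / correct / compare / fit / simulate / enumerate / network / run / recovery` subcommands |

The core statistic is a mixture model on stacked MIDs: for observed corrected
fractions **y** and regime template MIDs **T** (columns = direct glycolysis,
single-pass oxidative PPP, cyclic PPP, nonoxidative PPP, computed exactly by
the labeling engine at the experiment's tracer enrichment),

&nbsp;&nbsp;&nbsp;&nbsp;minimize ‖T·w − y‖² subject to w ≥ 0, Σw = 1,

giving the fractional pathway contributions w.

## Worked example

```python
import pentrace as pt

net = pt.default_network()
tracer = pt.glucose_tracer(net)  # glucose-13C6

# early cyclic PPP at 50% tracer enrichment
mids = pt.simulate_regime(
    net, pt.RegimeSpec("cyclic_ppp", tracer=tracer, enrichment=0.5, rounds=1)
)
print([round(f, 4) for f in mids["G6P"].fractions])
# [0.3438, 0.0312, 0.0938, 0.0625, 0.0938, 0.0312, 0.3438]

scores = pt.marker_scores(mids)
print(scores.oxidative, scores.nonoxidative)
# 0.75 0.0
```

The G6P MID shows the cyclic hallmark: besides the tracer-driven m+0/m+6
poles, partially labeled m+2/m+3 hexoses appear (m+3 from fully labeled GAP
condensing with unlabeled partners, m+2 from recombined labeled pentoses),
while the nonoxidative marker score is exactly zero under this regime.

Running the full pipeline on a synthetic experiment (10% peak-area noise,
5 replicates per group) and deconvolving the corrected MIDs:

```python
rep = pt.end_to_end_recovery(pt.SyntheticConfig(seed=1))
print(rep["groups"]["infected"]["recovered_weights"])
# {'direct_glycolysis': 0.358, 'oxppp_single_pass': 0.231,
#  'cyclic_ppp': 0.267, 'nonox_ppp': 0.144}
print(round(rep["max_weight_error"], 4))
# 0.0326
```

The infected group's true mixture (0.35 / 0.20 / 0.30 / 0.15, with the
cyclic-PPP share raised relative to the uninfected group) is recovered to
within a few percent despite measurement noise.

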