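# chromopulse

Deterministic and stochastic modeling of cytokine-induced gene expression
with three-state chromatin dynamics and upstream signal adaptation, plus
the single-cell time-lapse analysis toolkit that goes with it.

## The problem

Pro-inflammatory genes downstream of interferon-gamma (IFNγ)/STAT1 respond
very differently to the same dynamic stimulus: a primary-response gene like
IRF1 switches on quickly and uniformly even for weak or short inputs, while
chemokines like CXCL10 and CXCL9 need longer or stronger stimulation and
show striking cell-to-cell variability — including cells that never respond
at all. `chromopulse` implements a mechanistic framework for this behavior
and the analysis pipeline to study it: gene activation requires two
sequential TF-dependent chromatin steps (opening, then transcription
initiation), the upstream TF signal adapts through an induced negative
regulator, and heterogeneity emerges when the chromatin-opening timescale
competes with the adaptation window. It is intended for quantitative /
systems biologists simulating single-cell induction kinetics, fitting
induction models to population time courses, or extracting features from
single-cell reporter traces.

## The model

For each of two chromatin loci per gene (closed C, open-uninitiated OU,
open-initiated OI) with mRNA M and protein P:

    dC/dt  = k2·OU − k1·TF·C            dM/dt = k5·OI − δM·M
    dOU/dt = k1·TF·C − k2·OU            dP/dt = k6·M − δP·P
             − k3·TF·OU + k4·OI
    dOI/dt = k3·TF·OU − k4·OI           C + OU + OI = 2

with TF activity TF = tanh(α·([IFNγ] + Kd)), suppressed by an induced
negative regulator when adaptation is enabled:

    dregM/dt = a_regM·TF^c2/(1 + TF^c2) − δ_regM·regM
    dregP/dt = a_regP·regM − δ_regP·regP
    TF = tanh(α·([IFNγ] + Kd)) / (1 + (regP/reg_thr)^c1)

The same species and reactions run either as ODEs (population mean) or as
exact-count direct-Gillespie simulations (single cells), scaled so one
concentration unit is one molecule per cell volume and single-cell peaks
average ~40 protein / 3–6 mRNA molecules. Ships with three calibrated gene
archetypes (`IRF1`-like fast chromatin, `CXCL10`-like slow-opening /
fast-closing, `CXCL9`-like slow-opening / slow-closing), a multi-condition
fitting procedure (plate/chip scaling, peak-40 normalization, bounded
Nelder–Mead), stimulus protocols (constant / pulse / two-pulse), a
synthetic single-cell data generator, and trace feature extractors
(amplitude, lag, width, tanh kinetics, CV, responder classification).
See `docs/methods.md` for conventions and numerical details.

## Worked example

Simulate 1000 single cells per gene archetype under constant 10 ng/ml IFNγ
and compare with the deterministic model (`examples/02_stochastic_ensemble.py`):

```text
   gene peak-P mean peak-M mean CV @ peak nonresp % max |mean-ODE|/SEM
   IRF1        41.4        4.72      0.52       0.0               2.39
 CXCL10        38.6        4.41      1.19      30.9               1.13
  CXCL9        36.5        4.34      1.05      24.5               2.20
```

Single-cell peaks sit at the reference molecule scaling (~40 protein, 3–6
mRNA); the ensemble mean stays within ~3 standard errors of the ODE at
every timepoint; and the slow-chromatin genes are far noisier than the fast
one, with ~30 % of CXCL10-like cells never expressing despite constant
stimulation. The two-pulse experiment
(`examples/03_two_pulse_responders.py`) shows why those nonresponders are
not permanently silenced:

```text
CXCL10: +/+  119  +/-  309  -/+  183  -/-  389
    P(resp pulse1) = 0.43   P(resp pulse2) = 0.30
    P(resp2 | resp1) = 0.28   P(resp2 | no resp1) = 0.32   gap = 0.042
```

Responding to the first pulse barely changes the odds of responding to the
second (gap < 0.1): each pulse is an independent stochastic race between
chromatin opening and signal adaptation. The other examples cover the
deterministic dose/duration matrix, curve recovery by the multi-condition
fit, and feature extraction on synthetic imaging data.

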