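# gnrhinfo

Information transfer via gonadotropin-releasing hormone (GnRH) receptors
to NFAT, quantified at single-cell resolution.

Cell signaling pathways are noisy communication channels: even when a
population shows a clean dose–response, an individual cell's readout may
barely distinguish two stimulus concentrations.  This package provides
the tools to measure that, for GnRH receptor (GnRHR) signaling to the
Ca²⁺/calmodulin/calcineurin/NFAT pathway, and to ask when sensing
*dynamics* — response trajectories, the period after a hormone pulse, or
a second pulse — buys a cell additional information.

It is aimed at quantitative cell biologists and modellers working with
high-content or live-cell single-cell readouts (here: ppERK
immunofluorescence and an NFAT1c nuclear-translocation reporter,
NFAT-NF ∈ [0,1]).

## What it computes

**Mutual information with NSB entropies.**  For a stimulus S (GnRH
concentration as a categorical level) and response Z (a 1–3 dimensional
single-cell readout, discretized into 30 equal-width bins per
dimension):

    I(Z;S)       = H(Z) − H(Z|S)                      (bits)
    I(Z₂;S|Z₁)   = I(Z₂;S) − I(Z₁;Z₂) + I(Z₁;Z₂|S)     (chain rule)

with every entropy estimated by the Nemenman–Shafee–Bialek Bayesian
estimator (posterior mean ± sd under a mixture-of-Dirichlet prior that
is nearly flat on the entropy).  I(Z₂;S|Z₁) is the *additional
information* a second response carries beyond a first.

**A hybrid stochastic model of GnRH → NFAT.**  A six-state cascade
(receptor occupancy → Ca²⁺ → calcineurin → three NFAT pools) whose two
effector totals — GnRHR and calmodulin — fluctuate as exponentiated
Ornstein–Uhlenbeck processes with fluctuation lifetime FL (10 min =
unstable effector, 10,000 min = stable).  Simulated populations (1000
cells per concentration at 0, 10⁻¹¹, 10⁻⁹, 10⁻⁷ M GnRH) feed the MI
machinery to ask how much a cell learns during a 15-min GnRH pulse, in
the 15 min after it, and from a second pulse 135 min later.

**Supporting tools.**  Synthetic fixed-cell and tracked live-cell cohort
generators (log-logistic dose–response with lognormal cell-to-cell
heterogeneity; QC gate on time-0 NFAT-NF outside [0.40, 0.55]), and an
MCMC nucleus tracker (exponential-distance pairing likelihood, MAP by
Metropolis sampling).

## Worked example

```python
import numpy as np
from gnrhinfo import (StimulusResponseSample, mutual_information,
                      during_after_analysis)

# MI from any single-cell table: stimulus level + one readout per cell
rng = np.random.default_rng(0)
s = np.repeat([0.0, 1e-11, 1e-9, 1e-7], 1000)
z = np.log10(1 + s / 1e-9) + 0.5 * rng.standard_normal(4000)
est = mutual_information(StimulusResponseSample(s, z))
print(f"I(Z;S) = {est.value:.2f} ± {est.sd:.2f} bits")

# pulse sensing with the calibrated hybrid model (1000 cells x 4 doses)
res = during_after_analysis(fl=10.0, n_cells=1000, seed=1)
for k in ("I_during", "I_after", "additional"):
    print(f"{k:10s} = {res[k].value:.3f} ± {res[k].sd:.3f} bits")
```

Output:

```
I(Z;S) = 0.76 ± 0.02 bits
I_during   = 0.289 ± 0.023 bits
I_after    = 0.317 ± 0.023 bits
additional = 0.066 ± 0.053 bits
```

Read: with rapidly fluctuating effectors (FL = 10 min) a cell gains
about as much information about GnRH concentration from its NFAT
response after the pulse (0.32 bits) as during it (0.29 bits) — both far
below the 2-bit input entropy of four equiprobable concentrations — and
sensing both windows adds only ~0.07 bits.  Rerunning with
`fl=10000.0` drives the additional information to ~0: when
heterogeneity is stable, the response during the pulse already predicts
the response after it.

A command-line interface mirrors the library:

```
gnrhinfo mi --input cells.csv --signal-col stimulus --response-cols z1 --bins 30
gnrhinfo fig5 --cells 1000 --seed 1 --out results/
gnrhinfo synth tracked --cells 100 --seed 0 --out tracked.csv
gnrhinfo track --input frames.csv --out tracks.csv
```

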