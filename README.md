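# motioncomplexity

Entropic complexity analysis of repeated 2-D hand-motion trajectories, and
its relation to creativity judgments.

## The problem

In motor-creativity experiments, a participant draws a self-chosen
closed-form pattern in a 10 × 10 cm workspace and repeats it N = 10 times,
over 55 trials; an independent jury then ranks the visualised patterns from
most creative (rank 10) to least creative (rank 1). The scientific question
is whether the *informational complexity* of a motion pattern predicts how
creative observers judge it to be — and whether that relation is more than
a side effect of trial-by-trial variability.

Because 10 repetitions are far too few for classical symbol-sequence
complexity estimators, each pattern is first turned into a *probability
distribution over trajectories*, in two ways:

**Gaussian process (GP).** Each spatial dimension is a zero-mean GP over
the time index with squared-exponential covariance
k(t,t′) = σ_f² exp(−|t−t′|²/λ²). The log marginal likelihood of the
repetitions splits into a goodness-of-fit term and a data-independent
model-complexity term; the reported score is the differential entropy
½ log det(2πe (K_λ̂ + σ_ref² I)) at the fitted length scale λ̂, summed over
x and y. Wiggly patterns need short length scales and score high; smooth
ellipses score low; erratic-but-smooth scribbles are explained as noise
around a smooth path and also score low.

**Probabilistic movement primitives (PMP).** Each trajectory is compressed
onto n = 20 normalised Gaussian bases per dimension (ω ∈ ℝ⁴⁰); the
repetitions induce a Gaussian over ω inferred with a conjugate
Normal-inverse-Wishart prior (κ₀ = 0.1, ν₀ = 10, empirical-Bayes location
and scale pooled over the analysed collection). The score is the entropy of
the MAP predictive trajectory distribution
N(Ψμ_ω, ΨΣ_ωΨᵀ + 10⁻¹⁰ I).

Three further per-pattern measures complete the picture: the normalised
**LZ-76** complexity and the **effective measure complexity**
EMC = Σ_L (h_L − h), both computed on ≥ 10 000 grid-cell transition symbols
{l, r, u, d} sampled from the fitted PMP model, and the raw
across-repetition **variance** (VAR) as the confound control.

The correlation stage relates any of these scores to jury rank tables with
Spearman correlations: pooled over all (subject, trial) pairs, per subject,
and as within-trial rank–rank coincidence histograms.

## Worked example

Generate the four canonical artificial pattern classes (20 patterns each in
the full suite; 5 here) and compute all five measures per pattern — this is
the classic dissociation of complexity from variability:

```python
import numpy as np
from motioncomplexity import PatternSpec, generate_pattern, compute_complexity_records
from motioncomplexity.trajectory_core import MotionPattern

classes = ["random_high_var", "complex_low_var", "ellipse_high_var", "ellipse_low_var"]
for ci, cls in enumerate(classes):
    seeds = np.random.SeedSequence(100 + ci).spawn(5)
    patterns = [
        MotionPattern(cls, i + 1, generate_pattern(
            PatternSpec(pattern_class=cls, seed=int(s.generate_state(1)[0] % 2**31))
        ).repetitions)
        for i, s in enumerate(seeds)
    ]
    rec = compute_complexity_records(patterns, seed=ci)
    med = rec[["gp", "pmp", "lzc", "emc", "var"]].median()
    print(f"{cls:>17}  gp={med.gp:9.1f}  pmp={med.pmp:9.1f}  "
          f"lzc={med.lzc:.2f}  emc={med.emc:.2f}  var={med['var']:.2f}")
```

prints

```
  random_high_var  gp=  -1758.7  pmp=  -2628.8  lzc=0.88  emc=0.31  var=10.01
  complex_low_var  gp=  -1265.4  pmp=  -2770.8  lzc=0.57  emc=0.54  var=0.05
 ellipse_high_var  gp=  -2149.5  pmp=  -2789.4  lzc=0.46  emc=1.84  var=0.85
  ellipse_low_var  gp=  -2182.1  pmp=  -2835.6  lzc=0.33  emc=2.03  var=0.05
```

Read it column by column: the complex low-variance class beats the
high-variance ellipse on both probabilistic measures (gp −1265 > −2150,
pmp −2771 > −2789) even though its repetition variance is 17× smaller
(0.05 vs 0.85 cm²) — complexity is not variability in disguise. The random
class has low GP complexity (smooth path + noise explains it) but the
highest PMP entropy (a broad weight distribution is needed), while
normalised LZ-76 simply follows variability (0.88 and 0.46 for the
high-variance classes vs 0.57 and 0.33 for their low-variance
counterparts).

The same pipeline is available from the shell:

```bash
motioncomplexity simulate experiment --subjects 10 --trials 55 --seed 3 --output exp.csv
motioncomplexity gp --input exp.csv --output scores.csv
motioncomplexity simulate jury --scores scores.csv --measure complexity \
    --jurors 10 --noise-sd 0.5 --seed 2 --output ranks.csv
motioncomplexity correlate --scores scores.csv --ranks ranks.csv \
    --measure complexity --mode trial --output corr.csv
# trial-wise Spearman rho = 0.969 (p = 1.97e-12)   (4 subjects x 5 trials demo)
```

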