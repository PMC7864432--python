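# rseeg

Resting-state EEG spectral biomarkers of cognitive decline, as a tested
Python library: epoch-level power spectral densities, the theta/alpha
ratio (TAR), a quantile-distance statistic between band-power
distributions (PDDM), inter-channel coherence, group statistics, and a
PCA+LDA classifier validated by a random under-sampling bootstrap with
leave-one-out cross-validation. A synthetic cohort generator with
controllable group-level spectral structure makes the whole chain
reproducible without clinical recordings.

**Who it is for.** Researchers analysing eyes-closed resting EEG
(nominally 256 Hz, 20 channels in the 10-20 montage) who want
dementia-oriented spectral biomarkers — and in particular a statistic
that stays sensitive when abnormality is present in only a small
fraction of a recording, the regime typical of mild cognitive
impairment.

## The core statistic

EEG slowing in dementia is classically summarised by the theta/alpha
ratio averaged over a session. Averaging, however, dilutes abnormality
that occurs in only a few epochs. `rseeg` therefore treats each
channel's per-epoch log10 band powers as an empirical distribution with
CDF F_B and compares bands through their quantile functions:

    PDDF(u)          = F_theta^{-1}(u) − F_alpha^{-1}(u),  0 < u < 1
    PDDM_{c1,c2}     = ∫_{c1}^{c2} PDDF(u) du
    PDDM95           = PDDM with [c1, c2] = [0.95, 1]

PDDM95 compares the top 5% of theta epochs against the top 5% of alpha
epochs, so a handful of theta bursts that vanish into a session mean
still move it. The integral is computed exactly from order statistics
(piecewise-constant generalized inverse CDFs), making the statistic
antisymmetric and shift-equivariant to machine precision.

## Worked example

Sparse temporal theta bursts against a matched healthy subject
(`python examples/03_pddm.py`):

```
--- healthy ---
temporal TAR          : 0.552
temporal PDDM95       : -0.0184  (log10-power x probability)
PDDF at T6, tail mean : -0.623 log10 units

--- sparse theta bursts ---
temporal TAR          : 0.607
temporal PDDM95       : -0.0119  (log10-power x probability)
PDDF at T6, tail mean : -0.434 log10 units
```

Both subjects share a simulation seed, so the only difference is theta
bursts in ~8% of 1-s epochs on the temporal channels. The bursts lift
the right tail of the theta power distribution (the PDDF tail mean rises
by ~0.2 log10 units) and with it PDDM95, while the session-mean TAR
barely reacts — a burst in 1 epoch of 12 is diluted 12-fold in a mean.
At cohort scale (25 subjects/group, 100 replicate cohorts) this is the
package's headline property: the Hedges g of temporal PDDM95 exceeds
that of temporal TAR in essentially every replicate (mean g ≈ 0.75 vs
≈ 0.37).

The other examples each exercise one capability: `01` cohort simulation
and EDF output, `02` PSD/band/alpha-peak/TAR biomarkers, `04` normalised
coherence with pair classification, `05` group statistics plus the
bootstrap/LOO classifier, `06` the one-call pipeline
(`rseeg.run_pipeline`), whose outputs are byte-identical across reruns
of the same configuration.

```python
import rseeg

bundle = rseeg.run_pipeline(rseeg.demo_config(seed=1), outdir="out")
print(bundle["summary"])           # per-measure best channel, g, t, p
```

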