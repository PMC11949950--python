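# elanull

Energy-landscape analysis (ELA) of multichannel time series, together with
the stationary-linear surrogate null models needed to ask what ELA actually
measures — plus a Mapper-based topological analysis as a contrast method.

## The scientific question

Resting-state fMRI dynamics are often summarized as switching between a
small number of brain states. ELA formalizes this: ROI time courses are
binarized, a pairwise maximum-entropy (Ising) model is fitted, and the
resulting energy landscape's local minima are read as brain states whose
basin-of-attraction transitions describe the dynamics. But how much of
that structure is already implied by *stationary, linear, Gaussian*
properties of the signal — covariance, lag-1 autoregression, the power
spectrum? This package answers the question operationally: it generates
surrogate data that preserve exactly those properties, pushes real and
surrogate data through the identical ELA pipeline, and quantifies how
similar the outputs are. It is aimed at researchers who use or evaluate
state-based summaries of multichannel recordings (N ≲ 15 channels,
T ~ 10³–10⁴ samples).

## The model

For a binary pattern σ ∈ {−1, +1}ᴺ the pairwise maximum-entropy model is

    E(σ) = − Σᵢ hᵢ σᵢ − ½ Σ_{i≠j} J_ij σᵢ σⱼ,   P(σ) = e^{−E(σ)} / Z,

the maximum-entropy distribution matching the empirical ⟨σᵢ⟩ and ⟨σᵢσⱼ⟩.
Fitting is exact gradient ascent on the enumerated log-likelihood
(hᵢ ← hᵢ + ε(⟨σᵢ⟩_data − ⟨σᵢ⟩_model), likewise for J), feasible for
N ≤ 20. The landscape over all 2ᴺ states yields local minima (states below
all single-flip neighbours), steepest-descent basins, and a
disconnectivity tree of saddle energies (minimax barrier between minima,
computed by ascending-energy union-find).

Null models: **static** (i.i.d. Gaussian with the data's mean and
covariance), **ARR** (fitted VAR(1), A₁ = C₁C₀⁻¹, iterated from a random
real sample), **PR** (phase randomization with phases shared across
channels, preserving all auto- and cross-spectra exactly), and a
**dichotomized-Gaussian binary null** matching the mean and correlation of
the *binarized* data. Comparisons: Pearson correlation of the 2ᴺ energies;
elementwise correlation of basin transition matrices (all elements or
off-diagonal, the latter only with ≥ 4 basins), with surrogate dynamics
either labelled by their own basins or projected through the real ones.

All inputs are synthetic and seeded: a stable HCP-like VAR(1) generator
("pseudo-real" data), a two-regime Gaussian switching generator (for the
topological contrast), and an exact Ising sampler (for recovery tests).

## Worked example

```python
import elanull as en
from elanull.datatypes import SurrogateSpec

series, _ = en.hcp_like_series(seed=1, n_channels=7, n_samples=8000)
b = en.binarize(series)
pmem, info = en.fit_pmem(b, tol=1e-6)
ls = en.build_landscape(pmem)
print(f"fit: {info.n_iter} iterations, moment discrepancy {info.discrepancy:.2e}")
print(f"local minima (state indices): {ls.minima.tolist()}")

surr = en.pr_null(series, SurrogateSpec('pr', 1.0, seed=2))
ls_surr = en.build_landscape(en.fit_pmem(en.binarize(surr))[0])
print(f"energy-landscape correlation (real vs PR surrogate): "
      f"{en.landscape_correlation(ls, ls_surr):.4f}")

tm_real = en.transition_matrix(en.label_series(b, ls))
tm_surr = en.project_surrogate_dynamics(en.binarize(surr), ls)
print(f"transition-matrix correlation (all elements): "
      f"{en.tm_correlation(tm_real, tm_surr, 'all'):.4f}")
```

Output:

```
fit: 164 iterations, moment discrepancy 9.92e-07
local minima (state indices): [9, 21, 62, 65, 106, 118]
energy-landscape correlation (real vs PR surrogate): 0.9977
transition-matrix correlation (all elements): 0.9916
```

The PR surrogate — linear and stationary by construction — reproduces both
the landscape and the transition structure of this linear test signal
almost perfectly. The same comparison against the static null gives a
transition-matrix correlation of only 0.41: landscapes reflect covariance,
transition probabilities additionally require the lag-1 structure.

A command-line interface mirrors the library
(`elanull simulate|surrogate|fit|dynamics|tda|run-experiment`, see
`elanull --help`).

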