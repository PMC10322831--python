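# rsnphi

Integrated-information and causal metrics for small binary
brain-network time-series.

## The problem

How much does a small network of brain regions behave as an integrated
whole, rather than as a collection of independent parts — and does that
quantity track the level of awareness as an anesthetic takes hold and
wears off?  Integrated information theory (IIT 3.0) answers the first
question with Φ^max, the *maximally integrated conceptual information*:
starting from a network's transition probability matrix (TPM), it
relates the current state to all of its possible causes and effects,
partitions the system every possible way, and measures — with the earth
mover's distance between cause–effect structures — how much is lost by
the least destructive cut.  Because Φ^max is state-dependent, a
time-series is summarized by **μ[Φ^max]**, the average of Φ^max over
the visited states weighted by each state's occurrence frequency.

`rsnphi` implements that computation end to end for binarized
region-level resting-state fMRI-like signals (2–6 regions), together
with three reference measures computed on the same series:

* **Φ\*** — whole-system lagged mutual information minus the sum of
  part MIs, minimized over all 2|3 bipartitions of five regions;
* **CD** (causal density) — the mean conditional Granger causality 𝓕
  over all N(N−1) directed region pairs, from VAR fits with
  BIC-selected order in 1..20;
* **μ[ρ]** — the mean Pearson correlation over all N(N−1)/2 pairs.

Around the metrics sit the full study-style apparatus: band-pass
(0.01–0.1 Hz Butterworth) detrending, per-region z-scoring and
binarization at the region's own mean; little-endian state indexing and
TPM estimation from multi-subject concatenations (cross-subject
transitions excluded); spatial and temporal permutation controls; χ²
Markov-property and conditional-independence diagnostics; and a
modulation analysis that scores each network's 4-condition vector
M⃗ = [m_A, m_M, m_D, m_R] by its magnitude M = ‖M⃗‖ and its cosine
similarity S with the awareness model vector E⃗ = [1, 0, −1, 1].
A synthetic cohort generator with explicit ground-truth TPMs (17
subjects × 4 sedation conditions × 11 networks × 245 time points by
default) makes every stage testable without any data download.

It is aimed at computational neuroscientists who want a transparent,
fully tested Python implementation of these measures at small-network
scale — not at large-network approximations (the exact computation is
intractable beyond ~6 regions by design).

## Worked example

Eight simulated subjects from one strongly coupled 3-region network
(coupling 0.8), concatenated and analyzed:

```python
import numpy as np
from rsnphi import (GroundTruthNetwork, make_coupled_tpm,
                    simulate_binary_series, concatenate_subjects,
                    mu_phi_max, mean_correlation, temporal_shuffle)
from rsnphi.metrics import phi_star, causal_density

tpm = make_coupled_tpm(3, 0.8, seed=1)
net = GroundTruthNetwork(3, tpm, 0.8, label="demo")
subjects = [simulate_binary_series(net, 245, seed=s) for s in range(8)]
series = concatenate_subjects(subjects)

res = mu_phi_max(series)
print("mu[Phi^max] =", round(res.mu_phi_max, 4))
print("Phi* =", round(phi_star(series).phi_star, 4))
print("CD   =", round(causal_density(series, p_max=10).causal_density, 4))
print("mu[rho] =", round(mean_correlation(series).mu_rho, 4))
nulls = [mu_phi_max(s).mu_phi_max for s in temporal_shuffle(series, 10, seed=0)]
print("shuffled mu[Phi^max] mean =", round(float(np.mean(nulls)), 4))
```

prints

```
mu[Phi^max] = 0.3739
Phi* = -0.225
CD   = 0.0214
mu[rho] = 0.8295
shuffled mu[Phi^max] mean = 0.0114
```

Read: the coupled network generates substantial integrated information
(μ[Φ^max] ≈ 0.37 across its 8 visited states), which collapses by ~97%
when the time points are shuffled — integration lives in the temporal
order, which shuffling destroys, while μ[ρ] would not move at all.
Φ\* here is negative: its plain MI-difference form is minimized over
bipartitions and strongly self-persistent regions can push part MIs
above the whole — one reason it separates original from permuted data
poorly.  CD is small but positive at this series length.

The modulation analysis is statsmodels-style — build a model, fit it,
read the results:

```python
from rsnphi import SyntheticCohort, generate_cohort, ModulationAnalysis, mean_correlation

cohort = generate_cohort(SyntheticCohort(subjects=8, n_timepoints=150, n_nodes=3, seed=42))
model = ModulationAnalysis.from_cohort(cohort, lambda s: mean_correlation(s).mu_rho,
                                       metric_name="mu_rho")
results = model.fit()            # Welch t-tests + Benjamini-Hochberg
print(results.summary())         # per-network M, S, significant pairs
results.plot_magnitude_similarity()
```

A thin CLI (`rsnphi simulate / prep / tpm / phi / metrics / shuffle /
diagnose / all`) wraps the same functions for shell use; `rsnphi all
--config cfg.yaml` runs the whole pipeline reproducibly from one seed.

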