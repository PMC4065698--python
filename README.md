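# hsmmseg

Position-aware **hidden semi-Markov model (HSMM)** segmentation of genomic
profiles: array log-ratios, methylation differences, p-value tracks and
sequencing read counts.  The package partitions a position-indexed signal into
non-overlapping homogeneous segments and assigns each segment one of `J`
states (e.g. loss / null / gain for copy number, background / low / peak for
read counts), with the time spent in each state governed by an explicit,
learnable sojourn distribution rather than the geometric law an ordinary HMM
implies.

It is aimed at analysts of tiling-array, aCGH, bisulfite and NGS coverage
data who need a general segmentation engine whose duration model can absorb
genomic distance and prior annotation, plus a reproducible simulation
benchmark for segmentation power (ROC/AUC) and parsimony (segment counts).

## Model

At positions `t = 1..T` we observe `x_t` (one or more samples) emitted by a
hidden state `S_t ∈ {1..J}`.  The model is `θ = (π, A, B, D)`:

- `π` — initial state probabilities;
- `A` — the *embedded* transition matrix between distinct states
  (`a_jj = 0`);
- `B` — per-state emission densities `b_j(x_t)`: normal / Student-t
  (uni- or multivariate) for continuous signals, Poisson / negative binomial
  for counts;
- `D` — per-state sojourn distributions `d_j(u)` on durations
  `u ∈ {1..M}` (nonparametric, gamma, Poisson, negative binomial, or
  geometric — the last recovers a standard HMM).

For a state sequence with runs `(S_1, u_1), …, (S_R, u_R)` the likelihood is

```
L(θ) = π_{S1} d_{S1}(u1) [ ∏_{r=2..R} a_{S_{r-1} S_r} d_{S_r}(u_r) ]  →  last run censored:
       the final d_{S_R}(u_R) is replaced by the survivor D_{S_R}(u_R) = Σ_{v ≥ u_R} d_{S_R}(v),
       times ∏_t b_{S_t}(x_t).
```

Inference is exact: a forward–backward recursion over run endpoints gives the
total likelihood, the smoothed posterior `P(S_t = j | x)` and the EM
sufficient statistics in `O(J·T·min(T, M))` time and `O(J·T)` memory; a
duration-explicit Viterbi pass gives the most probable segmentation.
Parameters are estimated by EM with a *parametric* sojourn M-step (method of
moments on the expected duration weights), guarded so the likelihood trace
never decreases.

## Worked example

```python
import numpy as np
from hsmmseg import GenomicProfile, SegmentConfig, segment_profile, simulate_cnv

sim = simulate_cnv(r=2.0, seed=7)          # 3-state copy-number-like track
profile = GenomicProfile(np.full(sim.T, "chr1"), sim.positions,
                         sim.values[:, None], samples=["logratio"])
res = segment_profile(profile, SegmentConfig(J=3, emission_family="norm"))
print(res.segments[["start", "end", "state", "mean", "n_features"]].tail(3))
print((res.states[("chr1", "logratio")] == sim.true_states).mean())
```

prints

```
    start   end  state      mean  n_features
12    901  1150      2  3.940676         250
13   1151  1162      3  6.214710          12
14   1163  1164      2  4.683971           2
0.9965635738831615
```

— 15 segments over 1164 positions against 14 simulated ones; state 1/2/3 are
the low/null/high signal levels, `mean` is the average signal inside the
segment, and 99.7% of positions get their generating state back.  See
`examples/` for count peaks with run-length-compressed input, sojourn priors
learned from annotation, the ROC benchmark, and the two-track DMR workflow;
every capability is also reachable from the thin `hsmmseg` command line
(`segment`, `simulate`, `benchmark`, `dmr`).

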