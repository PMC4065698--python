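"""Synthetic data generators for benchmarking the segmentation engine.

Two scenarios emulate the study conditions of the simulation benchmark:

``cnv``
    Array-type copy-number data.  Three states (loss / null / gain) with
    segment lengths drawn from Poisson distributions with means 20, 270 and
    10 respectively (the null state is intentionally long), and intensities
    drawn from N(r, 1), N(2r, 1), N(3r, 1); the interstate ratio ``r`` acts
    as a signal-to-noise control (grid 1..3).  States of interest: loss
    (state 1) and gain (state 3).

``counts``
    Sequencing read counts.  Three states (intergenic background / short
    lowly-expressed feature / high-abundance coding feature) with segment
    lengths Poisson-distributed with means 285, 5 and 10, and counts drawn
    from Poisson(1), Poisson(r), Poisson(r^2) (grid 1.5..2 step 0.25).
    State of interest: the signal peak (state 3).

A sequence joins 14 segments on average: states are sampled uniformly with
adjacent segments forced to differ, redrawing until all three states occur;
inter-feature spacing is regular and equal to 1.  Zero-length Poisson draws
are redrawn so every segment is non-empty.

A third generator builds a planted-truth methylation fixture (two tracks:
methylation difference and test p-value over irregular CpG-like positions)
for exercising the DMR workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import GenomicProfile

__all__ = [
    "SimulatedSequence",
    "simulate_cnv",
    "simulate_counts",
    "draw_layout",
    "draw_values",
    "simulate_methylation",
]

CNV_LENGTH_MEANS = (20.0, 270.0, 10.0)
COUNT_LENGTH_MEANS = (285.0, 5.0, 10.0)
DEFAULT_SEGMENTS = 14


@dataclass
class SimulatedSequence:
    """One simulated track with its generating truth."""

    values: np.ndarray
    true_states: np.ndarray  # 0-based states per position
    true_segments: int
    r: float
    scenario: str  # "cnv" | "counts"
    seed: int | None = None

    @property
    def T(self) -> int:
        return self.values.size

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.T + 1, dtype=np.int64)

    @property
    def interest(self) -> set:
        """True states of interest (1-based): gain+loss for cnv, peak for counts."""
        return {1, 3} if self.scenario == "cnv" else {3}


def _poisson_at_least_1(rng: np.random.Generator, lam: float) -> int:
    u = 0
    while u < 1:
        u = int(rng.poisson(lam))
    return u


def draw_layout(rng: np.random.Generator, scenario: str, n_segments: int = DEFAULT_SEGMENTS):
    """Draw one segment formation: per-segment states and lengths.

    States are uniform over {0,1,2} with adjacent segments distinct, redrawn
    until all three states occur; lengths are Poisson draws (>= 1) with the
    scenario's per-state means.
    """
    lams = CNV_LENGTH_MEANS if scenario == "cnv" else COUNT_LENGTH_MEANS
    while True:
        states = np.empty(n_segments, dtype=np.int64)
        states[0] = rng.integers(0, 3)
        for k in range(1, n_segments):
            step = rng.integers(1, 3)
            states[k] = (states[k - 1] + step) % 3
        if n_segments < 3 or len(np.unique(states)) == 3:
            break
    lengths = np.array([_poisson_at_least_1(rng, lams[j]) for j in states], dtype=np.int64)
    return states, lengths


def draw_values(rng: np.random.Generator, states, lengths, r: float, scenario: str) -> np.ndarray:
    """Draw observation values for a fixed segment formation."""
    per_pos = np.repeat(np.asarray(states), np.asarray(lengths))
    if scenario == "cnv":
        means = np.array([r, 2.0 * r, 3.0 * r])
        return rng.normal(means[per_pos], 1.0)
    rates = np.array([1.0, r, r * r])
    return rng.poisson(rates[per_pos]).astype(np.int64)


def _simulate(scenario: str, r: float, seed, n_segments: int) -> SimulatedSequence:
    rng = np.random.default_rng(seed)
    states, lengths = draw_layout(rng, scenario, n_segments)
    values = draw_values(rng, states, lengths, r, scenario)
    return SimulatedSequence(
        values=values,
        true_states=np.repeat(states, lengths),
        true_segments=int(len(states)),
        r=float(r),
        scenario=scenario,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_cnv(r: float, seed=None, n_segments: int = DEFAULT_SEGMENTS) -> SimulatedSequence:
    """Simulate one copy-number-style sequence (3-state normal mixture)."""
    if r <= 0:
        raise ValueError("r must be > 0")
    return _simulate("cnv", r, seed, n_segments)


def simulate_counts(r: float, seed=None, n_segments: int = DEFAULT_SEGMENTS) -> SimulatedSequence:
    """Simulate one count-peak sequence (3-state Poisson mixture)."""
    if r <= 1:
        raise ValueError("r must be > 1 (peak rate r^2 must exceed background)")
    return _simulate("counts", r, seed, n_segments)


def simulate_methylation(
    seed=None,
    n_sites: int = 600,
    n_dmrs: int = 3,
    dmr_sites: int = 40,
    effect: float = 0.35,
    noise_sd: float = 0.05,
) -> tuple[GenomicProfile, pd.DataFrame]:
    """Planted-truth two-track methylation fixture for the DMR workflow.

    Irregularly spaced CpG-like sites carry a methylation-difference track
    (background near 0, planted hyper/hypomethylated regions at +-``effect``)
    and a p-value track (background roughly uniform, small inside DMRs).
    Returns the profile (samples ``meth.diff`` and ``p.val``) and a truth
    frame of the planted regions with a ``direction`` column.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.integers(2, 40, size=n_sites)
    positions = np.cumsum(gaps) + 100
    meth = rng.normal(0.0, noise_sd, n_sites)
    pval = rng.uniform(0.05, 1.0, n_sites)
    block = n_sites // (n_dmrs + 1)
    truth_rows = []
    for k in range(n_dmrs):
        i0 = (k + 1) * block - dmr_sites // 2
        i1 = i0 + dmr_sites - 1
        sign = -1.0 if k == n_dmrs - 1 else 1.0  # last planted region is hypomethylated
        meth[i0 : i1 + 1] = rng.normal(sign * effect, noise_sd, dmr_sites)
        pval[i0 : i1 + 1] = rng.uniform(1e-4, 0.01, dmr_sites)
        truth_rows.append(
            {
                "seqname": "chr1",
                "start": int(positions[i0]),
                "end": int(positions[i1]),
                "direction": "hypo" if sign < 0 else "hyper",
            }
        )
    profile = GenomicProfile(
        seqnames=np.full(n_sites, "chr1"),
        positions=positions,
        values=np.column_stack([meth, pval]),
        samples=["meth.diff", "p.val"],
        groups=["meth", "pval"],
    )
    return profile, pd.DataFrame(truth_rows)
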