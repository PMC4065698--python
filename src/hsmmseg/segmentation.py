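"""Batch segmentation of position-indexed genomic profiles.

Orchestrates the HSMM engine over the rows of a :class:`GenomicProfile`:
each sequence name (chromosome / contig / region) is processed in turn; sample
columns are stratified into groups that are modeled jointly (multivariate
emissions) or iteratively (univariate emissions sharing a learned sojourn
prior).  Decoded state tracks are turned into non-overlapping homogeneous
segments, with optional splitting of runs that span inter-feature gaps larger
than ``max_gap`` — important for irregularly spaced features such as CpG
sites.  The two-track intersection used for differentially methylated region
(DMR) calling lives here as :func:`intersect_extreme`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emission import EmissionModel, init_emission_cluster, init_emission_quantile
from .engine import EMConfig, HSMMSpec, decode_smoothed, em_fit, forward_backward, uniform_offdiag, viterbi
from .sojourn import SojournModel, flat_sojourn, resolve_max_sojourn, rescale_sojourn

__all__ = [
    "GenomicProfile",
    "SegmentConfig",
    "SegmentationResult",
    "segment_profile",
    "auto_group",
    "states_to_segments",
    "compress_runs",
    "expand_runs",
    "intersect_extreme",
]

_MV_FAMILIES = ("mvnorm", "mvt")
_COUNT_FAMILIES = ("pois", "nbinom")

SEGMENT_COLUMNS = ["seqname", "start", "end", "state", "group", "sample", "mean", "n_features"]


@dataclass
class GenomicProfile:
    """Position-indexed multi-sample signal matrix.

    ``seqnames`` and ``positions`` (1-based) index the rows of ``values``
    (T x N for N sample columns).  ``groups`` assigns each sample column to a
    modeling group.  ``weights`` optionally records per-row expansion counts
    (run lengths) for base-resolution count tracks stored run-compressed.
    """

    seqnames: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    samples: list[str] = field(default_factory=list)
    groups: list = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.seqnames = np.asarray(self.seqnames)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.positions.size > 1:
            self.values = self.values.T
        if self.values.shape[0] != self.positions.size:
            raise ValueError("values must have one row per position")
        if not self.samples:
            self.samples = [f"sample{i + 1}" for i in range(self.values.shape[1])]
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("one sample name per value column required")
        if not self.groups:
            self.groups = ["g1"] * len(self.samples)
        for sq in np.unique(self.seqnames):
            pos = self.positions[self.seqnames == sq]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions must be strictly increasing within {sq!r}")

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def seqname_list(self) -> list[str]:
        seen: list[str] = []
        for s in self.seqnames:
            if s not in seen:
                seen.append(s)
        return seen

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, groups=None) -> "GenomicProfile":
        """Build from a data frame with ``seqname``, ``position`` and sample columns."""
        samples = [c for c in frame.columns if c not in ("seqname", "position", "weight")]
        weights = frame["weight"].to_numpy(np.int64) if "weight" in frame else None
        return cls(
            frame["seqname"].to_numpy(),
            frame["position"].to_numpy(np.int64),
            frame[samples].to_numpy(float),
            samples=samples,
            groups=list(groups) if groups is not None else [],
            weights=weights,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"seqname": self.seqnames, "position": self.positions})
        for i, s in enumerate(self.samples):
            out[s] = self.values[:, i]
        if self.weights is not None:
            out["weight"] = self.weights
        return out


@dataclass
class SegmentConfig:
    """Configuration of one batch segmentation run."""

    J: int = 3
    emission_family: str = "norm"
    sojourn_family: str = "gamma"
    prior_mode: str = "quantile"  # flat | quantile | cluster | annotation
    annotation: list | None = None  # (start, end, label) intervals, 1-based closed
    max_k: int | None = None
    max_bp: float | None = None
    max_gap: float | None = None
    decode: str = "smoothed"  # smoothed | viterbi
    em: EMConfig = field(default_factory=EMConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("J must be >= 2 (default 3)")
        if self.prior_mode not in ("flat", "quantile", "cluster", "annotation"):
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")
        if self.decode not in ("smoothed", "viterbi"):
            raise ValueError(f"unknown decode mode {self.decode!r}")


@dataclass
class SegmentationResult:
    """Segments, decoded states and fitted models from one batch run.

    ``segments`` is a data frame with columns ``seqname, start, end, state,
    group, sample, mean, n_features`` (states are 1-based in output:
    state 1 = lowest emission level).  ``states``/``specs``/``logliks`` are
    keyed by ``(seqname, track)`` where ``track`` is the sample name for
    iterative fits and the group name for multivariate fits.
    """

    segments: pd.DataFrame
    states: dict = field(default_factory=dict)
    specs: dict = field(default_factory=dict)
    logliks: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)
    track_values: dict = field(default_factory=dict)


def compress_runs(values) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode an integer vector: ``(run values, run lengths)``."""
    v = np.asarray(values)
    if v.size == 0:
        return v, np.array([], dtype=np.int64)
    change = np.nonzero(np.diff(v) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [v.size])))
    return v[starts], lengths.astype(np.int64)


def expand_runs(values, lengths) -> np.ndarray:
    """Inverse of :func:`compress_runs`."""
    return np.repeat(np.asarray(values), np.asarray(lengths, dtype=np.int64))


def states_to_segments(states, positions, max_gap: float | None = None) -> pd.DataFrame:
    """Turn a decoded state track into homogeneous segments.

    Maximal runs of constant state become segments ``[first position, last
    position]`` (1-based closed); a run is additionally split wherever two
    consecutive features are more than ``max_gap`` apart.
    Returns a frame with ``start, end, state, i0, i1`` (``i0..i1`` inclusive
    row indices into the track).
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    if states.size != positions.size:
        raise ValueError("states and positions must have equal length")
    if states.size == 0:
        return pd.DataFrame(columns=["start", "end", "state", "i0", "i1"])
    brk = np.diff(states) != 0
    if max_gap is not None:
        brk = brk | (np.diff(positions) > max_gap)
    cut = np.nonzero(brk)[0]
    starts = np.concatenate(([0], cut + 1))
    ends = np.concatenate((cut, [states.size - 1]))
    return pd.DataFrame(
        {
            "start": positions[starts],
            "end": positions[ends],
            "state": states[starts],
            "i0": starts,
            "i1": ends,
        }
    )


def auto_group(profile: GenomicProfile, min_silhouette: float = 0.2) -> list:
    """Group sample columns by hierarchical clustering on correlation distance.

    Average-linkage clustering of ``1 - corr`` distances; the tree is cut at
    the number of clusters (2..min(N-1, 8)) that maximizes the mean silhouette
    width, falling back to a single group when the best silhouette is below
    ``min_silhouette``.  Deterministic for fixed input.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    from sklearn.metrics import silhouette_score

    N = profile.N
    if N == 1:
        return ["g1"]
    V = profile.values
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(V, rowvar=False)
    corr = np.nan_to_num(corr, nan=1.0)  # constant columns: treat as identical
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    best_labels, best_score = None, -np.inf
    if N >= 3:
        Z = linkage(squareform(dist, checks=False), method="average")
        for k in range(2, min(N - 1, 8) + 1):
            lab = fcluster(Z, k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(dist, lab, metric="precomputed")
            if score > best_score:
                best_labels, best_score = lab, score
    if best_labels is None or best_score < min_silhouette:
        return ["g1"] * N
    return [f"g{int(k)}" for k in best_labels]


def _expand_rows(pos: np.ndarray, vals: np.ndarray, weights: np.ndarray):
    """Expand run-compressed rows to unit positions (values repeated)."""
    reps = weights.astype(np.int64)
    new_pos = np.concatenate([p + np.arange(w) for p, w in zip(pos, reps)])
    return new_pos, np.repeat(vals, reps, axis=0)


def _init_emission(X: np.ndarray, cfg: SegmentConfig) -> EmissionModel:
    if cfg.prior_mode == "cluster":
        return init_emission_cluster(X, cfg.J, cfg.emission_family, seed=cfg.seed)
    return init_emission_quantile(X, cfg.J, cfg.emission_family)


def _init_sojourn(cfg: SegmentConfig, M: int, positions: np.ndarray) -> SojournModel:
    if cfg.prior_mode == "annotation" and cfg.annotation:
        from .sojourn import sojourn_from_annotation

        gaps = np.diff(positions)
        spacing = float(np.median(gaps)) if gaps.size else 1.0
        return sojourn_from_annotation(
            cfg.annotation, cfg.sojourn_family, cfg.J, M, scale=max(spacing, 1.0)
        )
    return flat_sojourn(cfg.sojourn_family, cfg.J, M)


def _fit_track(X: np.ndarray, positions: np.ndarray, cfg: SegmentConfig, sojourn0=None):
    T = X.shape[0]
    M = resolve_max_sojourn(positions, cfg.max_k, cfg.max_bp)
    emission0 = _init_emission(X, cfg)
    soj = sojourn0 if sojourn0 is not None and sojourn0.M == M else _init_sojourn(cfg, M, positions)
    spec0 = HSMMSpec(cfg.J, np.full(cfg.J, 1.0 / cfg.J), uniform_offdiag(cfg.J), emission0, soj, M)
    res = em_fit(X, spec0, cfg.em)
    if cfg.decode == "viterbi":
        states, _ = viterbi(X, res.spec)
    else:
        states = decode_smoothed(forward_backward(X, res.spec))
    return states, res


def segment_profile(profile: GenomicProfile, config: SegmentConfig | None = None) -> SegmentationResult:
    """Segment every sequence and sample group of a genomic profile.

    For each sequence name and each group: the emission model is initialized
    per ``prior_mode``, the sojourn prior per annotation or flat, the duration
    bound via ``max_k``/``max_bp``; the HSMM is fitted by EM and decoded
    (smoothed posterior by default).  Groups of several columns are modeled
    jointly only for the multivariate emission families; otherwise the columns
    are fitted iteratively, later columns inheriting the sojourn distribution
    fitted on the first.
    """
    cfg = config or SegmentConfig()
    if cfg.emission_family in _COUNT_FAMILIES:
        finite = np.isfinite(profile.values)
        vals = profile.values[finite]
        if np.any(vals != np.rint(vals)) or np.any(vals < 0):
            raise ValueError("count emission families require non-negative integer values")
    result = SegmentationResult(segments=pd.DataFrame(columns=SEGMENT_COLUMNS))
    rows: list[dict] = []
    groups = list(dict.fromkeys(profile.groups))
    for seq in profile.seqname_list():
        sel = profile.seqnames == seq
        pos = profile.positions[sel]
        vals = profile.values[sel]
        if profile.weights is not None:
            pos, vals = _expand_rows(pos, vals, profile.weights[sel])
        if pos.size < cfg.J:
            warnings.warn(f"sequence {seq!r} has fewer than J positions; skipped")
            continue
        result.positions[seq] = pos
        for grp in groups:
            cols = [i for i, g in enumerate(profile.groups) if g == grp]
            names = [profile.samples[i] for i in cols]
            mv = cfg.emission_family in _MV_FAMILIES and len(cols) > 1
            if mv:
                X = vals[:, cols]
                states, res = _fit_track(X, pos, cfg)
                key = (seq, grp)
                result.states[key] = states
                result.specs[key] = res.spec
                result.logliks[key] = res.loglik_trace
                result.track_values[key] = X
                segs = states_to_segments(states, pos, cfg.max_gap)
                for _, s in segs.iterrows():
                    for ci, name in zip(cols, names):
                        seg_vals = vals[int(s.i0) : int(s.i1) + 1, ci]
                        rows.append(
                            _segment_row(seq, s, grp, name, seg_vals)
                        )
            else:
                shared_sojourn = None
                for ci, name in zip(cols, names):
                    X = vals[:, ci]
                    states, res = _fit_track(X, pos, cfg, sojourn0=shared_sojourn)
                    if shared_sojourn is None:
                        shared_sojourn = res.spec.sojourn
                    key = (seq, name)
                    result.states[key] = states
                    result.specs[key] = res.spec
                    result.logliks[key] = res.loglik_trace
                    result.track_values[key] = X
                    segs = states_to_segments(states, pos, cfg.max_gap)
                    for _, s in segs.iterrows():
                        seg_vals = vals[int(s.i0) : int(s.i1) + 1, ci]
                        rows.append(_segment_row(seq, s, grp, name, seg_vals))
    if rows:
        result.segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return result


def _segment_row(seq, s, grp, sample, seg_vals) -> dict:
    return {
        "seqname": seq,
        "start": int(s.start),
        "end": int(s.end),
        "state": int(s.state) + 1,  # 1-based states in output
        "group": grp,
        "sample": sample,
        "mean": float(np.nanmean(seg_vals)) if np.isfinite(seg_vals).any() else np.nan,
        "n_features": int(s.i1 - s.i0 + 1),
    }


def _select_segments(result: SegmentationResult, states: set, track: str | None) -> pd.DataFrame:
    seg = result.segments
    if track is not None:
        seg = seg[seg["sample"] == track]
    return seg[seg["state"].isin(states)].sort_values(["seqname", "start"])


def intersect_extreme(
    result_a: SegmentationResult,
    states_a,
    result_b: SegmentationResult,
    states_b,
    track_a: str | None = None,
    track_b: str | None = None,
) -> pd.DataFrame:
    """Intersect extreme-state segments of two segmentation tracks.

    The DMR workflow: regions where track A (e.g. methylation difference) is
    in one of ``states_a`` (hypo/hyper) *and* track B (e.g. test p-values) is
    in one of ``states_b`` (high-confidence).  Output regions carry the
    average of both tracks over the contained positions.  States are 1-based
    as in ``SegmentationResult.segments``.
    """
    sa = _select_segments(result_a, set(states_a), track_a)
    sb = _select_segments(result_b, set(states_b), track_b)
    out_rows = []
    common = sorted(set(sa["seqname"]).intersection(sb["seqname"]))
    for seq in common:
        a = sa[sa["seqname"] == seq][["start", "end"]].to_numpy()
        b = sb[sb["seqname"] == seq][["start", "end"]].to_numpy()
        i = jx = 0
        while i < len(a) and jx < len(b):
            lo = max(a[i, 0], b[jx, 0])
            hi = min(a[i, 1], b[jx, 1])
            if lo <= hi:
                out_rows.append(
                    {
                        "seqname": seq,
                        "start": int(lo),
                        "end": int(hi),
                        "mean_a": _region_mean(result_a, seq, lo, hi),
                        "mean_b": _region_mean(result_b, seq, lo, hi),
                    }
                )
            if a[i, 1] < b[jx, 1]:
                i += 1
            else:
                jx += 1
    return pd.DataFrame(out_rows, columns=["seqname", "start", "end", "mean_a", "mean_b"])


def _region_mean(result: SegmentationResult, seq, lo, hi) -> float:
    pos = result.positions.get(seq)
    if pos is None:
        return np.nan
    mask = (pos >= lo) & (pos <= hi)
    vals = []
    for (s, _), v in result.track_values.items():
        if s == seq:
            v = np.atleast_2d(np.asarray(v, dtype=float).T).T
            vals.append(v[mask].ravel())
    if not vals:
        return np.nan
    allv = np.concatenate(vals)
    return float(np.nanmean(allv)) if np.isfinite(allv).any() else np.nan
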