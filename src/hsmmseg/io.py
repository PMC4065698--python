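"""Readers and writers for position-indexed signal tracks and segments.

Coordinate conventions: the in-memory representation is 1-based closed
(``position`` is the 1-based coordinate of a feature; segments are
``[start, end]`` inclusive).  BED and bedGraph files are 0-based half-open
and are converted at the boundary; GFF3 is 1-based closed.  Wide bedGraph
intervals are represented by their start position with the interval length
recorded as a per-row weight, so base-resolution count tracks stay compact
(run-length encoded) until the engine expands them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import GenomicProfile

__all__ = ["read_profile", "write_profile", "write_segments", "read_segments"]

_FORMATS = ("bedgraph", "bed", "tsv")


def _infer_format(path: str) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("bedgraph", "bg"):
        return "bedgraph"
    if suffix == "bed":
        return "bed"
    return "tsv"


def read_profile(path, fmt: str | None = None) -> GenomicProfile:
    """Read a signal track into a :class:`GenomicProfile`.

    ``bedgraph``: whitespace-delimited ``chrom start end value...`` (0-based
    half-open, no header); unit intervals become single positions, wider
    intervals keep a weight equal to their length.  ``bed``: BED5, the score
    column is the value.  ``tsv``: tab-separated with a header line naming
    ``seqname``, ``position`` (1-based) and one column per sample; empty
    cells are missing values (NaN), never zero.
    """
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        required = {"seqname", "position"}
        if not required.issubset(frame.columns):
            raise ValueError("tsv input needs 'seqname' and 'position' columns")
        samples = [c for c in frame.columns if c not in ("seqname", "position")]
        frame = _sorted_unique(frame, path)
        return GenomicProfile(
            frame["seqname"].to_numpy(),
            frame["position"].to_numpy(np.int64),
            frame[samples].to_numpy(float),
            samples=samples,
        )
    names = ["seqname", "start", "end"]
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if raw.shape[1] < 4:
        raise ValueError(f"{path}: expected at least 4 columns, found {raw.shape[1]}")
    if fmt == "bed":
        if raw.shape[1] < 5:
            raise ValueError(f"{path}: BED input needs a score column (5 columns)")
        frame = raw.iloc[:, [0, 1, 2, 4]].copy()
        frame.columns = names + ["value"]
        value_cols = ["value"]
    else:
        value_cols = [f"value{i}" if raw.shape[1] > 4 else "value" for i in range(raw.shape[1] - 3)]
        frame = raw.copy()
        frame.columns = names + value_cols
    for c in ("start", "end"):
        if not np.issubdtype(frame[c].dtype, np.number):
            bad = frame[~frame[c].astype(str).str.fullmatch(r"-?\d+")].index
            line = int(bad[0]) + 1 if len(bad) else 1
            raise ValueError(f"{path}: malformed coordinate on line {line}")
    widths = (frame["end"] - frame["start"]).to_numpy(np.int64)
    if np.any(widths < 1):
        line = int(np.nonzero(widths < 1)[0][0]) + 1
        raise ValueError(f"{path}: empty interval on line {line}")
    frame = frame.assign(position=frame["start"].astype(np.int64) + 1, weight=widths)
    frame = _sorted_unique(frame[["seqname", "position"] + value_cols + ["weight"]], path)
    weights = frame["weight"].to_numpy(np.int64)
    return GenomicProfile(
        frame["seqname"].to_numpy(),
        frame["position"].to_numpy(np.int64),
        frame[value_cols].to_numpy(float),
        samples=value_cols,
        weights=None if np.all(weights == 1) else weights,
    )


def _sorted_unique(frame: pd.DataFrame, path) -> pd.DataFrame:
    if frame.duplicated(["seqname", "position"]).any():
        raise ValueError(f"{path}: duplicate positions")
    ordered = frame.sort_values(["seqname", "position"], kind="stable").reset_index(drop=True)
    if not ordered[["seqname", "position"]].equals(
        frame[["seqname", "position"]].reset_index(drop=True)
    ):
        warnings.warn(f"{path}: input was not sorted; sorting by (seqname, position)")
    return ordered


def write_profile(profile: GenomicProfile, path, fmt: str = "bedgraph") -> None:
    """Write a profile back to disk (bedGraph for single-sample, tsv otherwise)."""
    if fmt == "tsv":
        profile.to_dataframe().to_csv(path, sep="\t", index=False)
        return
    if profile.N != 1 and fmt == "bed":
        raise ValueError("bed output supports a single sample column")
    w = profile.weights if profile.weights is not None else np.ones(profile.positions.size, np.int64)
    frame = pd.DataFrame(
        {
            "seqname": profile.seqnames,
            "start": profile.positions - 1,
            "end": profile.positions - 1 + w,
        }
    )
    for i in range(profile.N):
        frame[f"v{i}"] = profile.values[:, i]
    frame.to_csv(path, sep="\t", index=False, header=False)


def write_segments(segments: pd.DataFrame, path, fmt: str = "bed") -> None:
    """Write segments as BED (0-based half-open) or GFF3 (1-based closed).

    BED rows are ``chrom, start-1, end, state<k>, mean``; GFF3 attributes
    carry state, mean and feature count.  Rows are ordered deterministically
    by (seqname, start, sample).
    """
    seg = segments.sort_values(["seqname", "start", "sample"], kind="stable")
    if fmt == "bed":
        out = pd.DataFrame(
            {
                "seqname": seg["seqname"],
                "start": seg["start"].astype(np.int64) - 1,
                "end": seg["end"].astype(np.int64),
                "name": "state" + seg["state"].astype(int).astype(str),
                "score": seg["mean"].map(lambda v: f"{v:.6g}"),
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, s in seg.iterrows():
                attrs = (
                    f"state={int(s.state)};mean={s['mean']:.6g};"
                    f"n_features={int(s.n_features)};sample={s['sample']}"
                )
                fh.write(
                    f"{s.seqname}\thsmmseg\tsegment\t{int(s.start)}\t{int(s.end)}\t"
                    f"{s['mean']:.6g}\t.\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown segment format {fmt!r}")


def read_segments(path, fmt: str = "bed") -> pd.DataFrame:
    """Read segments written by :func:`write_segments` (coordinate round-trip)."""
    if fmt == "bed":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["seqname", "start", "end", "name", "score"]
        )
        return pd.DataFrame(
            {
                "seqname": frame["seqname"],
                "start": frame["start"].astype(np.int64) + 1,
                "end": frame["end"].astype(np.int64),
                "state": frame["name"].str.removeprefix("state").astype(int),
                "mean": frame["score"].astype(float),
            }
        )
    if fmt == "gff3":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                rows.append(
                    {
                        "seqname": f[0],
                        "start": int(f[3]),
                        "end": int(f[4]),
                        "state": int(attrs["state"]),
                        "mean": float(attrs["mean"]),
                        "n_features": int(attrs.get("n_features", 0)),
                        "sample": attrs.get("sample", ""),
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown segment format {fmt!r}")
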