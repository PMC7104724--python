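"""From raw per-base depth to clean binned coverage tracks.

Pipeline (in order): read a samtools-depth style table into a dense depth
vector -> moving median filter (window 100 nt, stride 100 nt by default,
which both denoises and bins) -> remove the top 1% highest bins (blanked,
then filled with 0, for conserved-region peak noise in metagenomic data)
-> map bin indices to circle angles.

Windows do not wrap across the origin; a tail bin shorter than the window
takes the median of the positions available.  The top-percent filter counts
bins of the binned track.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model import CoverageTrack


class RawDepth:
    """Dense per-base depth of one sample on one reference sequence."""

    def __init__(self, depths, reference: str = "ref", sample_id: str = "sample"):
        self.depths = np.asarray(depths)
        self.reference = reference
        self.sample_id = sample_id

    @property
    def length(self) -> int:
        return int(self.depths.size)


def read_depth(path, reference: str | None = None, length: int | None = None,
               sample_id: str | None = None) -> RawDepth:
    """Read a 3-column (ref, pos, depth) or 2-column (pos, depth) depth table.

    Positions are 1-based; absent positions get depth 0.  ``length`` defaults
    to the largest position seen.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        import warnings

        warnings.warn(f"{path}: no depth records; returning an all-zero track")
        return RawDepth(np.zeros(length or 0, dtype=np.int64),
                        reference or "ref", sample_id or str(path))
    if df.shape[1] >= 3:
        if reference is not None:
            df = df[df.iloc[:, 0] == reference]
        pos, depth = df.iloc[:, 1], df.iloc[:, 2]
    elif df.shape[1] == 2:
        pos, depth = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError(f"{path}: expected 2 or 3 tab-separated columns")
    pos = pd.to_numeric(pos, errors="raise")
    depth = pd.to_numeric(depth, errors="raise")
    if not np.allclose(depth, np.round(depth)):
        raise ValueError(f"{path}: depths must be integers")
    depth = depth.astype(np.int64)
    if len(pos) == 0:
        import warnings

        warnings.warn(f"{path}: no depth records; returning an all-zero track")
        return RawDepth(np.zeros(length or 0, dtype=np.int64),
                        reference or "ref", sample_id or str(path))
    if np.any(pos < 1):
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    n = int(pos.max()) if length is None else int(length)
    if pos.max() > n:
        raise ValueError(
            f"{path}: position {int(pos.max())} exceeds declared length {n}"
        )
    dense = np.zeros(n, dtype=np.int64)
    dense[np.asarray(pos, dtype=np.int64) - 1] = np.asarray(depth)
    return RawDepth(dense, reference or "ref", sample_id or str(path))


def write_depth(path, depths, reference: str = "ref") -> None:
    """Write a dense depth vector in the 3-column samtools-depth dialect."""
    depths = np.asarray(depths)
    pd.DataFrame({
        "ref": reference,
        "pos": np.arange(1, depths.size + 1),
        "depth": depths,
    }).to_csv(path, sep="\t", header=False, index=False)


def moving_median(depths, window: int = 100, stride: int = 100) -> np.ndarray:
    """Moving median filter; with stride == window it also bins the track.

    Bin j covers positions [j*stride, j*stride + window); the median of an
    even count is the mean of the middle pair.  The tail bin may be short.
    """
    depths = np.asarray(depths, dtype=float)
    n = depths.size
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    n_bins = math.ceil(n / stride)
    if stride == window and n % window == 0:
        return np.median(depths.reshape(n_bins, window), axis=1)
    out = np.empty(n_bins)
    for j in range(n_bins):
        start = j * stride
        out[j] = np.median(depths[start:start + window])
    return out


def remove_top_percent(binned, percent: float = 1.0):
    """Blank (set to 0) the ceil(percent% of bins) highest bins.

    Returns (filtered, n_removed).  Ties at the cutoff are broken by taking
    the highest-ranked bins first, so exactly ceil(percent/100 * n) bins are
    zeroed for percent > 0.
    """
    binned = np.asarray(binned, dtype=float)
    if not 0 <= percent < 100:
        raise ValueError(f"percent must lie in [0, 100), got {percent}")
    if percent == 0:
        return binned.copy(), 0
    k = math.ceil(percent / 100.0 * binned.size)
    idx = np.argsort(binned, kind="stable")[::-1][:k]
    out = binned.copy()
    out[idx] = 0.0
    return out, int(k)


def make_track(raw: RawDepth, window: int = 100, stride: int = 100,
               top_percent: float = 1.0, sample_id: str | None = None) -> CoverageTrack:
    """Full preprocessing pipeline: median-bin, outlier-blank, zero-fill.

    The returned track records every step in its metadata; its depths are
    rounded to integers (half-integer medians from even windows round to
    nearest even).
    """
    binned = moving_median(raw.depths, window, stride)
    filtered, n_removed = remove_top_percent(binned, top_percent)
    depths = np.rint(filtered).astype(np.int64)
    return CoverageTrack(
        depths=depths,
        sample_id=sample_id or raw.sample_id,
        metadata={
            "reference": raw.reference,
            "raw_length": raw.length,
            "window": window,
            "stride": stride,
            "top_percent": top_percent,
            "bins_blanked": n_removed,
        },
    )
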