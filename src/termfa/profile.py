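"""MFA profiles: control normalization and loess smoothing.

A marker-frequency profile is the per-window log2 ratio of a log-phase (or
spectinomycin run-off) sample to a stationary-phase control, scaled by
library size so that sequencing depth cancels, then smoothed with a loess
curve (local linear regression, tricube weights, span 0.1 by default).  In a
non-replicating stationary control every locus is at one copy, so the ratio
reads out relative copy number along the chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack

DEFAULT_SPAN = 0.1
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class MfaProfile:
    """Per-window log2 normalized ratio and its loess-smoothed curve."""

    window_centers: np.ndarray
    log2_ratio: np.ndarray
    loess: np.ndarray
    span: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.window_centers)
        if not (len(self.log2_ratio) == len(self.loess) == n):
            raise ValueError("profile arrays must have equal length")
        if not 0 < self.span <= 1:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if not np.all(np.isfinite(self.loess)):
            raise ValueError("loess curve contains non-finite values")


def normalize_to_control(
    sample: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Library-size-scaled per-window log2 ratio of sample to control.

    ``r[i] = log2( (s[i]+q) / S_total * C_total / (c[i]+q) )`` where the
    totals are raw filtered read counts and ``q`` is a pseudocount guarding
    zero-count windows.  A sample normalized against itself gives exactly
    zero everywhere, and multiplying all sample counts by a constant leaves
    the ratios unchanged up to the pseudocount.
    """
    if not sample.same_grid(control):
        raise ValueError("sample and control tracks are on different grids")
    if control.condition != "stationary_control":
        raise ValueError(
            f"control track must have condition 'stationary_control', got {control.condition!r}"
        )
    s = sample.counts.astype(float) + pseudocount
    c = control.counts.astype(float) + pseudocount
    s_total = float(sample.counts.sum())
    c_total = float(control.counts.sum())
    with np.errstate(divide="ignore"):
        return np.log2(s / s_total) - np.log2(c / c_total)


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = DEFAULT_SPAN,
    period: float | None = None,
) -> np.ndarray:
    """Loess (local linear, tricube-weighted) smoothing evaluated at ``x``.

    For each point the ``ceil(span * n)`` nearest neighbours (contiguous in
    sorted x) are fit by weighted least squares with tricube weights
    ``(1 - (d/d_max)^3)^3`` and the fit is evaluated at the point.  No
    robustness iterations are performed.

    ``period`` activates circular handling for genome coordinates: half a
    span of data is wrapped from each end (shifted by ∓period) before
    fitting and the result cropped, so the curve is continuous across the
    origin of a circular chromosome.

    ``x`` must be strictly increasing; raises if fewer than 10 points or if
    the span covers fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 10:
        raise ValueError(f"need at least 10 points to smooth, got {n}")
    if span * n < 3:
        raise ValueError(f"span {span} covers fewer than 3 of {n} points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    if period is not None:
        m = math.ceil(span * n / 2)
        m = min(m, n)
        x_pad = np.concatenate([x[-m:] - period, x, x[:m] + period])
        y_pad = np.concatenate([y[-m:], y, y[:m]])
        return _loess_linear(x_pad, y_pad, span * n / len(x_pad))[m : m + n]
    return _loess_linear(x, y, span)


def _loess_linear(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    n = len(x)
    k = min(max(math.ceil(span * n), 3), n)

    # Contiguous k-nearest-neighbour window start for each point (two-pointer).
    lo = np.empty(n, dtype=np.int64)
    j = 0
    for i in range(n):
        while j + k < n and x[i] - x[j] > x[j + k] - x[i]:
            j += 1
        lo[i] = j

    out = np.empty(n)
    offsets = np.arange(k)
    chunk = max(1, 2_000_000 // k)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        idx = lo[start:stop, None] + offsets[None, :]
        xi = x[start:stop, None]
        dx = x[idx] - xi
        yi = y[idx]
        d_max = np.abs(dx)[:, [0, -1]].max(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.abs(dx) / d_max
        u[~np.isfinite(u)] = 0.0
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        s0 = w.sum(axis=1)
        s1 = (w * dx).sum(axis=1)
        s2 = (w * dx * dx).sum(axis=1)
        sy = (w * yi).sum(axis=1)
        sxy = (w * dx * yi).sum(axis=1)
        denom = s0 * s2 - s1 * s1
        scale = np.maximum(s0 * s2, 1e-300)
        safe = denom > 1e-12 * scale
        fit = np.where(safe, (s2 * sy - s1 * sxy) / np.where(safe, denom, 1.0), sy / s0)
        out[start:stop] = fit
    return out


def assemble_profile(
    sample: CoverageTrack,
    control: CoverageTrack,
    span: float = DEFAULT_SPAN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    circular: bool = True,
) -> MfaProfile:
    """Normalize a sample against the stationary control and smooth it."""
    ratio = normalize_to_control(sample, control, pseudocount=pseudocount)
    centers = sample.centers
    period = float(sample.length) if circular else None
    smoothed = loess_smooth(centers, ratio, span=span, period=period)
    return MfaProfile(
        window_centers=centers,
        log2_ratio=ratio,
        loess=smoothed,
        span=span,
        sample_id=sample.sample_id,
    )


def write_profile_tsv(profile: MfaProfile, path) -> None:
    """Write the profile as TSV: center, log2_ratio, loess."""
    with open(path, "w") as fh:
        fh.write("center\tlog2_ratio\tloess\n")
        for c, r, s in zip(profile.window_centers, profile.log2_ratio, profile.loess):
            fh.write(f"{c:.1f}\t{r:.6f}\t{s:.6f}\n")


def write_profile_bedgraph(profile: MfaProfile, path, chrom_name: str = "chromosome") -> None:
    """Write the raw log2 ratios as bedGraph intervals around window centers."""
    centers = profile.window_centers
    edges = np.empty(len(centers) + 1)
    edges[1:-1] = (centers[:-1] + centers[1:]) / 2
    edges[0] = max(0.0, centers[0] - (edges[1] - centers[0]))
    edges[-1] = centers[-1] + (centers[-1] - edges[-2])
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.sample_id or "log2_ratio"}"\n')
        for lo, hi, r in zip(edges[:-1], edges[1:], profile.log2_ratio):
            fh.write(f"{chrom_name}\t{int(lo)}\t{int(hi)}\t{r:.6f}\n")
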