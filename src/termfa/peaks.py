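"""Ter-peak statistics on MFA profiles.

Quantifies terminus over-replication: the peak height (highest loess value
inside the candidate Ter interval minus the lowest value on the clockwise
flank), the spectinomycin peak-increase statistic (height after run-off
minus height before), marker-locus copy ratios (the sequencing analog of
qPCR readouts such as ydcM/lepA), the amplification-block fold, and a
flatness verdict for tus-deleted profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .genome import ChromosomeMap, Locus, innermost_ter_pair
from .profile import MfaProfile

DEFAULT_FLANK_WIDTH = 200


@dataclass(frozen=True)
class PeakRegion:
    """Candidate over-replicated interval (bp) and clockwise flank width (windows)."""

    left: int
    right: int
    flank_width: int = DEFAULT_FLANK_WIDTH

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError(f"region left {self.left} must be < right {self.right}")
        if self.flank_width < 1:
            raise ValueError("flank_width must be >= 1")


def region_from_map(chrom: ChromosomeMap, flank_width: int = DEFAULT_FLANK_WIDTH) -> PeakRegion:
    """The innermost Ter trap interval as the default peak region."""
    left, right = innermost_ter_pair(chrom)
    span = chrom.cw_distance(left.position, right.position)
    return PeakRegion(left.position, left.position + span, flank_width=flank_width)


def _region_windows(profile: MfaProfile, region: PeakRegion) -> np.ndarray:
    centers = profile.window_centers
    idx = np.nonzero((centers >= region.left) & (centers < region.right))[0]
    if idx.size == 0:
        raise ValueError(f"region [{region.left}, {region.right}) contains no windows")
    return idx


def peak_height(profile: MfaProfile, region: PeakRegion) -> float:
    """Highest loess value in the region minus the lowest on its clockwise flank.

    The flank is the ``flank_width`` windows immediately clockwise of the
    region's right boundary (wrapping around the chromosome origin).  The
    statistic is invariant to adding a constant to the whole curve.
    """
    idx = _region_windows(profile, region)
    n = len(profile.loess)
    flank = (idx[-1] + 1 + np.arange(region.flank_width)) % n
    return float(profile.loess[idx].max() - profile.loess[flank].min())


def ter_peak_increase(
    profile_pre: MfaProfile, profile_post: MfaProfile, region: PeakRegion
) -> float:
    """Peak-height change across the spectinomycin run-off: post minus pre.

    Positive values mean the Ter interval kept accumulating DNA after oriC
    initiations stopped, i.e. R-loop-dependent synthesis continued there.
    """
    if len(profile_pre.loess) != len(profile_post.loess) or not np.array_equal(
        profile_pre.window_centers, profile_post.window_centers
    ):
        raise ValueError("pre and post profiles are on different grids")
    return peak_height(profile_post, region) - peak_height(profile_pre, region)


def _locus_windows(bounds: np.ndarray, n: int, locus: Locus, w: int) -> np.ndarray:
    center = int(np.searchsorted(bounds, locus.position, side="right") - 1)
    if not 0 <= center < n:
        raise ValueError(f"locus {locus.name!r} at {locus.position} outside the grid")
    return (center + np.arange(-w, w + 1)) % n


def marker_ratio(
    data: CoverageTrack | MfaProfile,
    locusA: Locus,
    locusB: Locus,
    w: int = 1,
    pseudocount: float = 0.0,
) -> float:
    """Relative copy number of locus A over locus B.

    On a :class:`CoverageTrack` this is the ratio of mean raw counts over the
    ``2w + 1`` windows centred on each locus — the direct analog of a
    2^-ΔCt qPCR ratio on genomic DNA.  On an :class:`MfaProfile` the means
    are taken over ``2^loess``, the smoothed copy-number estimate.
    """
    if isinstance(data, CoverageTrack):
        bounds, n = data.bounds, data.grid_n
        values = data.counts.astype(float)
    else:
        centers = data.window_centers
        n = len(centers)
        half = np.diff(centers).mean() / 2.0
        bounds = np.concatenate([centers - half, [centers[-1] + half]])
        values = np.exp2(data.loess)
    a = values[_locus_windows(bounds, n, locusA, w)].mean()
    b = values[_locus_windows(bounds, n, locusB, w)].mean()
    if b + pseudocount == 0:
        raise ZeroDivisionError(
            f"no signal at reference locus {locusB.name!r}; supply a pseudocount"
        )
    return float((a + pseudocount) / (b + pseudocount))


def region_copy_ratio(
    track: CoverageTrack,
    region: tuple[int, int],
    reference_locus: Locus,
    w: int = 1,
    pseudocount: float = 0.0,
) -> float:
    """Mean count in a bp region over the mean count at a reference locus.

    The sequencing analog of the qPCR amplification estimate (e.g.
    qseC/lepA for the parC parE block): recovers the amplification fold
    when the region and reference sit at comparable replication distance.
    """
    a, b = region
    starts = track.bounds[:-1]
    idx = np.nonzero((starts >= a) & (starts < b))[0]
    if idx.size == 0:
        raise ValueError(f"region [{a}, {b}) contains no windows")
    region_mean = track.counts[idx].astype(float).mean()
    ref = track.counts[_locus_windows(track.bounds, track.grid_n, reference_locus, w)]
    ref_mean = ref.astype(float).mean()
    if ref_mean + pseudocount == 0:
        raise ZeroDivisionError("no signal at reference locus; supply a pseudocount")
    return float((region_mean + pseudocount) / (ref_mean + pseudocount))


def flatness_test(
    profile: MfaProfile,
    region: PeakRegion,
    threshold: float | None = None,
    control: MfaProfile | None = None,
) -> tuple[bool, float]:
    """Is the profile flat over the candidate region?

    The score is :func:`peak_height`.  The profile is called flat when the
    score falls below the threshold; by default the threshold is three times
    the loess standard deviation of a supplied control profile, or, absent a
    control, three times a robust (MAD-based) SD of this profile's own loess
    curve, which a genuine peak inflates only weakly.
    """
    score = peak_height(profile, region)
    if threshold is None:
        if control is not None:
            threshold = 3.0 * float(np.std(control.loess))
        else:
            mad = float(np.median(np.abs(profile.loess - np.median(profile.loess))))
            threshold = 3.0 * 1.4826 * mad
    return score < threshold, score
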