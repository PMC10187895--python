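"""qPCR relative quantification: 2^-ΔCt ratios and the adjusted topo IV activity.

The copy ratio of a target locus to a reference locus on the same genomic
DNA is ``2^{-(Ct_target - Ct_reference)}``: one threshold-cycle difference
corresponds to one doubling, assuming 100% amplification efficiency.
Replicate ratios are summarized by their arithmetic mean and sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class CtMeasurement:
    """One target/reference threshold-cycle pair from a single replicate."""

    target: str
    reference: str
    ct_target: float
    ct_reference: float
    replicate: str = "1"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")

    @property
    def ratio(self) -> float:
        return ddct_ratio(self.ct_target, self.ct_reference)


def ddct_ratio(ct_target: float, ct_reference: float) -> float:
    """Fold ratio ``2^{-(Ct_target - Ct_reference)}``."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


@dataclass(frozen=True)
class RatioSummary:
    mean: float
    sd: float
    n: int
    sd_defined: bool


def aggregate_ratios(measurements: Sequence[CtMeasurement]) -> RatioSummary:
    """Mean and sample SD of per-replicate 2^-ΔCt ratios.

    Ratios are computed per replicate first, then averaged — the SD
    describes the spread of the fold values themselves.  With a single
    replicate the SD is reported as 0 with ``sd_defined=False``.
    """
    if not measurements:
        raise ValueError("need at least one Ct measurement")
    ratios = [m.ratio for m in measurements]
    n = len(ratios)
    mean = sum(ratios) / n
    if n < 2:
        return RatioSummary(mean=mean, sd=0.0, n=n, sd_defined=False)
    var = sum((r - mean) ** 2 for r in ratios) / (n - 1)
    return RatioSummary(mean=mean, sd=math.sqrt(var), n=n, sd_defined=True)


def adjusted_activity(
    baseline_fold: float, raw_fold: float, k: float | tuple[float, float] = (5.0, 10.0)
) -> float | tuple[float, float]:
    """Topoisomerase-activity fold corrected for a less-active fusion enzyme.

    When overexpression is achieved through a fusion protein that is ``k``
    times less active than the native enzyme, the effective activity is the
    baseline plus the overexpressed excess scaled down:
    ``baseline + (raw - baseline) / k``.  ``k`` may be a single divisor or a
    ``(k_min, k_max)`` range (default 5-10 fold), in which case the interval
    endpoints ``(value at k_max, value at k_min)`` are returned.
    """
    if raw_fold < baseline_fold or baseline_fold < 0:
        raise ValueError(
            f"need raw_fold >= baseline_fold >= 0, got baseline {baseline_fold}, raw {raw_fold}"
        )
    if isinstance(k, tuple):
        k_min, k_max = k
        return (
            adjusted_activity(baseline_fold, raw_fold, k_max),
            adjusted_activity(baseline_fold, raw_fold, k_min),
        )
    if not 5.0 <= k <= 10.0:
        import warnings

        warnings.warn(f"activity divisor k={k} outside the reported 5-10x range", stacklevel=2)
    if k <= 0:
        raise ValueError("k must be > 0")
    return baseline_fold + (raw_fold - baseline_fold) / k


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

CT_COLUMNS = ["sample_id", "target", "reference", "ct_target", "ct_reference", "replicate"]


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read Ct measurements from TSV with columns sample_id, target,
    reference, ct_target, ct_reference, replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CtMeasurement(
            target=row.target,
            reference=row.reference,
            ct_target=float(row.ct_target),
            ct_reference=float(row.ct_reference),
            replicate=str(row.replicate),
            sample_id=str(row.sample_id),
        )
        for row in df.itertuples()
    ]


def summarize_ct_table(measurements: Iterable[CtMeasurement]) -> pd.DataFrame:
    """Per-(sample, target/reference pair) ratio summary table."""
    rows = []
    groups: dict[tuple[str, str, str], list[CtMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.sample_id, m.target, m.reference), []).append(m)
    for (sample_id, target, reference), ms in groups.items():
        summary = aggregate_ratios(ms)
        rows.append(
            {
                "sample_id": sample_id,
                "pair": f"{target}/{reference}",
                "mean_ratio": summary.mean,
                "sd": summary.sd,
                "n": summary.n,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "pair", "mean_ratio", "sd", "n"])
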