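"""Synthetic bacterial replication profiles.

Generates expected relative copy-number profiles and Poisson-sampled window
counts for a circular chromosome, emulating the experimental contrasts seen
in marker-frequency analysis of topoisomerase mutants:

* an exponential-culture oriC gradient — copy number ``2^{C/tau * (1 - m(x))}``
  where ``m(x)`` is the fraction of the replication period elapsed when
  position ``x`` is replicated by a fork travelling from oriC (fork paths
  respect Ter polarity);
* R-loop-dependent replication (RLDR) from weak origins distributed
  uniformly around the genome, firing stochastically per cell; each event
  launches two forks whose run lengths are exponential unless arrested by
  the first polar Ter/Tus barrier in blocking orientation;
* terminus over-replication: a Tus-trapped fork can trigger a re-replication
  burst that duplicates the innermost trapped interval (the TerA–TerB
  analog) a geometric number of times;
* spectinomycin run-off: oriC initiations stop (the gradient flattens to 1)
  while RLDR continues;
* chromosomal inversions that relocate barriers and flip their polarity,
  and a multiplicative gene-amplification block (the parC parE analog).

Window counts are Poisson around ``depth * expected copy number``,
independent across windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .coverage import CoverageTrack, build_grid
from .genome import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    ChromosomeMap,
    Locus,
    TerSite,
    apply_inversion,
    build_map,
    innermost_ter_pair,
)

SCENARIOS = ("wild_type", "topA", "topA_topB", "topA_topB_tus", "topA_topB_inv")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative knobs for one simulated sample.

    Parameters
    ----------
    c_over_tau
        Replication-period / doubling-time ratio; sets the oriC-to-terminus
        copy gradient (ori/ter = ``2^{C/tau}`` in an exponential culture).
    rldr_rate
        Expected RLDR initiation events per cell (Poisson).
    rldr_run_mean
        Mean unidirectional fork run length in bp when no barrier arrests it.
    rereplication_prob
        Probability that a Tus-trapped event triggers a re-replication burst.
    rereplication_gain
        Mean number of extra copies of the innermost trapped interval per
        burst (geometric, support >= 1); 0 disables bursts.
    spc
        Spectinomycin run-off mode: oriC gradient flattened, RLDR active.
    tus
        When False no Ter site arrests forks (tus deletion).
    inversion
        Optional ``(a, b)`` bp segment inverted before simulating.
    amplification
        Optional ``((start, end), fold)`` multiplicative copy-gain block.
    n_cells
        Cells in the Monte-Carlo average of the RLDR component.
    depth
        Mean reads per window in a flat (control-like) sample.
    seed
        RNG seed; full determinism of profiles and counts.
    """

    c_over_tau: float = 1.0
    rldr_rate: float = 0.0
    rldr_run_mean: float = 1_000_000.0
    rereplication_prob: float = 0.5
    rereplication_gain: float = 3.0
    spc: bool = False
    tus: bool = True
    inversion: tuple[int, int] | None = None
    amplification: tuple[tuple[int, int], float] | None = None
    n_cells: int = 2000
    depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c_over_tau, self.rldr_rate, self.rldr_run_mean, self.rereplication_gain) < 0:
            raise ValueError("rates and means must be >= 0")
        if not 0.0 <= self.rereplication_prob <= 1.0:
            raise ValueError("rereplication_prob must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def spc_variant(self, runoff_factor: float = 2.0, seed: int | None = None) -> "SimulationConfig":
        """The paired spectinomycin run-off sample for this condition.

        During the run-off incubation oriC forks finish (no new initiations)
        while R-loop-initiated forks keep firing, so RLDR events accumulate
        relative to the log-phase snapshot; the extra incubation is absorbed
        into the initiation rate as a multiplicative factor.
        """
        return replace(
            self,
            spc=True,
            rldr_rate=self.rldr_rate * runoff_factor,
            seed=self.seed if seed is None else seed,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "c_over_tau": self.c_over_tau,
            "rldr_rate": self.rldr_rate,
            "rldr_run_mean": self.rldr_run_mean,
            "rereplication_prob": self.rereplication_prob,
            "rereplication_gain": self.rereplication_gain,
            "spc": self.spc,
            "tus": self.tus,
            "n_cells": self.n_cells,
            "depth": self.depth,
            "seed": self.seed,
        }
        if self.inversion is not None:
            d["inversion"] = list(self.inversion)
        if self.amplification is not None:
            (a, b), fold = self.amplification
            d["amplification"] = {"region": [a, b], "fold": fold}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "inversion" in d and d["inversion"] is not None:
            d["inversion"] = tuple(d["inversion"])
        if "amplification" in d and d["amplification"] is not None:
            amp = d["amplification"]
            d["amplification"] = ((amp["region"][0], amp["region"][1]), amp["fold"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ReplicationEvent:
    """One RLDR initiation: origin, fork extents, trapping and burst size.

    ``left_end``/``right_end`` are unwrapped coordinates (``left_end`` may be
    negative, ``right_end`` may exceed the chromosome length); the replicated
    interval always contains the origin and spans at most one full circle.
    """

    origin: int
    left_end: float
    right_end: float
    trapped_left: TerSite | None = None
    trapped_right: TerSite | None = None
    extra_copies: int = 0

    def __post_init__(self) -> None:
        if not self.left_end <= self.origin <= self.right_end:
            raise ValueError("replicated interval must contain the origin")
        if self.extra_copies < 0:
            raise ValueError("extra_copies must be >= 0")


# ---------------------------------------------------------------------------
# Canonical synthetic chromosome
# ---------------------------------------------------------------------------

def default_map() -> ChromosomeMap:
    """A synthetic E. coli K-12-like chromosome for simulations.

    4.64 Mb circle with oriC at 3.92 Mb, strong innermost barriers TerA
    (1.34 Mb, arrests counterclockwise forks) and TerB (1.68 Mb, arrests
    clockwise forks), the weaker TerG (2.40 Mb, clockwise, efficiency 0.5),
    and the marker loci used for copy-ratio readouts: ydcM inside the Ter
    trap, lepA outside it, qseC inside the 2.99-3.24 Mb amplification block.
    Coordinates are representative, not genome-accurate.
    """
    return build_map(
        length=4_640_000,
        oriC=3_920_000,
        ter_sites=[
            TerSite("TerA", 1_340_000, COUNTERCLOCKWISE, 1.0),
            TerSite("TerB", 1_680_000, CLOCKWISE, 1.0),
            TerSite("TerG", 2_400_000, CLOCKWISE, 0.5),
        ],
        loci=[
            Locus("ydcM", 1_510_000),
            Locus("lepA", 2_700_000),
            Locus("qseC", 3_100_000),
        ],
        dif=1_590_000,
    )


AMP_REGION = (2_990_000, 3_240_000)


def make_scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Preset configurations for the strain classes the method contrasts.

    ``wild_type``: oriC replication only.  ``topA``: RLDR active with modest
    terminus re-replication and a 1.3-fold parC-parE-like amplification.
    ``topA_topB``: same RLDR level but strong re-replication bursts and a
    4.9-fold amplification.  ``topA_topB_tus``: the same cell with no Tus
    barriers.  ``topA_topB_inv``: the same cell with the 1.52-1.84 Mb
    segment (containing TerB) inverted.
    """
    base = dict(c_over_tau=1.0, n_cells=2000, depth=100.0, seed=seed)
    if name == "wild_type":
        return SimulationConfig(rldr_rate=0.0, **base)
    if name == "topA":
        return SimulationConfig(
            rldr_rate=2.0,
            rereplication_prob=0.8,
            rereplication_gain=2.0,
            amplification=(AMP_REGION, 1.3),
            **base,
        )
    if name == "topA_topB":
        return SimulationConfig(
            rldr_rate=2.0,
            rereplication_prob=0.8,
            rereplication_gain=8.0,
            amplification=(AMP_REGION, 4.9),
            **base,
        )
    if name == "topA_topB_tus":
        return replace(make_scenario("topA_topB", seed=seed), tus=False)
    if name == "topA_topB_inv":
        return replace(make_scenario("topA_topB", seed=seed), inversion=(1_520_000, 1_840_000))
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def effective_map(config: SimulationConfig, chrom: ChromosomeMap) -> ChromosomeMap:
    """The chromosome as the simulated strain carries it (inversion applied)."""
    if config.inversion is not None:
        chrom = apply_inversion(chrom, *config.inversion)
    return chrom


# ---------------------------------------------------------------------------
# oriC component
# ---------------------------------------------------------------------------

def _blocking_sites_in_path(
    chrom: ChromosomeMap, start: int, direction: str
) -> list[tuple[int, TerSite]]:
    """Blocking Ter sites ordered by travel distance from ``start``."""
    out = []
    for site in chrom.ter_sites:
        if site.blocks != direction:
            continue
        if direction == CLOCKWISE:
            d = chrom.cw_distance(start, site.position)
        else:
            d = chrom.cw_distance(site.position, start)
        if d > 0:
            out.append((d, site))
    return sorted(out, key=lambda t: t[0])


def _arrest_outcomes(
    chrom: ChromosomeMap, start: int, direction: str
) -> list[tuple[float | None, float]]:
    """(arrest travel distance or None, probability) for a fork from ``start``.

    Enumerates the chain ``P(stop at site k) = e_k * prod_{j<k}(1 - e_j)``;
    outcomes with zero probability are pruned.
    """
    outcomes: list[tuple[float | None, float]] = []
    p_pass = 1.0
    for d, site in _blocking_sites_in_path(chrom, start, direction):
        p_stop = p_pass * site.efficiency
        if p_stop > 0:
            outcomes.append((float(d), p_stop))
        p_pass *= 1.0 - site.efficiency
        if p_pass == 0:
            break
    if p_pass > 0:
        outcomes.append((None, p_pass))
    return outcomes


def _replication_times(
    n_windows: int, ori_idx: int, stop_cw: int | None, stop_ccw: int | None
) -> np.ndarray:
    """Window replication times for two unit-speed forks leaving ``ori_idx``.

    ``stop_cw``/``stop_ccw`` are the travel distances (in windows) at which
    each fork is arrested, or None for unbounded.  A fork also terminates on
    reaching a window the other fork already replicated.  Windows neither
    fork reaches (both trapped facing away) are assigned the final time.
    """
    times = np.full(n_windows, -1.0)
    times[ori_idx] = 0.0
    pos_cw, pos_ccw = ori_idx, ori_idx
    d_cw = d_ccw = 0
    active_cw = active_ccw = True
    t = 0.0
    while active_cw or active_ccw:
        t += 1.0
        moved = False
        if active_cw:
            if stop_cw is not None and d_cw >= stop_cw:
                active_cw = False
            else:
                nxt = (pos_cw + 1) % n_windows
                if times[nxt] >= 0:
                    active_cw = False
                else:
                    times[nxt] = t
                    pos_cw, d_cw, moved = nxt, d_cw + 1, True
        if active_ccw:
            if stop_ccw is not None and d_ccw >= stop_ccw:
                active_ccw = False
            else:
                nxt = (pos_ccw - 1) % n_windows
                if times[nxt] >= 0:
                    active_ccw = False
                else:
                    times[nxt] = t
                    pos_ccw, d_ccw, moved = nxt, d_ccw + 1, True
        if not moved and (active_cw or active_ccw):
            # both forks stalled at barriers with windows left: remaining DNA
            # is replicated last, at a common final time
            break
    t_max = times.max()
    times[times < 0] = t_max + 1.0
    return times


def oric_copy_component(
    config: SimulationConfig, chrom: ChromosomeMap, grid_n: int
) -> np.ndarray:
    """Expected copy number per window from oriC-initiated replication.

    Exponential-culture marker frequency: ``2^{C/tau * (1 - m(x))}`` with
    ``m(x)`` the normalized replication time of ``x``.  Ter arrest outcomes
    (for barriers with efficiency < 1) are mixture-averaged.  Under
    spectinomycin run-off all rounds have completed: the component is flat 1.
    """
    if config.spc or config.c_over_tau == 0:
        return np.ones(grid_n)
    bounds = build_grid(chrom.length, grid_n)
    centers = (bounds[:-1] + bounds[1:]) / 2.0
    ori_idx = int(np.searchsorted(bounds, chrom.oriC, side="right") - 1)
    window_bp = chrom.length / grid_n

    def to_windows(dist_bp: float | None) -> int | None:
        return None if dist_bp is None else max(1, round(dist_bp / window_bp))

    cw_outcomes = _arrest_outcomes(chrom, chrom.oriC, CLOCKWISE) if config.tus else [(None, 1.0)]
    ccw_outcomes = (
        _arrest_outcomes(chrom, chrom.oriC, COUNTERCLOCKWISE) if config.tus else [(None, 1.0)]
    )
    profile = np.zeros(grid_n)
    for d_cw, p_cw in cw_outcomes:
        for d_ccw, p_ccw in ccw_outcomes:
            times = _replication_times(grid_n, ori_idx, to_windows(d_cw), to_windows(d_ccw))
            m = times / times.max() if times.max() > 0 else times
            profile += p_cw * p_ccw * np.exp2(config.c_over_tau * (1.0 - m))
    return profile


# ---------------------------------------------------------------------------
# RLDR component
# ---------------------------------------------------------------------------

def simulate_rldr_events(
    config: SimulationConfig,
    chrom: ChromosomeMap,
    rng: np.random.Generator,
) -> list[ReplicationEvent]:
    """Draw all RLDR events for ``config.n_cells`` cells.

    The event count is Poisson(rldr_rate * n_cells).  Each event fires at a
    uniform position; each of its two forks runs an Exponential(rldr_run_mean)
    distance (capped at one full circle) unless arrested by the first Ter
    site in blocking orientation (arrest probability = site efficiency,
    otherwise it passes through).  With Tus present, a trapped event
    triggers, with probability ``rereplication_prob``, a geometric burst of
    extra copies of the interval between the innermost flanking Ter pair.
    """
    if config.rldr_rate == 0:
        return []
    n_events = rng.poisson(config.rldr_rate * config.n_cells)
    if n_events == 0:
        return []
    trap: tuple[TerSite, TerSite] | None = None
    if config.tus and len(chrom.ter_sites) >= 2:
        try:
            trap = innermost_ter_pair(chrom)
        except Exception:
            trap = None
    origins = rng.integers(0, chrom.length, size=n_events)
    runs_cw = rng.exponential(config.rldr_run_mean, size=n_events)
    runs_ccw = rng.exponential(config.rldr_run_mean, size=n_events)
    gain = config.rereplication_gain
    events: list[ReplicationEvent] = []
    for origin, run_cw, run_ccw in zip(origins, runs_cw, runs_ccw):
        origin = int(origin)
        d_cw, trapped_right = _fork_run(chrom, origin, CLOCKWISE, run_cw, config.tus, rng)
        d_ccw, trapped_left = _fork_run(chrom, origin, COUNTERCLOCKWISE, run_ccw, config.tus, rng)
        if d_cw + d_ccw > chrom.length:  # forks met on the far side
            scale = chrom.length / (d_cw + d_ccw)
            d_cw *= scale
            d_ccw *= scale
        extra = 0
        if (
            config.tus
            and (trapped_left is not None or trapped_right is not None)
            and gain >= 1.0
            and config.rereplication_prob > 0
            and rng.random() < config.rereplication_prob
        ):
            extra = int(rng.geometric(min(1.0, 1.0 / gain)))
        events.append(
            ReplicationEvent(
                origin=origin,
                left_end=origin - d_ccw,
                right_end=origin + d_cw,
                trapped_left=trapped_left,
                trapped_right=trapped_right,
                extra_copies=extra if trap is not None else 0,
            )
        )
    return events


def _fork_run(
    chrom: ChromosomeMap,
    origin: int,
    direction: str,
    run: float,
    tus: bool,
    rng: np.random.Generator,
) -> tuple[float, TerSite | None]:
    """Travel distance and arresting site (if any) for one fork."""
    run = min(run, float(chrom.length))
    if not tus:
        return run, None
    for d, site in _blocking_sites_in_path(chrom, origin, direction):
        if d > run:
            break
        if site.efficiency >= 1.0 or rng.random() < site.efficiency:
            return float(d), site
    return run, None


def _accumulate_circular(
    acc: np.ndarray, bounds: np.ndarray, length: int, lo: float, hi: float, amount: float
) -> None:
    """Add ``amount`` to every window whose start lies in circular [lo, hi)."""
    n = len(acc)
    if hi - lo >= length:
        acc += amount
        return
    i = int(np.searchsorted(bounds, lo % length, side="right") - 1)
    j = int(np.searchsorted(bounds, hi % length, side="right") - 1)
    if i <= j:
        acc[i : j + 1] += amount
    else:
        acc[i:] += amount
        acc[: j + 1] += amount


def rldr_copy_component(
    config: SimulationConfig,
    chrom: ChromosomeMap,
    grid_n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo mean extra copies per window from RLDR events."""
    acc = np.zeros(grid_n)
    events = simulate_rldr_events(config, chrom, rng)
    if not events:
        return acc
    bounds = build_grid(chrom.length, grid_n)
    trap = None
    if config.tus and any(e.extra_copies for e in events):
        trap = innermost_ter_pair(chrom)
    for ev in events:
        _accumulate_circular(acc, bounds, chrom.length, ev.left_end, ev.right_end, 1.0)
        if ev.extra_copies and trap is not None:
            left, right = trap
            span = chrom.cw_distance(left.position, right.position)
            _accumulate_circular(
                acc, bounds, chrom.length, left.position, left.position + span, ev.extra_copies
            )
    return acc / config.n_cells


# ---------------------------------------------------------------------------
# Assembly and sampling
# ---------------------------------------------------------------------------

def expected_copy_profile(
    config: SimulationConfig,
    chrom: ChromosomeMap,
    grid_n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expected relative copy number per window, genome mean normalized to 1.

    Sum of the oriC component (flat under spectinomycin) and the Monte-Carlo
    RLDR component, then the amplification fold applied multiplicatively
    over its region.  The inversion in the config is applied to the map
    before any component is computed.
    """
    chrom = effective_map(config, chrom)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profile = oric_copy_component(config, chrom, grid_n)
    profile = profile + rldr_copy_component(config, chrom, grid_n, rng)
    if config.amplification is not None:
        (a, b), fold = config.amplification
        bounds = build_grid(chrom.length, grid_n)
        centers = (bounds[:-1] + bounds[1:]) / 2.0
        profile = np.where((centers >= a) & (centers < b), profile * fold, profile)
    return profile / profile.mean()


def sample_counts(
    expected: np.ndarray,
    depth: float,
    rng: np.random.Generator,
    length: int | None = None,
    condition: str = "log",
    sample_id: str = "",
) -> CoverageTrack:
    """Poisson read counts per window: ``counts[i] ~ Poisson(depth * expected[i])``."""
    expected = np.asarray(expected, dtype=float)
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    if (expected < 0).any():
        raise ValueError("expected copy numbers must be non-negative")
    grid_n = len(expected)
    bounds = build_grid(length if length is not None else grid_n, grid_n)
    counts = rng.poisson(depth * expected)
    return CoverageTrack(bounds=bounds, counts=counts, condition=condition, sample_id=sample_id)


def simulate_track(
    config: SimulationConfig,
    chrom: ChromosomeMap,
    grid_n: int = 10_000,
    sample_id: str = "",
) -> CoverageTrack:
    """expected_copy_profile + sample_counts with a single seeded RNG."""
    rng = np.random.default_rng(config.seed)
    expected = expected_copy_profile(config, chrom, grid_n, rng)
    condition = "spc" if config.spc else "log"
    return sample_counts(
        expected, config.depth, rng, length=chrom.length, condition=condition, sample_id=sample_id
    )


def simulate_control(
    chrom: ChromosomeMap,
    grid_n: int = 10_000,
    depth: float = 100.0,
    seed: int = 0,
    sample_id: str = "stationary_control",
) -> CoverageTrack:
    """Stationary-phase control: one copy everywhere, Poisson depth."""
    rng = np.random.default_rng(seed)
    return sample_counts(
        np.ones(grid_n),
        depth,
        rng,
        length=chrom.length,
        condition="stationary_control",
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    track: CoverageTrack,
    path: str | Path,
    format: str = "tsv",
    chrom_name: str = "chromosome",
    read_length: int = 50,
) -> None:
    """Write a track as a test fixture.

    ``tsv`` writes the window count table.  ``sam_lite`` expands each window
    count into that many single-end reads placed at the window start (MAPQ
    60, FLAG 0, CIGAR ``<read_length>M``, SEQ/QUAL omitted), preceded by
    @HD/@SQ headers, so the full SAM -> counts path can be round-tripped.
    """
    if format == "tsv":
        from .coverage import write_track_tsv

        write_track_tsv(track, path)
        return
    if format != "sam_lite":
        raise ValueError(f"unknown fixture format {format!r}")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom_name}\tLN:{track.length}\n")
        for i, (start, count) in enumerate(zip(track.bounds[:-1], track.counts)):
            pos = int(start) + 1  # SAM is 1-based
            for j in range(int(count)):
                fh.write(
                    f"r{i}_{j}\t0\t{chrom_name}\t{pos}\t60\t{read_length}M\t*\t0\t0\t*\t*\n"
                )
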