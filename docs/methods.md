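# Methods

## The measurement

Marker-frequency analysis infers replication dynamics from relative
sequencing depth. The pipeline mirrors the standard experimental recipe:

1. mapped reads are kept if MAPQ ≥ 10 (inclusive), assigned to windows by
   their leftmost mapped coordinate (CIGAR ignored, duplicates kept — no
   dedup step is part of the recipe);
2. the genome is divided into `grid_n = 10,000` contiguous windows; base
   width is `floor(L / grid_n)` and the first `L mod grid_n` windows are
   one bp wider, so windows exactly partition `[0, L)`;
3. each window's count is normalized against a stationary-phase control in
   which every locus is at one copy:
   `r_i = log2((s_i + q) / S · C / (c_i + q))` with library totals `S, C`
   and pseudocount `q = 0.5` on both sides (symmetric guard for zero-count
   windows; the totals use raw counts so self-normalization is exactly 0);
4. the log2 ratios are smoothed with loess: local linear fit, tricube
   weights over the `ceil(span·n)` nearest neighbours, span 0.1, no
   robustness iterations (the canonical defaults for this curve). For the
   circular chromosome, half a span of data is wrap-padded from each end
   (x shifted by ∓L) before fitting and cropped after, so the curve is
   continuous across the origin. Degenerate local fits (singular normal
   equations) fall back to the tricube-weighted mean.

Smoothing operates on the log2 ratios, not raw counts, because the peak
statistics are defined on that scale and the small printed magnitudes of
the run-off statistic (~0.2) are only sensible in log2 units; this is a
recorded assumption, as the original scale is not stated.

## Peak statistics

* **peak height** = (max loess inside the candidate Ter interval) − (min
  loess over the `flank_width` windows immediately clockwise of the
  interval). The flank is fixed-width (default 200 windows ≈ 93 kb at
  standard resolution) to make the statistic deterministic; the original
  description ("lowest value on the right side of the peak") does not
  bound the search. The statistic is invariant to constant shifts of the
  curve.
* **ter peak increase** = height(after spectinomycin) − height(before).
  Positive values mean terminus DNA kept accumulating after oriC
  initiations stopped.
* **marker ratio** (*ydcM*/*lepA* analog) = mean counts over the `2w+1`
  windows centred on each locus, ratioed; `w` defaults to 1 (≈1.4 kb
  context) and is widened (w = 5) in recovery studies where Poisson noise
  at single-window depth would dominate. A profile-based variant averages
  `2^loess` instead.
* **region copy ratio** (*qseC*/*lepA* analog) = mean count in a bp region
  over the mean at a reference locus — the sequencing analog of the qPCR
  amplification estimate.
* **flatness** : flat iff peak height < threshold; default threshold is
  3× the loess SD of a control profile, or 3× a robust (MAD-based) SD of
  the profile's own curve when no control is supplied (a localized peak
  inflates the MAD only weakly).

The candidate Ter interval defaults to the innermost fork trap: the
clockwise-adjacent barrier pair (ccw-blocking, then cw-blocking, nothing
between) whose midpoint lies farthest from oriC. After an inversion this
search automatically returns the relocated trap (TerB′–TerG).

## The generative model

The simulator provides ground truth, not realism. Expected copy number per
window is the sum of:

* **oriC component** — `2^{C/τ·(1−m(x))}` where `m(x) ∈ [0,1]` is the
  normalized time at which position x is replicated by two unit-speed
  forks leaving oriC, arrested at polar barriers according to efficiency
  (sub-unit efficiencies are mixture-averaged over arrest outcomes), each
  fork also terminating when it meets DNA the other has replicated. Under
  spectinomycin run-off all rounds have completed and the component is
  flat 1.
* **RLDR component** — a Monte-Carlo average over `n_cells`:
  Poisson(rate·n_cells) events, origins uniform (the "weak, widely
  distributed origins" picture), each fork running an
  Exponential(run-mean) distance capped at one circle unless arrested at
  the first blocking barrier (probability = efficiency). With Tus present,
  a trapped event triggers with probability `p_burst` a geometric burst
  (mean `gain`) of extra copies of the innermost trap interval —
  re-replication duplicates the trapped interval as a unit, matching a
  peak bordered by the innermost barriers.
* **amplification** — a multiplicative fold over a stated region
  (the parC-parE block analog at 2.99–3.24 Mb).

The profile is normalized to genome-wide mean 1 and window counts are drawn
Poisson(depth · expected), independent across windows.

**Spectinomycin pairing.** Run-off is not modelled in time; only the
profile shape is observable. `spc_variant(runoff_factor=2.0)` flattens the
oriC component and doubles the RLDR rate, standing in for the events that
accumulate during the two extra hours of incubation. The factor 2 is a
package choice; any factor > 1 yields a positive peak-increase with Tus.

**Scenario presets** (the study conditions): C/τ = 1 throughout (ori/ter
= 2); `topA_topB` uses rate 2 events/cell, 1 Mb mean runs, burst
probability 0.8, mean gain 8, and a 4.9-fold amplification — chosen so the
log-phase profile shows the canonical ordering (Ter peak > amplification
block > oriC gradient) and the inversion scenario relocates a dominant
peak; `topA` is the same with gain 2 and fold 1.3; `topA_topB_tus` sets
`tus=False`; `topA_topB_inv` inverts 1.52–1.84 Mb, which flips TerB's
polarity in place and re-bounds the trap as TerB′–TerG. The bundled
synthetic chromosome (4.64 Mb, oriC 3.92 Mb, TerA/TerB/TerG at
1.34/1.68/2.40 Mb with efficiencies 1/1/0.5, ydcM/lepA/qseC at
1.51/2.70/3.10 Mb) is representative, not genome-accurate; real analyses
should supply a coordinate-accurate map file (`termfa.genome.read_map`).

**Saturation of the log2 statistic.** Because the peak-increase is a
difference of log2 contrasts, it saturates when trap occupancy is high in
both members of a pair: as the initiation rate grows, pre- and post-run-off
heights both approach `log2(trap yield / flank yield)` and their difference
shrinks. Dose-response studies of the statistic therefore use a low
per-event intensity (run mean 100 kb, gain 1, burst probability 0.5),
which keeps the response in its informative range — the regime where the
small printed values of the statistic live.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: GC/mappability bias, overdispersed counts,
paired-end structure, rrn-operon extraction artefacts, the codB-lacI gap,
replication-speed variation, RecA/RecG mechanism, and fork timing within
single cells. Poisson-per-window is the simplest adequate noise model; an
overdispersion knob was deliberately deferred.

## Numerical choices and problem sizes

* Coordinates 0-based half-open internally; positions displayed as Mb with
  two decimals. Clockwise = increasing coordinate.
* Inversion `[a, b)` maps p → a+b−1−p and flips barrier polarity; it is an
  involution, property-tested.
* Fork-time simulation runs on the window grid (arrest distances rounded
  to windows); event coverage is accumulated at window resolution
  (windows whose start falls in the replicated interval).
* Monte-Carlo replicate studies use 1000–2000 windows and 300–500 cells —
  enough for stable medians across seed banks; the single-sample recovery
  checks (ori/ter ratio, amplification folds) run at the full 10,000
  windows and depth 500. The full suite runs in ~11 s, the acceptance
  script in ~5 s.
* The loess smoother is validated two ways: exactly (≤1e-6) against a
  brute-force weighted-least-squares implementation, and loosely against
  statsmodels lowess on interior points (the two agree to <0.02 on smooth
  signals; boundary handling differs).

## Known limitations

* The peak region must be supplied or derived from a barrier map; there is
  no de-novo genome-wide peak discovery, and no significance testing of
  peak heights.
* `marker_ratio` on raw counts assumes comparable local replication
  timing at the two loci; across a steep gradient it confounds C/τ with
  copy-number differences, exactly as the qPCR it emulates does.
* Multi-mapping reads below MAPQ 10 are discarded, not fractionally
  assigned.
* The adjusted-activity correction assumes activity combines additively
  (baseline + scaled excess) and is only as good as the 5–10× activity
  range it takes as input.
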