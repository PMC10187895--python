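"""Circular-chromosome model: polar Ter/Tus fork barriers, marker loci,
window arithmetic and segment inversions.

Coordinates are 0-based, half-open bp offsets on a circular chromosome.
"Clockwise" means increasing coordinate, with wrap-around at ``length -> 0``;
"counterclockwise" is the opposite.  A polar Ter site bound by Tus arrests
replication forks travelling in the direction it *blocks* and is permissive
for forks travelling the other way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"

_BLOCK_ALIASES = {
    "clockwise": CLOCKWISE,
    "cw": CLOCKWISE,
    "counterclockwise": COUNTERCLOCKWISE,
    "ccw": COUNTERCLOCKWISE,
}


class MapValidationError(ValueError):
    """A chromosome-map feature violates a positional or naming constraint."""


@dataclass(frozen=True)
class TerSite:
    """A polar Ter/Tus replication-fork barrier.

    Parameters
    ----------
    name
        Short label, e.g. ``"TerA"``.
    position
        0-based bp offset.
    blocks
        Fork direction arrested: ``"clockwise"`` or ``"counterclockwise"``.
    efficiency
        Arrest probability in [0, 1] for a fork arriving in the blocked
        direction.  Strong barriers (TerA, TerB) are 1.0; weaker sites
        such as TerG are < 1.
    """

    name: str
    position: int
    blocks: str
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.blocks not in _BLOCK_ALIASES:
            raise MapValidationError(
                f"TerSite {self.name!r}: blocks must be cw/ccw, got {self.blocks!r}"
            )
        object.__setattr__(self, "blocks", _BLOCK_ALIASES[self.blocks])
        if not 0.0 <= self.efficiency <= 1.0:
            raise MapValidationError(
                f"TerSite {self.name!r}: efficiency {self.efficiency} not in [0, 1]"
            )

    @property
    def flipped(self) -> "TerSite":
        other = CLOCKWISE if self.blocks == COUNTERCLOCKWISE else COUNTERCLOCKWISE
        return replace(self, blocks=other)


@dataclass(frozen=True)
class Locus:
    """A named marker position (gene or qPCR amplicon midpoint)."""

    name: str
    position: int


@dataclass(frozen=True)
class ChromosomeMap:
    """A circular chromosome with its origin, fork barriers and marker loci."""

    length: int
    oriC: int
    ter_sites: tuple[TerSite, ...] = ()
    loci: tuple[Locus, ...] = ()
    dif: int | None = None
    circular: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise MapValidationError(f"chromosome length must be > 0, got {self.length}")
        self._check_pos("oriC", self.oriC)
        if self.dif is not None:
            self._check_pos("dif", self.dif)
        seen: set[str] = set()
        for site in self.ter_sites:
            self._check_pos(site.name, site.position)
            if site.name in seen:
                raise MapValidationError(f"duplicate Ter site name {site.name!r}")
            seen.add(site.name)
        for locus in self.loci:
            self._check_pos(locus.name, locus.position)

    def _check_pos(self, name: str, pos: int) -> None:
        if not 0 <= pos < self.length:
            raise MapValidationError(
                f"feature {name!r} at position {pos} outside [0, {self.length})"
            )

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"locus {name!r} not on the chromosome map")

    def ter(self, name: str) -> TerSite:
        for site in self.ter_sites:
            if site.name == name:
                return site
        raise KeyError(f"Ter site {name!r} not on the chromosome map")

    def cw_distance(self, a: int, b: int) -> int:
        """Clockwise bp distance travelled going from ``a`` to ``b``."""
        return (b - a) % self.length

    def circ_distance(self, a: int, b: int) -> int:
        """Shorter-arc distance between two positions."""
        d = self.cw_distance(a, b)
        return min(d, self.length - d)

    def format_mb(self, pos: int) -> str:
        """Display a position as Mb with two decimals (``1520000 -> '1.52'``)."""
        return f"{pos / 1e6:.2f}"


def build_map(
    length: int,
    oriC: int,
    ter_sites: Iterable[TerSite] = (),
    loci: Iterable[Locus] = (),
    dif: int | None = None,
) -> ChromosomeMap:
    """Construct and validate a :class:`ChromosomeMap`.

    Raises :class:`MapValidationError` naming the offending feature when a
    position falls outside ``[0, length)`` or two Ter sites share a name.
    """
    return ChromosomeMap(
        length=length, oriC=oriC, ter_sites=tuple(ter_sites), loci=tuple(loci), dif=dif
    )


def apply_inversion(chrom: ChromosomeMap, a: int, b: int) -> ChromosomeMap:
    """Invert the segment ``[a, b)`` of the chromosome.

    Every feature at position ``p`` in the segment maps to ``a + b - 1 - p``;
    a Ter site inside the segment also flips the fork direction it blocks
    (its polarity is physically reversed by the rearrangement).  Features
    outside the segment are untouched.  Applying the same inversion twice
    restores the original map.
    """
    if not (0 <= a < b <= chrom.length):
        raise MapValidationError(f"invalid inversion bounds [{a}, {b}) on length {chrom.length}")

    def move(p: int) -> int:
        return a + b - 1 - p if a <= p < b else p

    ter_sites = tuple(
        replace(s.flipped, position=move(s.position)) if a <= s.position < b else s
        for s in chrom.ter_sites
    )
    loci = tuple(replace(l, position=move(l.position)) for l in chrom.loci)
    return ChromosomeMap(
        length=chrom.length,
        oriC=move(chrom.oriC),
        ter_sites=ter_sites,
        loci=loci,
        dif=move(chrom.dif) if chrom.dif is not None else None,
    )


def locate_window(grid_n: int, length: int, pos: int) -> int:
    """Window index of a bp position on the standard genome grid.

    The grid puts ``grid_n`` contiguous windows on ``[0, length)``: the base
    width is ``length // grid_n`` and the first ``length % grid_n`` windows
    are one bp wider, so every bp belongs to exactly one window.
    """
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside [0, {length})")
    if not 0 < grid_n <= length:
        raise ValueError(f"grid_n {grid_n} not in (0, {length}]")
    w, r = divmod(length, grid_n)
    wide_span = r * (w + 1)
    if pos < wide_span:
        return pos // (w + 1)
    return r + (pos - wide_span) // w


def innermost_ter_pair(chrom: ChromosomeMap) -> tuple[TerSite, TerSite]:
    """The pair of barriers bounding the innermost fork trap.

    Searches clockwise-adjacent Ter pairs (left site blocking counterclockwise
    forks, right site blocking clockwise forks, no site between them): forks
    entering that interval from either side cannot leave it.  When several
    candidates exist the one whose midpoint lies farthest from oriC is taken,
    matching the terminus trap opposite the origin.
    """
    sites = sorted(chrom.ter_sites, key=lambda s: s.position)
    if len(sites) < 2:
        raise MapValidationError("need at least two Ter sites to define a fork trap")
    candidates: list[tuple[TerSite, TerSite]] = []
    n = len(sites)
    for i in range(n):
        left, right = sites[i], sites[(i + 1) % n]
        if left.blocks == COUNTERCLOCKWISE and right.blocks == CLOCKWISE:
            candidates.append((left, right))
    if not candidates:
        raise MapValidationError("no (ccw-blocking, cw-blocking) Ter pair forms a trap")

    def anti_ori(pair: tuple[TerSite, TerSite]) -> int:
        left, right = pair
        span = chrom.cw_distance(left.position, right.position)
        mid = (left.position + span // 2) % chrom.length
        return chrom.circ_distance(mid, chrom.oriC)

    return max(candidates, key=anti_ori)


# ---------------------------------------------------------------------------
# Map file I/O
# ---------------------------------------------------------------------------

_MAP_HEADER = ["feature_type", "name", "position_bp", "blocks", "efficiency"]


def read_map(path: str | Path, length: int | None = None) -> ChromosomeMap:
    """Read a chromosome map from TSV.

    Columns: ``feature_type`` (ter|locus|oriC|dif|length), ``name``,
    ``position_bp``, ``blocks`` (cw|ccw|.), ``efficiency`` ('.' for loci).
    The chromosome length may be given either as a ``length`` row (name '.')
    or via the ``length`` argument.
    """
    ter_sites: list[TerSite] = []
    loci: list[Locus] = []
    oriC: int | None = None
    dif: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == _MAP_HEADER[0]:
                continue
            if len(parts) < 3:
                raise MapValidationError(f"{path}:{lineno}: expected >=3 columns")
            ftype, name, pos_s = parts[0], parts[1], parts[2]
            pos = int(pos_s)
            if ftype == "length":
                length = pos
            elif ftype == "oriC":
                oriC = pos
            elif ftype == "dif":
                dif = pos
            elif ftype == "ter":
                blocks = parts[3] if len(parts) > 3 else "cw"
                eff = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 1.0
                ter_sites.append(TerSite(name, pos, blocks, eff))
            elif ftype == "locus":
                loci.append(Locus(name, pos))
            else:
                raise MapValidationError(f"{path}:{lineno}: unknown feature_type {ftype!r}")
    if length is None or oriC is None:
        raise MapValidationError(f"{path}: map must define both length and oriC")
    return build_map(length, oriC, ter_sites, loci, dif=dif)


def write_map(chrom: ChromosomeMap, path: str | Path) -> None:
    """Write a chromosome map as TSV (inverse of :func:`read_map`)."""
    lines = ["\t".join(_MAP_HEADER)]
    lines.append(f"length\t.\t{chrom.length}\t.\t.")
    lines.append(f"oriC\toriC\t{chrom.oriC}\t.\t.")
    if chrom.dif is not None:
        lines.append(f"dif\tdif\t{chrom.dif}\t.\t.")
    for s in chrom.ter_sites:
        short = "cw" if s.blocks == CLOCKWISE else "ccw"
        lines.append(f"ter\t{s.name}\t{s.position}\t{short}\t{s.efficiency}")
    for l in chrom.loci:
        lines.append(f"locus\t{l.name}\t{l.position}\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_loci(path: str | Path) -> list[Locus]:
    """Read marker loci from BED3+name; the locus position is the interval midpoint."""
    loci: list[Locus] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MapValidationError(f"{path}: BED loci need 4 columns (chrom start end name)")
            start, end, name = int(parts[1]), int(parts[2]), parts[3]
            loci.append(Locus(name, (start + end) // 2))
    return loci
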