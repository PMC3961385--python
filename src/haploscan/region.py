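"""Model of the resequenced target region.

The region is an abstract coordinate system ``[0, L)`` tiled by long-range
PCR amplicons, with optional declared gaps (stretches that could not be
amplified, e.g. a GC-rich promoter) and homopolymer intervals where the
per-base error rate is elevated.  Coordinates are 0-based half-open
internally; VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Interval", "RegionModel", "build_region", "default_region"]


@dataclass(frozen=True)
class Interval:
    """Half-open interval ``[start, end)`` with an optional name/value."""

    start: int
    end: int
    name: str = ""
    value: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionModel:
    """Target region: amplicon tiling, declared gaps and homopolymers.

    Parameters
    ----------
    length_bp:
        Region length L, the denominator used for nucleotide diversity.
    amplicons:
        Amplicon intervals; together with ``gaps`` they must tile [0, L).
    gaps:
        Explicitly declared un-amplifiable stretches (zero depth).
    homopolymers:
        Intervals with elevated base-call error (value = run length).
    origin_offset:
        Genomic coordinate of position 0 (only affects reported positions).
    """

    length_bp: int
    amplicons: list[Interval]
    gaps: list[Interval] = field(default_factory=list)
    homopolymers: list[Interval] = field(default_factory=list)
    origin_offset: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        pieces = sorted(
            [(iv.start, iv.end, "amplicon", iv.name) for iv in self.amplicons]
            + [(iv.start, iv.end, "gap", iv.name) for iv in self.gaps]
        )
        cursor = 0
        for start, end, kind, name in pieces:
            if start < 0 or end > self.length_bp:
                raise ValueError(f"{kind} {name!r} [{start},{end}) outside [0, {self.length_bp})")
            if start < cursor:
                raise ValueError(f"{kind} {name!r} overlaps the previous interval")
            if start > cursor:
                raise ValueError(f"uncovered stretch [{cursor},{start}) — declare it as a gap")
            cursor = end
        if cursor != self.length_bp:
            raise ValueError(f"uncovered stretch [{cursor},{self.length_bp}) — declare it as a gap")
        for iv in self.homopolymers:
            if iv.start < 0 or iv.end > self.length_bp:
                raise ValueError(f"homopolymer [{iv.start},{iv.end}) outside [0, {self.length_bp})")

    # -- lookups -------------------------------------------------------

    def amplicon_index(self, positions: np.ndarray) -> np.ndarray:
        """Index into ``self.amplicons`` per position, -1 inside gaps."""
        positions = np.asarray(positions)
        out = np.full(positions.shape, -1, dtype=np.int64)
        for i, iv in enumerate(self.amplicons):
            out[(positions >= iv.start) & (positions < iv.end)] = i
        return out

    def in_homopolymer(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        out = np.zeros(positions.shape, dtype=bool)
        for iv in self.homopolymers:
            out |= (positions >= iv.start) & (positions < iv.end)
        return out


def build_region(config: dict) -> RegionModel:
    """Build a :class:`RegionModel` from a plain config mapping.

    ``config`` keys: ``length`` (int), ``amplicons`` (list of
    ``[start, end]`` or ``[start, end, name]``), optional ``gaps`` and
    ``homopolymers`` (same shape; homopolymer third element is run length),
    optional ``origin_offset``.
    """

    def to_intervals(rows, prefix: str, numeric_third: bool = False) -> list[Interval]:
        out = []
        for i, row in enumerate(rows or []):
            if numeric_third and len(row) > 2:
                out.append(Interval(int(row[0]), int(row[1]), f"{prefix}{i + 1}", float(row[2])))
            elif len(row) > 2:
                out.append(Interval(int(row[0]), int(row[1]), str(row[2])))
            else:
                out.append(Interval(int(row[0]), int(row[1]), f"{prefix}{i + 1}"))
        return out

    return RegionModel(
        length_bp=int(config["length"]),
        amplicons=to_intervals(config["amplicons"], "amp"),
        gaps=to_intervals(config.get("gaps"), "gap"),
        homopolymers=to_intervals(config.get("homopolymers"), "hp", numeric_third=True),
        origin_offset=int(config.get("origin_offset", 0)),
    )


def default_region(scale: str = "test") -> RegionModel:
    """Default region geometry: eight amplicons plus one declared gap.

    ``scale="full"`` gives the ~95 kb shape of a whole gene locus with
    ~20 kb flanks; ``scale="test"`` is the same shape scaled to 10 kb,
    the size used throughout the test suite and the default pipeline run.
    """
    if scale == "full":
        L = 95_000
    elif scale == "test":
        L = 10_000
    else:  # pragma: no cover - config error path
        raise ValueError(f"unknown scale {scale!r}")

    def s(x: int) -> int:
        return round(x * L / 10_000)

    # gap sits between amplicons 1 and 2, around the GC-rich promoter
    bounds = [0, 1400, 1900, 3100, 4300, 5500, 6700, 7800, 8900, 10_000]
    amplicons = []
    gaps = []
    k = 0
    for start, end in zip(bounds[:-1], bounds[1:]):
        if (start, end) == (1400, 1900):
            gaps.append(Interval(s(start), s(end), "gap1"))
        else:
            k += 1
            amplicons.append(Interval(s(start), s(end), f"amp{k}"))
    homopolymers = [
        Interval(s(2350), s(2350) + 15, "hp1", 12),
        Interval(s(4920), s(4920) + 15, "hp2", 11),
        Interval(s(7210), s(7210) + 20, "hp3", 14),
    ]
    return RegionModel(length_bp=L, amplicons=amplicons, gaps=gaps, homopolymers=homopolymers)
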