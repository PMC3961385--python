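"""Regulatory-annotation intersection and candidate selection.

Variants are intersected with three track families: DNase I
hypersensitivity site peaks (DHSPs, source codes 1 = neuronal, 2 = hESC,
3 = foetal brain), predicted enhancer elements (NPC / HSMM cell types),
and conserved elements carrying an evolutionary-constraint (GERP-like)
score.  A variant only receives a constraint score when it lies inside a
conserved element, and is "conserved" when that score exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .region import Interval

__all__ = [
    "AnnotationTrack",
    "VariantAnnotation",
    "overlap_annotate",
    "conservation_enrichment",
    "merge_supported_intervals",
    "select_candidates",
]

GERP_CONSERVED = 2.0

DHSP_SOURCES = ("1", "2", "3")  # neuronal, hESC, foetal brain
ENHANCER_SOURCES = ("NPC", "HSMM")


@dataclass
class AnnotationTrack:
    """One annotation track: sorted half-open intervals of one kind.

    ``kind`` is ``"dhsp"`` (interval name = cell-class source code),
    ``"enhancer"`` (name = cell type) or ``"conserved"`` (value =
    constraint score).
    """

    kind: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        starts = [iv.start for iv in self.intervals]
        if starts != sorted(starts):
            raise ValueError(f"{self.kind} track intervals are not sorted")
        self._tree = IntervalTree()
        for iv in self.intervals:
            self._tree.addi(iv.start, iv.end, iv)

    def hits(self, pos: int) -> list[Interval]:
        return [h.data for h in self._tree.at(pos)]


@dataclass
class VariantAnnotation:
    """Per-variant track membership."""

    position: int
    dhsp_codes: frozenset[str] = frozenset()
    enhancer_flags: frozenset[str] = frozenset()
    gerp_score: float | None = None

    @property
    def conserved(self) -> bool:
        return self.gerp_score is not None and self.gerp_score > GERP_CONSERVED

    @property
    def in_dhsp(self) -> bool:
        return bool(self.dhsp_codes)

    @property
    def in_enhancer(self) -> bool:
        return bool(self.enhancer_flags)


def overlap_annotate(
    positions: list[int], tracks: dict[str, AnnotationTrack]
) -> list[VariantAnnotation]:
    """Point-in-interval membership per variant, half-open convention.

    Multi-track membership accumulates source codes; when several
    conserved elements cover a position the maximum score is attached.
    """
    dhsp = tracks.get("dhsp")
    enhancer = tracks.get("enhancer")
    conserved = tracks.get("conserved")
    out = []
    for pos in positions:
        codes = frozenset(iv.name for iv in dhsp.hits(pos)) if dhsp else frozenset()
        flags = frozenset(iv.name for iv in enhancer.hits(pos)) if enhancer else frozenset()
        score = None
        if conserved:
            scores = [iv.value for iv in conserved.hits(pos) if iv.value is not None]
            score = max(scores) if scores else None
        out.append(
            VariantAnnotation(
                position=pos, dhsp_codes=codes, enhancer_flags=flags, gerp_score=score
            )
        )
    return out


def conservation_enrichment(
    annotations: list[VariantAnnotation],
) -> dict[str, float | int | None]:
    """Proportion of conserved variants inside vs outside DHSPs.

    Reports the two proportions with their counts; a stratum with no
    variants yields a None proportion (not applicable).  No test statistic
    is attached — the contrast is descriptive.
    """
    in_d = [a for a in annotations if a.in_dhsp]
    out_d = [a for a in annotations if not a.in_dhsp]
    prop_in = sum(a.conserved for a in in_d) / len(in_d) if in_d else None
    prop_out = sum(a.conserved for a in out_d) / len(out_d) if out_d else None
    return {
        "prop_conserved_in_dhsp": prop_in,
        "prop_conserved_outside": prop_out,
        "n_in_dhsp": len(in_d),
        "n_outside": len(out_d),
    }


def merge_supported_intervals(
    tracks: list[list[Interval]], min_support: int = 2, name: str = "3"
) -> list[Interval]:
    """Merge per-library interval lists, keeping regions seen in >= min_support.

    Emulates clustering peak calls across library preparations to drop
    peaks supported by a single library: a breakpoint sweep counts how
    many input lists cover each stretch and keeps stretches at or above
    the support threshold (adjacent kept stretches are fused).
    """
    events: list[tuple[int, int]] = []
    for track in tracks:
        for iv in track:
            events.append((iv.start, +1))
            events.append((iv.end, -1))
    if not events:
        return []
    events.sort()
    merged: list[Interval] = []
    depth = 0
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_support and open_start is None:
            open_start = pos
        elif depth < min_support and open_start is not None:
            if merged and merged[-1].end == open_start:
                merged[-1] = Interval(merged[-1].start, pos, name)
            elif pos > open_start:
                merged.append(Interval(open_start, pos, name))
            open_start = None
    return merged


@dataclass
class CandidateRecord:
    """Inputs to the candidate-selection rule for one variant."""

    position: int
    gerp_score: float | None = None
    in_dhsp: bool = False
    in_enhancer: bool = False
    freq_diff: float = 0.0
    novel: bool = False
    criteria: tuple[str, ...] = field(default_factory=tuple)


def select_candidates(
    records: list[CandidateRecord],
    gerp_min: float = GERP_CONSERVED,
    freq_diff_min: float = 0.05,
) -> list[CandidateRecord]:
    """Two-criteria candidate selection for validation genotyping.

    Criterion 1: constraint score > ``gerp_min`` AND (in a DHSP, in an
    enhancer, or |frequency difference| >= ``freq_diff_min``).  Criterion
    2: (in an enhancer or DHSP) AND (|frequency difference| >=
    ``freq_diff_min`` or novel).  Selected records are returned labelled
    with the criteria that fired.
    """
    selected = []
    for r in records:
        conserved = r.gerp_score is not None and r.gerp_score > gerp_min
        big_diff = abs(r.freq_diff) >= freq_diff_min
        fired = []
        if conserved and (r.in_dhsp or r.in_enhancer or big_diff):
            fired.append("C1")
        if (r.in_enhancer or r.in_dhsp) and (big_diff or r.novel):
            fired.append("C2")
        if fired:
            selected.append(
                CandidateRecord(
                    position=r.position,
                    gerp_score=r.gerp_score,
                    in_dhsp=r.in_dhsp,
                    in_enhancer=r.in_enhancer,
                    freq_diff=r.freq_diff,
                    novel=r.novel,
                    criteria=tuple(fired),
                )
            )
    return selected
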