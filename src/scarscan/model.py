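"""Core data model for structural-variant junction analysis.

Coordinates are 1-based inclusive throughout the library; BEDPE I/O converts
from 0-based half-open. A break end is an oriented endpoint of a rearrangement
junction: its orientation records which side of the breakpoint is retained in
the fused (derivative) sequence. ``LEFT`` means the sequence toward lower
coordinates is retained, ``RIGHT`` the sequence toward higher coordinates.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional


@functools.total_ordering
class Orient(enum.Enum):
    """Which side of a break-end position is retained by the fusion."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"

    def __lt__(self, other: "Orient") -> bool:
        order = {Orient.LEFT: 0, Orient.RIGHT: 1}
        return order[self] < order[other]


class SvClass(enum.Enum):
    """Simple junction classes derived from break-end orientations."""

    DEL_LIKE = "DEL-like"
    DUP_LIKE = "DUP-like"
    INV_LIKE = "INV-like"
    TRA = "TRA"


class SpanClass(enum.Enum):
    """Junction span classes (distance between break ends)."""

    INTRA_LT_1MBP = "intra_lt1Mbp"
    INTRA_1_10MBP = "intra_1_10Mbp"
    INTRA_GT_10MBP = "intra_gt10Mbp"
    INTERCHROMOSOMAL = "interchromosomal"


@dataclass(frozen=True)
class GenomeInfo:
    """Chromosome names, lengths and optional centromere intervals.

    Centromere intervals are 1-based inclusive and must lie within the
    chromosome they annotate.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValueError(f"chromosome {name!r} has no length")
        for chrom, (start, end) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"centromere {chrom}:{start}-{end} outside chromosome bounds"
                )

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def chrom_rank(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True, order=True)
class BreakEnd:
    """One oriented endpoint of a rearrangement junction."""

    chrom: str
    pos: int
    orient: Orient

    def validate(self, genome: Optional[GenomeInfo] = None) -> None:
        if self.pos < 1:
            raise ValueError(f"break-end position {self.pos} < 1")
        if genome is not None:
            if self.chrom not in genome.chrom_lengths:
                raise ValueError(f"unknown chromosome {self.chrom!r}")
            if self.pos > genome.length(self.chrom):
                raise ValueError(
                    f"break end {self.chrom}:{self.pos} beyond chromosome end"
                )


@dataclass(frozen=True)
class Junction:
    """An adjacency between two break ends created by a rearrangement.

    Break ends are stored in canonical order: lexicographic by (chrom, pos),
    ties broken by orientation (LEFT < RIGHT).
    """

    id: str
    be1: BreakEnd
    be2: BreakEnd

    def __post_init__(self) -> None:
        key1 = (self.be1.chrom, self.be1.pos, self.be1.orient)
        key2 = (self.be2.chrom, self.be2.pos, self.be2.orient)
        if key1 > key2:
            object.__setattr__(self, "be1", replace(self.be2))
            object.__setattr__(self, "be2", BreakEnd(key1[0], key1[1], key1[2]))

    @property
    def intrachromosomal(self) -> bool:
        return self.be1.chrom == self.be2.chrom

    @property
    def span(self) -> Optional[int]:
        """Distance between break ends in bases; None for translocations."""
        if not self.intrachromosomal:
            return None
        return abs(self.be2.pos - self.be1.pos)

    @property
    def svclass(self) -> SvClass:
        return classify_simple_junction(self)

    @property
    def span_class(self) -> SpanClass:
        return junction_span_class(self)

    def break_ends(self) -> tuple[BreakEnd, BreakEnd]:
        return (self.be1, self.be2)


@dataclass
class JunctionSet:
    """A sample's junction calls plus genome context."""

    sample_id: str
    junctions: list[Junction]
    genome: Optional[GenomeInfo] = None

    def __post_init__(self) -> None:
        ids = [j.id for j in self.junctions]
        if len(ids) != len(set(ids)):
            raise ValueError("junction ids are not unique")
        if self.genome is not None:
            for j in self.junctions:
                j.be1.validate(self.genome)
                j.be2.validate(self.genome)

    def __iter__(self) -> Iterable[Junction]:
        return iter(self.junctions)

    def __len__(self) -> int:
        return len(self.junctions)

    def by_id(self, junction_id: str) -> Junction:
        for j in self.junctions:
            if j.id == junction_id:
                return j
        raise KeyError(junction_id)


@dataclass(frozen=True)
class CNSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    total_cn: int
    major_cn: Optional[int] = None
    minor_cn: Optional[int] = None


@dataclass
class CNProfile:
    """Per-segment total and allelic copy number, 1-based inclusive.

    Segments must be non-overlapping per chromosome and, where allelic values
    are present, satisfy total = major + minor.
    """

    segments: list[CNSegment]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            if seg.start > seg.end:
                raise ValueError(f"segment {seg} has start > end")
            if seg.major_cn is not None and seg.minor_cn is not None:
                if seg.total_cn != seg.major_cn + seg.minor_cn:
                    raise ValueError(
                        f"segment {seg}: total_cn != major_cn + minor_cn"
                    )
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping segments on {chrom}")

    def total_cn_at(self, chrom: str, pos: int) -> Optional[int]:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.total_cn
        return None


def classify_simple_junction(j: Junction) -> SvClass:
    """Classify a canonical junction by its break-end orientations.

    Intrachromosomal junctions with the low break end retaining its left side
    and the high break end its right side are deletion-like (the middle is
    lost from the derivative); the opposite pattern is duplication-like; equal
    orientations are inversion-like. Interchromosomal junctions are
    translocations.
    """
    if not j.intrachromosomal:
        return SvClass.TRA
    o1, o2 = j.be1.orient, j.be2.orient
    if o1 == o2:
        return SvClass.INV_LIKE
    if o1 is Orient.LEFT:  # LEFT at low, RIGHT at high
        return SvClass.DEL_LIKE
    return SvClass.DUP_LIKE


_MBP = 1_000_000


def junction_span_class(j: Junction) -> SpanClass:
    """Bin a junction by span: <1 Mbp, [1, 10) Mbp, >=10 Mbp, or interchromosomal."""
    span = j.span
    if span is None:
        return SpanClass.INTERCHROMOSOMAL
    if span < _MBP:
        return SpanClass.INTRA_LT_1MBP
    if span < 10 * _MBP:
        return SpanClass.INTRA_1_10MBP
    return SpanClass.INTRA_GT_10MBP
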