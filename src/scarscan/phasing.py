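"""Somatic phasing of reciprocal pairs and centromeric-orientation typing.

A reciprocal pair admits a small family of derivative reconstructions,
represented as *walks*: ordered, oriented reference segments. For rDups and
rDelDups both junctions may sit consecutively on one derivative (*cis*, a
templated copy-paste) or on two distant derivatives (*trans*, a quasi-balanced
rearrangement); rDels are trans by topology. Phase is either imputed from gap
lengths (decision threshold 10^3.5 bases) or called from linked-read barcode
support for each candidate walk within a 100-kbp window of the junctions.

Independently of phase, the hypothetical trans derivatives of a pair fall in
one of two centromeric orientations: type I, where every derivative is
monocentric, and type II, which produces acentric and/or dicentric products.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import BreakEnd, GenomeInfo, JunctionSet, Orient
from .rpairs import GapSegment, Polarity, RPairClass, ReciprocalCluster

LOG10_GAP_THRESHOLD = 3.5  # cis/trans imputation cut on log10 gap length
SCORING_WINDOW = 100_000  # walk flank length for barcode scoring (bases)
MIN_SIDE_OVERLAP = 1_000  # molecule overlap required on each junction flank


class Phase(enum.Enum):
    CIS = "cis"
    TRANS = "trans"
    AMBIGUOUS = "ambiguous"


class OrientationType(enum.Enum):
    TYPE_I = "typeI"
    TYPE_II = "typeII"
    NA = "NA"


@dataclass(frozen=True)
class Segment:
    """Oriented reference interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self} has start > end")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Walk:
    """Ordered oriented reference segments forming (part of) a derivative.

    ``junction_ids[i]`` names the junction joining ``segments[i]`` to
    ``segments[i+1]``; a None entry marks a reference-adjacent boundary.
    """

    label: str
    segments: list[Segment]
    junction_ids: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.junction_ids and len(self.junction_ids) != len(self.segments) - 1:
            raise ValueError("need one boundary annotation per segment pair")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def junction_offsets(self) -> list[tuple[str, int]]:
        """Walk coordinate (last base of the left segment) of each junction."""
        out = []
        offset = 0
        for seg, jid in zip(self.segments, self.junction_ids + [None]):
            offset += seg.length
            if jid is not None:
                out.append((jid, offset))
        return out


@dataclass
class Reconstructions:
    """Candidate derivative walk sets for one reciprocal pair."""

    rpair_id: str
    rpair_class: RPairClass
    cis: list[list[Walk]]  # each option: [derivative walk, intact partner]
    trans: list[Walk]  # the two trans derivatives, one set


@dataclass
class PhaseCall:
    rpair_id: str
    phase: Phase
    method: str  # 'imputed' or 'barcode'
    support: dict[str, int] = field(default_factory=dict)
    orientation_type: OrientationType = OrientationType.NA


class _RPairView:
    """Resolved geometry of an rPair: junctions, gaps, break-end ownership."""

    def __init__(self, cluster: ReciprocalCluster,
                 gaps: dict[str, GapSegment], js: JunctionSet):
        if cluster.rpair_class is RPairClass.NA:
            raise ValueError(f"cluster {cluster.id} is not a reciprocal pair")
        self.cluster = cluster
        self.gaps = [gaps[g] for g in sorted(cluster.gap_ids)]
        self.junctions = {jid: js.by_id(jid) for jid in cluster.junction_ids}

    def other_breakend(self, jid: str, gap: GapSegment) -> BreakEnd:
        """The break end of junction jid that is NOT on the given gap."""
        j = self.junctions[jid]
        lo_orient = (Orient.RIGHT if gap.polarity is Polarity.PLUS
                     else Orient.LEFT)
        hi_orient = (Orient.LEFT if gap.polarity is Polarity.PLUS
                     else Orient.RIGHT)
        if gap.lo_junction == jid:
            on_gap = BreakEnd(gap.chrom, gap.lo_pos, lo_orient)
        else:
            on_gap = BreakEnd(gap.chrom, gap.hi_pos, hi_orient)
        for be in j.break_ends():
            if be != on_gap:
                return be
        raise ValueError(f"junction {jid} has both break ends on gap {gap.id}")


def _flank_ending_at(be: BreakEnd, genome: GenomeInfo,
                     window: Optional[int]) -> Segment:
    """Retained flank of a break end, oriented to END at the junction."""
    if be.orient is Orient.LEFT:
        start = 1 if window is None else max(1, be.pos - window + 1)
        return Segment(be.chrom, start, be.pos, "+")
    length = genome.length(be.chrom)
    end = length if window is None else min(length, be.pos + window - 1)
    return Segment(be.chrom, be.pos, end, "-")


def _flank_starting_at(be: BreakEnd, genome: GenomeInfo,
                       window: Optional[int]) -> Segment:
    """Retained flank of a break end, oriented to START at the junction."""
    if be.orient is Orient.RIGHT:
        length = genome.length(be.chrom)
        end = length if window is None else min(length, be.pos + window - 1)
        return Segment(be.chrom, be.pos, end, "+")
    start = 1 if window is None else max(1, be.pos - window + 1)
    return Segment(be.chrom, start, be.pos, "-")


def trans_derivative_walks(
    cluster: ReciprocalCluster,
    gaps: dict[str, GapSegment],
    js: JunctionSet,
    genome: GenomeInfo,
    window: Optional[int] = SCORING_WINDOW,
) -> list[Walk]:
    """The two hypothetical trans derivatives, one per junction.

    Each derivative joins the retained flanks of one junction's break ends;
    with ``window=None`` flanks extend to the chromosome ends (used for
    centromere typing), otherwise they are truncated for barcode scoring.
    """
    walks = []
    for label, jid in zip(("trans_a", "trans_b"),
                          sorted(cluster.junction_ids)):
        j = js.by_id(jid)
        walks.append(Walk(
            label=label,
            segments=[_flank_ending_at(j.be1, genome, window),
                      _flank_starting_at(j.be2, genome, window)],
            junction_ids=[jid],
        ))
    return walks


def _cis_walk_through(view: _RPairView, gap: GapSegment,
                      genome: GenomeInfo, window: Optional[int],
                      label: str) -> Walk:
    """Cis derivative traversing the duplicated (+) gap between the junctions."""
    j_lo, j_hi = gap.lo_junction, gap.hi_junction
    enter = view.other_breakend(j_lo, gap)
    leave = view.other_breakend(j_hi, gap)
    return Walk(
        label=label,
        segments=[
            _flank_ending_at(enter, genome, window),
            Segment(gap.chrom, gap.lo_pos, gap.hi_pos, "+"),
            _flank_starting_at(leave, genome, window),
        ],
        junction_ids=[j_lo, j_hi],
    )


def _intact_walk(gap: GapSegment, genome: GenomeInfo,
                 window: Optional[int]) -> Walk:
    """Unrearranged reference walk covering a gap and its flanks."""
    length = genome.length(gap.chrom)
    start = 1 if window is None else max(1, gap.lo_pos - window + 1)
    end = length if window is None else min(length, gap.hi_pos + window - 1)
    return Walk(label="intact", segments=[Segment(gap.chrom, start, end, "+")],
                junction_ids=[])


def enumerate_reconstructions(
    cluster: ReciprocalCluster,
    gaps: dict[str, GapSegment],
    js: JunctionSet,
    genome: GenomeInfo,
    window: Optional[int] = SCORING_WINDOW,
) -> Reconstructions:
    """Enumerate candidate cis and trans walk sets for a reciprocal pair.

    rDups admit two cis options (the copy-paste may run through either (+)
    gap, leaving the other locus intact) plus one trans set; rDelDups admit
    one cis option (through the (+) gap, deleting the (−) gap); rDels admit
    only the trans set.
    """
    view = _RPairView(cluster, gaps, js)
    cls = cluster.rpair_class
    trans = trans_derivative_walks(cluster, gaps, js, genome, window)
    cis: list[list[Walk]] = []
    if cls is RPairClass.RDUP:
        # the copy-paste may traverse either (+) gap; the donor locus (the
        # traversed gap's own locus) is left intact
        for i, gap in enumerate(view.gaps):
            cis.append([
                _cis_walk_through(view, gap, genome, window, f"cis{i + 1}"),
                _intact_walk(gap, genome, window),
            ])
    elif cls is RPairClass.RDELDUP:
        # the (−) gap appears in no cis walk; the intact partner locus is
        # the reference around the duplicated (+) gap
        plus = next(g for g in view.gaps if g.polarity is Polarity.PLUS)
        cis.append([
            _cis_walk_through(view, plus, genome, window, "cis1"),
            _intact_walk(plus, genome, window),
        ])
    elif cls is RPairClass.RDEL:
        pass  # trans is the only phase the topology allows
    else:
        raise ValueError(f"cannot reconstruct class {cls.value}")
    return Reconstructions(rpair_id=cluster.id, rpair_class=cls,
                           cis=cis, trans=trans)


def impute_phase(cluster: ReciprocalCluster,
                 gaps: dict[str, GapSegment]) -> PhaseCall:
    """Impute cis/trans phase from gap lengths.

    rDup: cis iff the smaller log10 gap length is below 3.5; rDelDup: cis iff
    the (+)-polarity gap's log10 length is below 3.5; rDel: always trans.
    """
    cls = cluster.rpair_class
    gap_list = [gaps[g] for g in sorted(cluster.gap_ids)]
    if cls is RPairClass.RDEL:
        phase = Phase.TRANS
    elif cls is RPairClass.RDUP:
        min_log = min(math.log10(g.length) for g in gap_list)
        phase = Phase.CIS if min_log < LOG10_GAP_THRESHOLD else Phase.TRANS
    elif cls is RPairClass.RDELDUP:
        plus = next(g for g in gap_list if g.polarity is Polarity.PLUS)
        phase = (Phase.CIS if math.log10(plus.length) < LOG10_GAP_THRESHOLD
                 else Phase.TRANS)
    else:
        raise ValueError(f"cannot impute phase for class {cls.value}")
    return PhaseCall(rpair_id=cluster.id, phase=phase, method="imputed")


def _map_pieces_to_walk(walk: Walk, pieces) -> list[tuple[int, int]]:
    """Project reference intervals onto walk coordinates (all occurrences)."""
    mapped = []
    offset = 0
    for seg in walk.segments:
        for chrom, s, e in pieces:
            if chrom != seg.chrom:
                continue
            lo, hi = max(s, seg.start), min(e, seg.end)
            if lo > hi:
                continue
            if seg.strand == "+":
                mapped.append((offset + lo - seg.start + 1,
                               offset + hi - seg.start + 1))
            else:
                mapped.append((offset + seg.end - hi + 1,
                               offset + seg.end - lo + 1))
        offset += seg.length
    return sorted(mapped)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _barcode_supports_walk(walk: Walk, pieces,
                           min_side_overlap: int) -> bool:
    """True if the molecule pieces span every junction the walk traverses.

    A junction at walk coordinate c is spanned when some merged projection of
    the barcode's molecules covers [c − min_side_overlap + 1,
    c + min_side_overlap] — at least ``min_side_overlap`` retained bases on
    each side of the fusion.
    """
    offsets = walk.junction_offsets()
    if not offsets:
        return False
    merged = _merge_intervals(_map_pieces_to_walk(walk, pieces))
    for _, c in offsets:
        lo, hi = c - min_side_overlap + 1, c + min_side_overlap
        if not any(s <= lo and e >= hi for s, e in merged):
            return False
    return True


def score_walks_barcodes(
    recon: Reconstructions,
    barcodes: pd.DataFrame,
    min_side_overlap: int = MIN_SIDE_OVERLAP,
) -> PhaseCall:
    """Call cis/trans phase from linked-read barcode support.

    A barcode supports a walk when its molecules, projected onto the walk,
    span the walk's junction adjacency pattern (both junctions for a cis
    walk, one for each trans derivative). The phase is taken from the best
    supported option, comparing each individual cis walk against the two
    trans walks' supports summed; ties (including zero evidence everywhere)
    are ambiguous.
    """
    support: dict[str, int] = {}
    scored = [w for option in recon.cis for w in option
              if w.junction_ids] + list(recon.trans)
    by_barcode: dict[str, list] = {}
    for rec in barcodes.itertuples(index=False):
        by_barcode.setdefault(str(rec.barcode), []).append(
            (str(rec.chrom), int(rec.start), int(rec.end)))
    for walk in scored:
        support[walk.label] = sum(
            _barcode_supports_walk(walk, pieces, min_side_overlap)
            for pieces in by_barcode.values()
        )
    scores: dict[str, int] = {
        w.label: support[w.label]
        for option in recon.cis for w in option if w.junction_ids
    }
    if recon.trans:
        scores["trans"] = sum(support[w.label] for w in recon.trans)
    if not scores or max(scores.values()) == 0:
        phase = Phase.AMBIGUOUS
    else:
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            phase = Phase.AMBIGUOUS
        elif ranked[0][0] == "trans":
            phase = Phase.TRANS
        else:
            phase = Phase.CIS
    return PhaseCall(rpair_id=recon.rpair_id, phase=phase,
                     method="barcode", support=support)


def clip_walk_around_junctions(walk: Walk, window: int) -> Walk:
    """Restrict a walk to within ``window`` walk-bases of its junctions.

    Keeps the single walk-coordinate interval from ``window`` bases before
    the first junction to ``window`` bases after the last (segments between
    junctions are kept whole), preserving junction boundaries. Used to
    confine linked-read simulation and barcode scoring to the neighbourhood
    of the junctions being phased.
    """
    offsets = walk.junction_offsets()
    if not offsets:
        return walk
    keep_lo = max(1, offsets[0][1] - window + 1)
    keep_hi = min(walk.length, offsets[-1][1] + window)
    segments: list[Segment] = []
    junction_ids: list[Optional[str]] = []
    offset = 0
    jids = walk.junction_ids + [None]
    for seg, jid in zip(walk.segments, jids):
        seg_lo, seg_hi = offset + 1, offset + seg.length
        a, b = max(keep_lo, seg_lo), min(keep_hi, seg_hi)
        if a <= b:
            if seg.strand == "+":
                clipped = Segment(seg.chrom, seg.start + (a - seg_lo),
                                  seg.start + (b - seg_lo), "+")
            else:
                clipped = Segment(seg.chrom, seg.end - (b - seg_lo),
                                  seg.end - (a - seg_lo), "-")
            if segments:
                junction_ids.append(prev_jid)
            segments.append(clipped)
            prev_jid = jid
        offset = seg_hi
    return Walk(label=walk.label, segments=segments,
                junction_ids=junction_ids)


def _centromere_copies(walk: Walk, genome: GenomeInfo) -> Optional[int]:
    """Count centromere copies on a derivative walk.

    A segment carries a centromere copy when it covers the centromere's
    midpoint. Returns None when an involved chromosome has no centromere.
    """
    count = 0
    for seg in walk.segments:
        cen = genome.centromeres.get(seg.chrom)
        if cen is None:
            return None
        mid = (cen[0] + cen[1]) // 2
        if seg.start <= mid <= seg.end:
            count += 1
    return count


def classify_centromere_type(
    cluster: ReciprocalCluster,
    gaps: dict[str, GapSegment],
    js: JunctionSet,
    genome: GenomeInfo,
) -> OrientationType:
    """Type the centromeric orientation of a reciprocal pair.

    Builds the two hypothetical trans derivatives (flanks extended to the
    chromosome ends, using junction orientations only — phase is not an
    input) and counts centromere copies: type I iff every derivative is
    monocentric, type II otherwise (acentric or dicentric products).
    """
    walks = trans_derivative_walks(cluster, gaps, js, genome, window=None)
    counts = [_centromere_copies(w, genome) for w in walks]
    if any(c is None for c in counts):
        return OrientationType.NA
    return (OrientationType.TYPE_I if all(c == 1 for c in counts)
            else OrientationType.TYPE_II)


def phase_to_dataframe(calls: list[PhaseCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        rows.append({
            "rpair_id": call.rpair_id,
            "phase": call.phase.value,
            "method": call.method,
            "orientation_type": call.orientation_type.value,
            "support": ";".join(f"{k}={v}" for k, v in
                                sorted(call.support.items())),
        })
    return pd.DataFrame(rows)
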