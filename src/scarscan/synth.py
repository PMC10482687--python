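"""Synthetic genomes, planted rearrangements and linked-read simulation.

Everything the other modules consume can be generated here with ground
truth: reference sequences with centromeres, reciprocal pairs of every class
x phase x centromeric orientation (with the junctions, gap intervals,
copy-number track and derivative walks they imply), scattered background
junctions, linked-read molecule tables sampled along derivative walks, and
homeology-bearing deletion fixtures. All generators are deterministic given
a seed.

Planted reciprocal pairs are interchromosomal, with both loci on q-arms
(right of the mid-chromosome centromere); the direct junction pairing then
realises the type I centromeric orientation and the inverted pairing
type II.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    BreakEnd, CNProfile, CNSegment, GenomeInfo, Junction, JunctionSet, Orient,
)
from .phasing import OrientationType, Phase, Segment, Walk
from .rpairs import Polarity, RPairClass

MOL_LEN_MEDIAN = 24_400  # target median molecule length, bases
MOL_LEN_MIN = 500  # molecules shorter than this are discarded
BACKGROUND_CLEARANCE = 2_000_000  # background break ends keep this distance


# ---------------------------------------------------------------------------
# reference and genome generation

def make_genome_info(
    n_chrom: int = 2,
    lengths: Sequence[int] = (40_000_000, 40_000_000),
    centromere_halfwidth: int = 50_000,
) -> GenomeInfo:
    """Chromosome metadata with a centromere at each chromosome's midpoint."""
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    chrom_lengths = dict(zip(names, lengths))
    centromeres = {}
    for name, length in chrom_lengths.items():
        hw = min(centromere_halfwidth, length // 2 - 1)
        centromeres[name] = (length // 2 - hw, length // 2 + hw)
    return GenomeInfo(names, chrom_lengths, centromeres)


def make_reference(
    seed: int,
    n_chrom: int = 2,
    lengths: Sequence[int] = (1_000_000, 1_000_000),
    gc: float = 0.41,
    centromere_halfwidth: int = 10_000,
) -> tuple[dict[str, str], GenomeInfo]:
    """Deterministic i.i.d. reference sequences plus genome metadata.

    Base composition is symmetric within the GC and AT pairs. Returns a
    plain chrom -> sequence mapping (sliceable like an indexed FASTA).
    """
    rng = np.random.default_rng(seed)
    genome = make_genome_info(n_chrom, lengths, centromere_halfwidth)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name in genome.chrom_names:
        draws = rng.choice(alphabet, size=genome.length(name), p=probs)
        seqs[name] = draws.tobytes().decode("ascii")
    return seqs, genome


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# reciprocal-pair planting

_GAP_POLARITIES = {
    RPairClass.RDUP: (Polarity.PLUS, Polarity.PLUS),
    RPairClass.RDEL: (Polarity.MINUS, Polarity.MINUS),
    RPairClass.RDELDUP: (Polarity.MINUS, Polarity.PLUS),
}


@dataclass
class PlantedRPair:
    """Ground truth for one planted reciprocal pair."""

    id: str
    rpair_class: RPairClass
    phase: Phase
    orientation_type: OrientationType
    junctions: list[Junction]
    gaps: list[tuple[str, int, int, Polarity]]  # (chrom, lo, hi, polarity)
    walks: list[Walk]  # derivative allele(s) + intact partner for this phase
    imputable_phase: Phase = Phase.AMBIGUOUS  # what the length rule will say

    @property
    def junction_ids(self) -> frozenset[str]:
        return frozenset(j.id for j in self.junctions)


def _gap_breakends(chrom: str, lo: int, hi: int, polarity: Polarity):
    """The two break ends bounding a gap of the given polarity."""
    if polarity is Polarity.PLUS:
        return BreakEnd(chrom, lo, Orient.RIGHT), BreakEnd(chrom, hi, Orient.LEFT)
    return BreakEnd(chrom, lo, Orient.LEFT), BreakEnd(chrom, hi, Orient.RIGHT)


def _expected_imputed_phase(cls: RPairClass, len_b: int, len_e: int,
                            pol_b: Polarity) -> Phase:
    threshold = 10 ** 3.5
    if cls is RPairClass.RDEL:
        return Phase.TRANS
    if cls is RPairClass.RDUP:
        return Phase.CIS if min(len_b, len_e) < threshold else Phase.TRANS
    plus_len = len_e if pol_b is Polarity.MINUS else len_b
    return Phase.CIS if plus_len < threshold else Phase.TRANS


def plant_rpair(
    genome: GenomeInfo,
    rpair_class: RPairClass,
    phase: Phase,
    gap_lengths: tuple[int, int],
    orientation_type: OrientationType = OrientationType.TYPE_I,
    loci: Optional[tuple[tuple[str, int], tuple[str, int]]] = None,
    event_id: str = "rp0",
) -> PlantedRPair:
    """Plant a reciprocal pair and derive its junctions, gaps and walks.

    ``gap_lengths`` gives the lengths of the first and second gap; for cis
    rDups the copy-paste runs through the second gap, so callers wanting an
    imputable cis event make the second gap short. ``loci`` fixes the start
    coordinates of the two gaps (defaults to mid-q-arm positions on the
    first two chromosomes). Requesting a cis rDel raises: the rDel topology
    admits only trans derivatives.
    """
    if rpair_class not in _GAP_POLARITIES:
        raise ValueError(f"cannot plant class {rpair_class}")
    if rpair_class is RPairClass.RDEL and phase is Phase.CIS:
        raise ValueError("cis rDel is topologically impossible")
    if phase not in (Phase.CIS, Phase.TRANS):
        raise ValueError(f"cannot plant phase {phase}")
    pol_b, pol_e = _GAP_POLARITIES[rpair_class]
    len_b, len_e = gap_lengths
    if loci is None:
        c1, c2 = genome.chrom_names[0], genome.chrom_names[1]
        b_lo = genome.centromeres[c1][1] + 5_000_000
        e_lo = genome.centromeres[c2][1] + 5_000_000
    else:
        (c1, b_lo), (c2, e_lo) = loci
    b_hi, e_hi = b_lo + len_b - 1, e_lo + len_e - 1
    for chrom, hi in ((c1, b_hi), (c2, e_hi)):
        if hi >= genome.length(chrom):
            raise ValueError(f"gap runs past the end of {chrom}")

    b1, b2 = _gap_breakends(c1, b_lo, b_hi, pol_b)  # (lo end, hi end)
    e1, e2 = _gap_breakends(c2, e_lo, e_hi, pol_e)
    inverted = orientation_type is OrientationType.TYPE_II
    # direct pairing joins opposite gap ends (lo<->hi); inverted joins like
    # ends, flipping the second locus's strand in every derivative
    if rpair_class is RPairClass.RDUP:
        pairs = ((b2, e2), (b1, e1)) if inverted else ((b2, e1), (b1, e2))
    elif rpair_class is RPairClass.RDEL:
        pairs = ((b1, e1), (b2, e2)) if inverted else ((b1, e2), (b2, e1))
    else:  # rDelDup: b MINUS, e PLUS
        pairs = ((b1, e2), (b2, e1)) if inverted else ((b1, e1), (b2, e2))
    j1 = Junction(f"{event_id}_j1", *pairs[0])
    j2 = Junction(f"{event_id}_j2", *pairs[1])

    walks = _derivative_walks(
        genome, rpair_class, phase, inverted,
        c1, b_lo, b_hi, c2, e_lo, e_hi, j1.id, j2.id, event_id)
    return PlantedRPair(
        id=event_id, rpair_class=rpair_class, phase=phase,
        orientation_type=orientation_type,
        junctions=[j1, j2],
        gaps=[(c1, b_lo, b_hi, pol_b), (c2, e_lo, e_hi, pol_e)],
        walks=walks,
        imputable_phase=_expected_imputed_phase(rpair_class, len_b, len_e,
                                                pol_b),
    )


def _derivative_walks(genome, cls, phase, inverted,
                      c1, b_lo, b_hi, c2, e_lo, e_hi,
                      j1_id, j2_id, event_id) -> list[Walk]:
    """Full-length derivative walk set for the planted phase.

    The set contains the rearranged allele(s) plus the intact partner
    chromosome of the unrearranged locus; unrearranged homologs can be added
    separately with :func:`reference_walks`.
    """
    L1, L2 = genome.length(c1), genome.length(c2)
    e_fwd = Segment(c2, e_lo, e_hi, "+")
    e_rev = Segment(c2, e_lo, e_hi, "-")

    def walk(label, segs, jids):
        return Walk(label=f"{event_id}_{label}", segments=segs,
                    junction_ids=jids)

    if cls is RPairClass.RDUP:
        if phase is Phase.CIS:
            mid = e_rev if inverted else e_fwd
            return [
                walk("cis", [Segment(c1, 1, b_hi, "+"), mid,
                             Segment(c1, b_lo, L1, "+")], [j1_id, j2_id]),
                walk("intact", [Segment(c2, 1, L2, "+")], []),
            ]
        if inverted:
            return [
                walk("trans_a", [Segment(c1, 1, b_hi, "+"),
                                 Segment(c2, 1, e_hi, "-")], [j1_id]),
                walk("trans_b", [Segment(c2, e_lo, L2, "-"),
                                 Segment(c1, b_lo, L1, "+")], [j2_id]),
            ]
        return [
            walk("trans_a", [Segment(c1, 1, b_hi, "+"),
                             Segment(c2, e_lo, L2, "+")], [j1_id]),
            walk("trans_b", [Segment(c2, 1, e_hi, "+"),
                             Segment(c1, b_lo, L1, "+")], [j2_id]),
        ]
    if cls is RPairClass.RDELDUP:
        if phase is Phase.CIS:
            mid = e_rev if inverted else e_fwd
            return [
                walk("cis", [Segment(c1, 1, b_lo, "+"), mid,
                             Segment(c1, b_hi, L1, "+")], [j1_id, j2_id]),
                walk("intact", [Segment(c2, 1, L2, "+")], []),
            ]
        if inverted:
            return [
                walk("trans_a", [Segment(c1, 1, b_lo, "+"),
                                 Segment(c2, 1, e_hi, "-")], [j1_id]),
                walk("trans_b", [Segment(c2, e_lo, L2, "-"),
                                 Segment(c1, b_hi, L1, "+")], [j2_id]),
            ]
        return [
            walk("trans_a", [Segment(c1, 1, b_lo, "+"),
                             Segment(c2, e_lo, L2, "+")], [j1_id]),
            walk("trans_b", [Segment(c2, 1, e_hi, "+"),
                             Segment(c1, b_hi, L1, "+")], [j2_id]),
        ]
    # rDel: trans only
    if inverted:
        return [
            walk("trans_a", [Segment(c1, 1, b_lo, "+"),
                             Segment(c2, 1, e_lo, "-")], [j1_id]),
            walk("trans_b", [Segment(c2, e_hi, L2, "-"),
                             Segment(c1, b_hi, L1, "+")], [j2_id]),
        ]
    return [
        walk("trans_a", [Segment(c1, 1, b_lo, "+"),
                         Segment(c2, e_hi, L2, "+")], [j1_id]),
        walk("trans_b", [Segment(c2, 1, e_lo, "+"),
                         Segment(c1, b_hi, L1, "+")], [j2_id]),
    ]


def reference_walks(genome: GenomeInfo,
                    chroms: Optional[Sequence[str]] = None) -> list[Walk]:
    """One full-chromosome reference walk per (homolog) chromosome."""
    chroms = list(chroms) if chroms is not None else list(genome.chrom_names)
    return [
        Walk(label=f"homolog_{c}",
             segments=[Segment(c, 1, genome.length(c), "+")],
             junction_ids=[])
        for c in chroms
    ]


def planted_cn_profile(genome: GenomeInfo,
                       events: Sequence[PlantedRPair]) -> CNProfile:
    """Integer purity-1 CN track: baseline 1+1, (+) gaps 2+1, (−) gaps 1+0."""
    by_chrom: dict[str, list[tuple[int, int, Polarity]]] = {}
    for ev in events:
        for chrom, lo, hi, pol in ev.gaps:
            by_chrom.setdefault(chrom, []).append((lo, hi, pol))
    segments: list[CNSegment] = []
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        cursor = 1
        for lo, hi, pol in sorted(by_chrom.get(chrom, [])):
            if lo > cursor:
                segments.append(CNSegment(chrom, cursor, lo - 1, 2, 1, 1))
            if pol is Polarity.PLUS:
                segments.append(CNSegment(chrom, lo, hi, 3, 2, 1))
            else:
                segments.append(CNSegment(chrom, lo, hi, 1, 1, 0))
            cursor = hi + 1
        if cursor <= length:
            segments.append(CNSegment(chrom, cursor, length, 2, 1, 1))
    return CNProfile(segments)


# ---------------------------------------------------------------------------
# multi-event samples with background junctions

@dataclass
class SimulatedSample:
    junctions: JunctionSet
    cn: CNProfile
    events: list[PlantedRPair]
    background_ids: frozenset[str] = field(default_factory=frozenset)


def _event_grid(genome: GenomeInfo, n_events: int,
                spacing: int = 2_200_000) -> list[tuple[tuple[str, int],
                                                        tuple[str, int]]]:
    """Allocate non-interfering q-arm locus pairs across chromosome pairs."""
    names = genome.chrom_names
    if len(names) < 2:
        raise ValueError("need at least two chromosomes")
    pairs = [(names[i], names[i + 1]) for i in range(0, len(names) - 1, 2)]
    slots = []
    for c1, c2 in pairs:
        start1 = genome.centromeres[c1][1] + 1_000_000
        start2 = genome.centromeres[c2][1] + 1_000_000
        stop1 = genome.length(c1) - spacing
        stop2 = genome.length(c2) - spacing
        k = 0
        while start1 + k * spacing < stop1 and start2 + k * spacing < stop2:
            slots.append(((c1, start1 + k * spacing),
                          (c2, start2 + k * spacing)))
            k += 1
    if len(slots) < n_events:
        raise ValueError(
            f"genome accommodates only {len(slots)} events, need {n_events}")
    return slots[:n_events]


_EVENT_CYCLE = [
    (RPairClass.RDUP, Phase.CIS, OrientationType.TYPE_I, (30_000, 500)),
    (RPairClass.RDUP, Phase.CIS, OrientationType.TYPE_II, (30_000, 500)),
    (RPairClass.RDUP, Phase.TRANS, OrientationType.TYPE_I, (30_000, 20_000)),
    (RPairClass.RDUP, Phase.TRANS, OrientationType.TYPE_II, (30_000, 20_000)),
    (RPairClass.RDELDUP, Phase.CIS, OrientationType.TYPE_I, (8_000, 500)),
    (RPairClass.RDELDUP, Phase.CIS, OrientationType.TYPE_II, (8_000, 500)),
    (RPairClass.RDELDUP, Phase.TRANS, OrientationType.TYPE_I, (8_000, 20_000)),
    (RPairClass.RDELDUP, Phase.TRANS, OrientationType.TYPE_II, (8_000, 20_000)),
    (RPairClass.RDEL, Phase.TRANS, OrientationType.TYPE_I, (7, 6)),
    (RPairClass.RDEL, Phase.TRANS, OrientationType.TYPE_II, (7, 6)),
]


def simulate_sample(
    seed: int,
    genome: Optional[GenomeInfo] = None,
    n_events: int = 10,
    n_background: int = 20,
    sample_id: str = "synthetic",
) -> SimulatedSample:
    """A sample cycling through every class x phase x orientation combination.

    Events use the study gap-length regimes: short (< 10^3.5 bases) second
    gaps for cis events ('long-short'), long gaps for trans ('long-long'),
    and few-bp gaps for rDels (balanced-translocation-like). Background
    junctions are scattered with break ends at least 2 Mbp from everything
    else, so they produce no gap candidates.
    """
    if genome is None:
        n_chrom = max(4, 2 * math.ceil(n_events / 8))
        genome = make_genome_info(n_chrom, [40_000_000] * n_chrom)
    rng = np.random.default_rng(seed)
    slots = _event_grid(genome, n_events)
    events = []
    for i, slot in enumerate(slots):
        cls, phase, otype, gap_lengths = _EVENT_CYCLE[i % len(_EVENT_CYCLE)]
        events.append(plant_rpair(
            genome, cls, phase, gap_lengths, otype,
            loci=slot, event_id=f"ev{i:03d}"))
    junctions = [j for ev in events for j in ev.junctions]
    background = _background_junctions(genome, n_background, events, rng)
    junctions += background
    return SimulatedSample(
        junctions=JunctionSet(sample_id, junctions, genome),
        cn=planted_cn_profile(genome, events),
        events=events,
        background_ids=frozenset(j.id for j in background),
    )


def _background_junctions(genome, n, events, rng) -> list[Junction]:
    """Scattered junctions whose break ends admit no gap candidates.

    Break ends keep 2 Mbp of clearance from planted gaps (so truth labels
    stay unambiguous) and just over the 1-Mbp gap cap from each other (so no
    background pair forms a gap candidate).
    """
    planted: list[tuple[str, int]] = []
    for ev in events:
        for j in ev.junctions:
            for be in j.break_ends():
                planted.append((be.chrom, be.pos))
    placed: list[tuple[str, int]] = []
    mutual = 1_100_000  # just over the gap-length cap

    def clear(chrom: str, pos: int) -> bool:
        return all(c != chrom or abs(p - pos) >= BACKGROUND_CLEARANCE
                   for c, p in planted) and all(
            c != chrom or abs(p - pos) >= mutual for c, p in placed)

    out = []
    names = list(genome.chrom_names)
    attempts = 0
    while len(out) < n and attempts < 50_000:
        attempts += 1
        c1 = str(rng.choice(names))
        c2 = str(rng.choice(names))
        p1 = int(rng.integers(1_000_000, genome.length(c1) - 1_000_000))
        p2 = int(rng.integers(1_000_000, genome.length(c2) - 1_000_000))
        if not clear(c1, p1) or not clear(c2, p2):
            continue
        if c1 == c2 and abs(p2 - p1) < mutual:
            continue
        o1 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        o2 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        out.append(Junction(f"bg{len(out):03d}",
                            BreakEnd(c1, p1, o1), BreakEnd(c2, p2, o2)))
        placed += [(c1, p1), (c2, p2)]
    if len(out) < n:
        raise RuntimeError("could not place background junctions")
    return out


# ---------------------------------------------------------------------------
# linked-read molecule simulation

def simulate_linked_reads(
    walks: Sequence[Walk],
    physical_coverage: float,
    median_mol_len: int = MOL_LEN_MEDIAN,
    min_mol_len: int = MOL_LEN_MIN,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample barcoded molecules along derivative walks.

    Molecule lengths are exponential, scaled so the post-truncation median
    matches ``median_mol_len``, and left-truncated at ``min_mol_len``. Each
    molecule carries a unique barcode and is split at walk junction
    boundaries into its reference-coordinate pieces (columns: barcode,
    chrom, start, end, 1-based inclusive).
    """
    rng = np.random.default_rng(seed)
    scale = (median_mol_len - min_mol_len) / math.log(2)
    rows = []
    mol_idx = 0
    for walk in walks:
        n_mol = int(round(physical_coverage * walk.length
                          / (scale + min_mol_len)))
        if n_mol == 0:
            continue
        starts = rng.integers(1, walk.length + 1, size=n_mol)
        lengths = min_mol_len + rng.exponential(scale, size=n_mol)
        for s, ln in zip(starts, lengths):
            lo = int(s)
            hi = min(walk.length, lo + int(ln) - 1)
            if hi - lo + 1 < min_mol_len:
                continue
            barcode = f"BC{mol_idx:07d}"
            mol_idx += 1
            for chrom, rs, re_ in _walk_interval_to_reference(walk, lo, hi):
                rows.append((barcode, chrom, rs, re_))
    return pd.DataFrame(rows, columns=["barcode", "chrom", "start", "end"])


def _walk_interval_to_reference(walk: Walk, lo: int, hi: int):
    """Split a walk-coordinate interval into reference-coordinate pieces."""
    offset = 0
    for seg in walk.segments:
        seg_lo, seg_hi = offset + 1, offset + seg.length
        a, b = max(lo, seg_lo), min(hi, seg_hi)
        if a <= b:
            if seg.strand == "+":
                yield (seg.chrom, seg.start + (a - seg_lo),
                       seg.start + (b - seg_lo))
            else:
                yield (seg.chrom, seg.end - (b - seg_lo),
                       seg.end - (a - seg_lo))
        offset = seg_hi


# ---------------------------------------------------------------------------
# homeology fixtures

@dataclass
class PlantedHomeology:
    junction: Junction
    tract_len: int
    identity: float
    span: int
    expect_detection: bool


def plant_homeology_deletion(
    seqs: dict[str, str],
    chrom: str,
    p1: int,
    span: int,
    tract_len: int,
    identity: float,
    seed: int = 0,
    junction_id: str = "homeo0",
) -> PlantedHomeology:
    """Write a degenerate repeat pair flanking a planted deletion junction.

    A random tract is written straddling break end p1 and a copy with
    per-base substitution rate 1 − identity straddling p2 = p1 + span, then
    a DEL-like junction joining the two break ends is returned. Detection is
    expected when identity is at least 0.8 (the annealing-competence cut);
    lower identities are allowed but marked as expected non-detections.
    """
    if span <= tract_len:
        raise ValueError("deletion span must exceed the repeat tract length")
    rng = np.random.default_rng(seed)
    p2 = p1 + span
    half = tract_len // 2
    bases = "ACGT"
    tract = "".join(str(b) for b in rng.choice(list(bases), size=tract_len))
    copy = list(tract)
    # substitutions at a fixed period with a random phase: the divergence of
    # the copy is then a guaranteed local property of every sub-window, so
    # the truth label (detectable or not) is exact rather than a draw
    if identity < 1.0:
        period = max(2, round(1.0 / (1.0 - identity)))
        phase_off = int(rng.integers(period))
        for i in range(phase_off, tract_len, period):
            copy[i] = str(rng.choice([b for b in bases if b != copy[i]]))
    seq = list(seqs[chrom])
    start1, start2 = p1 - 1 - half, p2 - 1 - half  # tract centred on break end
    if start1 < 0 or start2 + tract_len > len(seq):
        raise ValueError("tract does not fit on the contig")
    seq[start1:start1 + tract_len] = tract
    seq[start2:start2 + tract_len] = copy
    seqs[chrom] = "".join(seq)
    junction = Junction(junction_id,
                        BreakEnd(chrom, p1, Orient.LEFT),
                        BreakEnd(chrom, p2, Orient.RIGHT))
    return PlantedHomeology(junction=junction, tract_len=tract_len,
                            identity=identity, span=span,
                            expect_detection=identity >= 0.8)


# ---------------------------------------------------------------------------
# feature-level cohorts for the classifier

_COHORT_RATES = {
    # class-conditional Poisson rates / Beta parameters for scar features
    "BRCA1d": dict(n_rDup=8.0, n_rDel=0.1, n_rDelDup=2.0, n_homeo_del=0.3,
                   n_dup_sizegate=20.0, hrd_loh_index=15.0, mh=(6.0, 4.0)),
    "BRCA2d": dict(n_rDup=0.1, n_rDel=5.0, n_rDelDup=2.0, n_homeo_del=4.0,
                   n_dup_sizegate=2.0, hrd_loh_index=12.0, mh=(6.0, 4.0)),
    "HRP": dict(n_rDup=0.1, n_rDel=0.1, n_rDelDup=0.1, n_homeo_del=0.1,
                n_dup_sizegate=1.0, hrd_loh_index=1.5, mh=(1.0, 9.0)),
}


def simulate_feature_cohort(
    seed: int,
    n_per_class: int = 60,
    classes: Sequence[str] = ("BRCA1d", "BRCA2d", "HRP"),
) -> tuple[pd.DataFrame, list[str]]:
    """Feature-level synthetic cohort with cleanly separated scar profiles.

    Counts are Poisson with class-conditional rates (rDup-rich BRCA1-type,
    rDel/homeologous-deletion-rich BRCA2-type, scar-poor HR-proficient);
    the microhomology fraction is Beta-distributed. Returns a feature frame
    indexed by sample id plus the matching label list.
    """
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    count_keys = ["n_rDup", "n_rDel", "n_rDelDup", "n_homeo_del",
                  "n_dup_sizegate", "hrd_loh_index"]
    for cls in classes:
        rates = _COHORT_RATES[cls]
        for i in range(n_per_class):
            row = {k: int(rng.poisson(rates[k])) for k in count_keys}
            a, b = rates["mh"]
            row["mh_del_fraction"] = float(rng.beta(a, b))
            rows.append(row)
            labels.append(cls)
            index.append(f"{cls}_{i:03d}")
    return pd.DataFrame(rows, index=index), labels


def simulate_importance_fixture(
    seed: int,
    n_per_class: int = 40,
    informative_rates: tuple[float, float] = (8.0, 0.5),
) -> tuple[pd.DataFrame, list[str]]:
    """Two-class cohort where a single feature carries all the signal.

    ``n_rDup`` is Poisson with class-conditional rates (BRCA1-type vs
    BRCA2-type); the remaining scar features are class-independent nuisance
    counts and ``noise`` is a pure standard-normal column. Used to check
    that permutation importance ranks a planted informative feature above
    injected noise.
    """
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for cls, rate in zip(("BRCA1d", "BRCA2d"), informative_rates):
        for i in range(n_per_class):
            rows.append({
                "n_rDup": int(rng.poisson(rate)),
                "n_rDel": int(rng.poisson(2.0)),
                "n_rDelDup": int(rng.poisson(2.0)),
                "n_homeo_del": int(rng.poisson(2.0)),
                "mh_del_fraction": float(rng.beta(3.0, 5.0)),
                "noise": float(rng.normal()),
            })
            labels.append(cls)
            index.append(f"{cls}_{i:03d}")
    return pd.DataFrame(rows, index=index), labels
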