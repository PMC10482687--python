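"""Reciprocal-pair detection from junction topology.

A *gap segment* is a short reference interval joining reference-consecutive
break ends of two distinct junctions with opposite orientations. Its polarity
records the local topology: (+) when the junctions attach directly to the gap
(mass balance duplicates the gap), (−) when they attach to the flanking
segments (the gap is lost). Junctions sharing gap segments are clustered;
cyclic clusters with exactly two gaps are reciprocal pairs (rPairs), typed by
their gap polarities as rDup (+/+), rDel (−/−) or rDelDup (+/−).

Short gap candidates stand out against a per-sample exponential background on
candidate lengths; the background model is confirmatory — by default the
length cap alone selects candidates.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import CNProfile, JunctionSet, Orient, SpanClass

logger = logging.getLogger(__name__)

MAX_GAP_LENGTH = 1_000_000  # 1-Mbp cap on gap segment length
MIN_FIT_N = 10  # below this, the exponential background is skipped


class Polarity(enum.Enum):
    PLUS = "+"
    MINUS = "-"


class RPairClass(enum.Enum):
    RDUP = "rDup"
    RDEL = "rDel"
    RDELDUP = "rDelDup"
    OTHER = "other"
    NA = "NA"


class CNConsistency(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    UNKNOWN = "unknown"


@dataclass
class GapSegment:
    """Reference interval between reference-consecutive break ends.

    ``lo_junction``/``hi_junction`` identify the junction owning the break end
    at ``lo_pos``/``hi_pos`` respectively; polarity is PLUS when the low break
    end retains its right side (junctions attached to the gap itself).
    """

    id: str
    chrom: str
    lo_pos: int
    hi_pos: int
    polarity: Polarity
    lo_junction: str
    hi_junction: str
    pval: float = float("nan")
    qval: float = float("nan")
    significant: bool = True

    @property
    def length(self) -> int:
        return self.hi_pos - self.lo_pos + 1

    @property
    def junction_ids(self) -> frozenset[str]:
        return frozenset((self.lo_junction, self.hi_junction))


@dataclass
class ReciprocalCluster:
    """Connected component of the bipartite junction–gap graph."""

    id: str
    junction_ids: frozenset[str]
    gap_ids: frozenset[str]
    cyclic: bool
    rpair_class: RPairClass = RPairClass.NA
    span_class: Optional[SpanClass] = None
    cn_consistency: dict[str, CNConsistency] = field(default_factory=dict)


def _breakend_records(js: JunctionSet):
    recs = []
    for j in js.junctions:
        for be in j.break_ends():
            recs.append((be.chrom, be.pos, be.orient, j.id))
    return recs


def _gap_polarity(lo_orient: Orient, hi_orient: Orient) -> Polarity:
    # PLUS: break ends retain the gap itself (RIGHT at low, LEFT at high).
    return Polarity.PLUS if lo_orient is Orient.RIGHT else Polarity.MINUS


def enumerate_gap_candidates(
    js: JunctionSet,
    max_gap_length: int = MAX_GAP_LENGTH,
    per_breakend_filter: bool = True,
) -> list[GapSegment]:
    """Enumerate gap-segment candidates between break ends of distinct junctions.

    A candidate pairs two break ends that are (a) on the same chromosome with
    gap length (hi − lo + 1) at most ``max_gap_length``, (b) from distinct
    junctions, (c) oppositely oriented, and (d) reference-consecutive — no
    third break end strictly between them. When positions coincide, the
    RIGHT-oriented break end is taken as the low end (the gap is then a
    single retained base, polarity PLUS).

    With ``per_breakend_filter`` each break end keeps only its shortest gap
    (tie broken toward the leftmost partner); a candidate survives only if it
    is the kept gap of both its break ends. This prevents a single junction
    from joining more than two gaps through chains of nearby break ends.
    """
    recs = _breakend_records(js)
    positions = sorted({(c, p) for c, p, _, _ in recs})

    def consecutive(chrom: str, lo: int, hi: int) -> bool:
        return not any(c == chrom and lo < p < hi for c, p in positions)

    candidates: list[tuple] = []  # (chrom, lo, hi, lo_orient, lo_jid, hi_jid)
    n = len(recs)
    for a in range(n):
        for b in range(a + 1, n):
            ca, pa, oa, ja = recs[a]
            cb, pb, ob, jb = recs[b]
            if ca != cb or ja == jb or oa == ob:
                continue
            if pa < pb or (pa == pb and oa is Orient.RIGHT):
                lo, hi, olo, ohi, jlo, jhi = pa, pb, oa, ob, ja, jb
            else:
                lo, hi, olo, ohi, jlo, jhi = pb, pa, ob, oa, jb, ja
            if hi - lo + 1 > max_gap_length:
                continue
            if not consecutive(ca, lo, hi):
                continue
            candidates.append((ca, lo, hi, olo, jlo, jhi, a, b))

    if per_breakend_filter:
        best: dict[int, tuple] = {}
        for cand in candidates:
            length = cand[2] - cand[1] + 1
            for endpoint, partner in ((cand[6], cand[7]), (cand[7], cand[6])):
                partner_pos = recs[partner][1]
                key = (length, partner_pos, recs[partner][3])
                if endpoint not in best or key < best[endpoint][0]:
                    best[endpoint] = (key, cand)
        candidates = [
            cand for cand in candidates
            if best[cand[6]][1] is cand and best[cand[7]][1] is cand
        ]

    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[4], c[5]))
    gaps = []
    for i, (chrom, lo, hi, olo, jlo, jhi, _, _) in enumerate(candidates):
        gaps.append(
            GapSegment(
                id=f"gap{i:04d}", chrom=chrom, lo_pos=lo, hi_pos=hi,
                polarity=_gap_polarity(olo, Orient.LEFT if olo is Orient.RIGHT
                                       else Orient.RIGHT),
                lo_junction=jlo, hi_junction=jhi,
            )
        )
    return gaps


@dataclass
class BackgroundFit:
    rate: Optional[float]
    pvals: np.ndarray
    qvals: np.ndarray
    flags: np.ndarray
    fitted: bool


def fit_gap_background(
    lengths: Sequence[float],
    fdr: float = 0.10,
    min_fit_n: int = MIN_FIT_N,
) -> BackgroundFit:
    """Fit an exponential to candidate gap lengths; flag short outliers.

    The maximum-likelihood rate is 1/mean. Each candidate gets a left-tail
    p-value 1 − exp(−rate·length), Benjamini–Hochberg adjusted; flags mark
    q < fdr. With fewer than ``min_fit_n`` candidates the model is skipped
    and every candidate is flagged (the length cap alone governs).
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    if n < min_fit_n:
        logger.warning(
            "only %d gap candidates (< %d); exponential background skipped",
            n, min_fit_n,
        )
        nan = np.full(n, np.nan)
        return BackgroundFit(None, nan, nan.copy(), np.ones(n, dtype=bool), False)
    rate = 1.0 / lengths.mean()
    pvals = 1.0 - np.exp(-rate * lengths)
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return BackgroundFit(rate, pvals, qvals, qvals < fdr, True)


def apply_background(
    gaps: list[GapSegment], fdr: float = 0.10, min_fit_n: int = MIN_FIT_N
) -> BackgroundFit:
    """Annotate gap segments in place with background p/q-values and flags."""
    fit = fit_gap_background([g.length for g in gaps], fdr, min_fit_n)
    for g, p, q, f in zip(gaps, fit.pvals, fit.qvals, fit.flags):
        g.pval, g.qval, g.significant = float(p), float(q), bool(f)
    return fit


def cluster_reciprocal(
    js: JunctionSet, gaps: list[GapSegment]
) -> list[ReciprocalCluster]:
    """Cluster junctions linked by shared gap segments.

    Clusters are connected components of the bipartite junction–gap graph.
    A cluster is cyclic when every member junction touches exactly two gap
    segments; cyclic clusters with exactly two gaps are classified as rPairs.
    """
    graph = nx.Graph()
    gap_by_id = {g.id: g for g in gaps}
    for g in gaps:
        graph.add_node(("gap", g.id))
        for jid in (g.lo_junction, g.hi_junction):
            graph.add_edge(("junction", jid), ("gap", g.id))
    clusters = []
    components = sorted(
        nx.connected_components(graph),
        key=lambda comp: min(node[1] for node in comp),
    )
    for i, comp in enumerate(components):
        jids = frozenset(n[1] for n in comp if n[0] == "junction")
        gids = frozenset(n[1] for n in comp if n[0] == "gap")
        cyclic = all(graph.degree(("junction", jid)) == 2 for jid in jids)
        cluster = ReciprocalCluster(
            id=f"cluster{i:04d}", junction_ids=jids, gap_ids=gids, cyclic=cyclic
        )
        cluster.rpair_class = classify_rpair(cluster, gap_by_id)
        cluster.span_class = _dominant_span_class(js, jids)
        clusters.append(cluster)
    return clusters


def classify_rpair(
    cluster: ReciprocalCluster, gaps: dict[str, GapSegment]
) -> RPairClass:
    """Type a cyclic two-gap cluster by its gap polarities.

    Two (+) gaps make an rDup, two (−) gaps an rDel, one of each an rDelDup.
    Anything else (non-cyclic, or a larger cyclic cluster) is NA.
    """
    if not cluster.cyclic or len(cluster.gap_ids) != 2 \
            or len(cluster.junction_ids) != 2:
        return RPairClass.NA
    pols = sorted(gaps[g].polarity.value for g in cluster.gap_ids)
    if pols == ["+", "+"]:
        return RPairClass.RDUP
    if pols == ["-", "-"]:
        return RPairClass.RDEL
    return RPairClass.RDELDUP


def _dominant_span_class(js: JunctionSet, jids) -> Optional[SpanClass]:
    classes = [js.by_id(j).span_class for j in sorted(jids)]
    if not classes:
        return None
    counts: dict[SpanClass, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    return max(counts, key=lambda c: (counts[c], -classes.index(c)))


def validate_cn_polarity(
    cluster: ReciprocalCluster,
    gaps: dict[str, GapSegment],
    cn: CNProfile,
) -> dict[str, CNConsistency]:
    """Check each gap's polarity against copy-number mass balance.

    A (+) gap should be a copy gain relative to both flanks; a (−) gap a
    loss. Ties are inconsistent; missing coverage yields 'unknown'.
    """
    result = {}
    for gid in sorted(cluster.gap_ids):
        g = gaps[gid]
        mid = (g.lo_pos + g.hi_pos) // 2
        gap_cn = cn.total_cn_at(g.chrom, mid)
        left_cn = cn.total_cn_at(g.chrom, g.lo_pos - 1)
        right_cn = cn.total_cn_at(g.chrom, g.hi_pos + 1)
        if gap_cn is None or left_cn is None or right_cn is None:
            result[gid] = CNConsistency.UNKNOWN
        elif g.polarity is Polarity.PLUS:
            result[gid] = (
                CNConsistency.CONSISTENT
                if gap_cn > max(left_cn, right_cn)
                else CNConsistency.INCONSISTENT
            )
        else:
            result[gid] = (
                CNConsistency.CONSISTENT
                if gap_cn < min(left_cn, right_cn)
                else CNConsistency.INCONSISTENT
            )
    cluster.cn_consistency = result
    return result


@dataclass
class RPairResult:
    gaps: list[GapSegment]
    clusters: list[ReciprocalCluster]
    background: Optional[BackgroundFit] = None

    @property
    def gap_by_id(self) -> dict[str, GapSegment]:
        return {g.id: g for g in self.gaps}

    def rpairs(self) -> list[ReciprocalCluster]:
        return [c for c in self.clusters if c.rpair_class in
                (RPairClass.RDUP, RPairClass.RDEL, RPairClass.RDELDUP)]


def call_rpairs(
    js: JunctionSet,
    max_gap_length: int = MAX_GAP_LENGTH,
    background_fdr: Optional[float] = None,
    cn: Optional[CNProfile] = None,
) -> RPairResult:
    """End-to-end reciprocal-pair calling on a junction set.

    When ``background_fdr`` is given, gap candidates are additionally
    filtered to those flagged significant under the exponential background;
    by default the 1-Mbp length cap alone selects candidates and the model
    only annotates them.
    """
    gaps = enumerate_gap_candidates(js, max_gap_length=max_gap_length)
    fit = apply_background(gaps, fdr=background_fdr or 0.10)
    if background_fdr is not None and fit.fitted:
        gaps = [g for g in gaps if g.significant]
    clusters = cluster_reciprocal(js, gaps)
    if cn is not None:
        gap_by_id = {g.id: g for g in gaps}
        for cluster in clusters:
            validate_cn_polarity(cluster, gap_by_id, cn)
    return RPairResult(gaps=gaps, clusters=clusters, background=fit)


def rpairs_to_dataframe(js: JunctionSet, result: RPairResult) -> pd.DataFrame:
    """Flatten clusters into a per-gap table for TSV output."""
    gap_by_id = result.gap_by_id
    rows = []
    for cluster in result.clusters:
        for gid in sorted(cluster.gap_ids):
            g = gap_by_id[gid]
            rows.append({
                "cluster_id": cluster.id,
                "rpair_class": cluster.rpair_class.value,
                "cyclic": cluster.cyclic,
                "span_class": cluster.span_class.value
                if cluster.span_class else "NA",
                "gap_id": g.id, "chrom": g.chrom,
                "lo_pos": g.lo_pos, "hi_pos": g.hi_pos,
                "length": g.length, "polarity": g.polarity.value,
                "junctions": ",".join(sorted(g.junction_ids)),
                "pval": g.pval, "qval": g.qval,
                "cn_consistency": cluster.cn_consistency.get(
                    gid, CNConsistency.UNKNOWN
                ).value if cluster.cn_consistency else "NA",
            })
    return pd.DataFrame(rows)
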