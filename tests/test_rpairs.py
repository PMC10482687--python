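"""Gap-segment enumeration, background model and reciprocal clustering.

The brute-force reference implementations here apply the documented
predicates literally with nested loops and set arithmetic, independent of
the library's data structures, and serve as oracles for the optimized path.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from scarscan.model import CNProfile, CNSegment, JunctionSet, Orient
from scarscan.rpairs import (
    CNConsistency,
    Polarity,
    RPairClass,
    call_rpairs,
    cluster_reciprocal,
    enumerate_gap_candidates,
    fit_gap_background,
    validate_cn_polarity,
)

from conftest import make_junction, random_junction_set


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_gaps(js: JunctionSet, max_gap_length=1_000_000):
    """Literal scan over all break-end pairs with the four gap predicates,
    followed by the per-break-end shortest-gap filter."""
    ends = []
    for j in js.junctions:
        for be in (j.be1, j.be2):
            ends.append((be.chrom, be.pos, be.orient, j.id))
    all_pos = {(c, p) for c, p, _, _ in ends}
    raw = []
    for (i, a), (k, b) in itertools.combinations(enumerate(ends), 2):
        if a[0] != b[0]:
            continue  # same chromosome
        if a[3] == b[3]:
            continue  # distinct junctions
        if a[2] == b[2]:
            continue  # opposite orientations
        if a[1] < b[1] or (a[1] == b[1] and a[2] is Orient.RIGHT):
            lo, hi = a, b
            lo_i, hi_i = i, k
        else:
            lo, hi = b, a
            lo_i, hi_i = k, i
        if hi[1] - lo[1] + 1 > max_gap_length:
            continue  # length cap
        if any(c == a[0] and lo[1] < p < hi[1] for c, p in all_pos):
            continue  # reference-consecutive
        polarity = Polarity.PLUS if lo[2] is Orient.RIGHT else Polarity.MINUS
        raw.append(dict(chrom=a[0], lo=lo[1], hi=hi[1], polarity=polarity,
                        lo_jid=lo[3], hi_jid=hi[3], ends=(lo_i, hi_i)))
    # each break end keeps its shortest gap; ties to the leftmost partner
    best = {}
    for cand in raw:
        length = cand["hi"] - cand["lo"] + 1
        for endpoint, partner in ((cand["ends"][0], cand["ends"][1]),
                                  (cand["ends"][1], cand["ends"][0])):
            key = (length, ends[partner][1], ends[partner][3])
            if endpoint not in best or key < best[endpoint][0]:
                best[endpoint] = (key, id(cand))
    return [c for c in raw
            if best[c["ends"][0]][1] == id(c) and best[c["ends"][1]][1] == id(c)]


def brute_force_clusters(js, gaps):
    """Union-find over junctions sharing gaps; literal cyclic/rPair rules."""
    parent = {j.id: j.id for j in js.junctions}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for g in gaps:
        a, b = find(g["lo_jid"]), find(g["hi_jid"])
        parent[a] = b
    clusters = {}
    for g in gaps:
        clusters.setdefault(find(g["lo_jid"]), []).append(g)
    out = []
    for gap_list in clusters.values():
        jids = {g["lo_jid"] for g in gap_list} | {g["hi_jid"] for g in gap_list}
        degree = {j: 0 for j in jids}
        for g in gap_list:
            degree[g["lo_jid"]] += 1
            degree[g["hi_jid"]] += 1
        cyclic = all(d == 2 for d in degree.values())
        if cyclic and len(gap_list) == 2 and len(jids) == 2:
            pols = sorted(g["polarity"].value for g in gap_list)
            cls = {"++": RPairClass.RDUP, "--": RPairClass.RDEL,
                   "+-": RPairClass.RDELDUP}["".join(pols)]
        else:
            cls = RPairClass.NA
        out.append(dict(junctions=frozenset(jids), cyclic=cyclic,
                        n_gaps=len(gap_list), rpair_class=cls))
    return out


# ---------------------------------------------------------------------------

class TestGapEnumeration:
    def test_plus_gap_example(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1000, "RIGHT", "chr2", 3_000_000, "LEFT"),
            make_junction("j2", "chr1", 1006, "LEFT", "chr2", 6_000_000, "RIGHT"),
        ], toy_genome)
        (gap,) = enumerate_gap_candidates(js)
        assert (gap.polarity, gap.length) == (Polarity.PLUS, 7)

    def test_minus_gap_example(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1000, "LEFT", "chr2", 3_000_000, "LEFT"),
            make_junction("j2", "chr1", 1006, "RIGHT", "chr2", 6_000_000, "RIGHT"),
        ], toy_genome)
        (gap,) = enumerate_gap_candidates(js)
        assert (gap.polarity, gap.length) == (Polarity.MINUS, 7)

    def test_distance_cap_excludes(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1_000_000, "RIGHT", "chr2", 1000, "LEFT"),
            make_junction("j2", "chr1", 3_000_000, "LEFT", "chr2", 8_000_000, "RIGHT"),
        ], toy_genome)
        assert enumerate_gap_candidates(js) == []

    def test_same_orientation_excluded(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1000, "RIGHT", "chr2", 3_000_000, "LEFT"),
            make_junction("j2", "chr1", 1006, "RIGHT", "chr2", 6_000_000, "LEFT"),
        ], toy_genome)
        assert enumerate_gap_candidates(js) == []

    def test_intervening_breakend_blocks(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1000, "RIGHT", "chr2", 3_000_000, "LEFT"),
            make_junction("j2", "chr1", 9000, "LEFT", "chr2", 6_000_000, "RIGHT"),
            make_junction("j3", "chr1", 5000, "RIGHT", "chr2", 8_500_000, "RIGHT"),
        ], toy_genome)
        gaps = enumerate_gap_candidates(js)
        assert all(not (g.lo_pos == 1000 and g.hi_pos == 9000) for g in gaps)

    def test_polarity_orientation_duality(self, toy_genome):
        """PLUS gap break ends read locally as DUP-like, MINUS as DEL-like."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            js = random_junction_set(rng, 12, toy_genome)
            for g in enumerate_gap_candidates(js):
                local = make_junction(
                    "local", g.chrom, g.lo_pos,
                    "RIGHT" if g.polarity is Polarity.PLUS else "LEFT",
                    g.chrom, g.hi_pos,
                    "LEFT" if g.polarity is Polarity.PLUS else "RIGHT")
                expected = ("DUP-like" if g.polarity is Polarity.PLUS
                            else "DEL-like")
                assert local.svclass.value == expected

    def test_matches_brute_force(self, toy_genome):
        rng = np.random.default_rng(42)
        for _ in range(50):
            js = random_junction_set(rng, int(rng.integers(2, 21)), toy_genome)
            got = {(g.chrom, g.lo_pos, g.hi_pos, g.polarity,
                    g.lo_junction, g.hi_junction)
                   for g in enumerate_gap_candidates(js)}
            want = {(g["chrom"], g["lo"], g["hi"], g["polarity"],
                     g["lo_jid"], g["hi_jid"])
                    for g in brute_force_gaps(js)}
            assert got == want


class TestBackgroundModel:
    def test_closed_form_pvalue(self):
        lengths = [5e6] * 99 + [1e4]
        fit = fit_gap_background(lengths)
        rate = 1.0 / np.mean(lengths)
        assert fit.rate == pytest.approx(rate)
        assert fit.pvals[-1] == pytest.approx(1 - np.exp(-rate * 1e4))

    def test_mle_rate_for_constant_lengths(self):
        fit = fit_gap_background([2000.0] * 50)
        assert fit.rate == pytest.approx(1 / 2000.0)

    def test_too_few_candidates_flags_all(self, caplog):
        fit = fit_gap_background([100.0] * 5)
        assert not fit.fitted
        assert fit.flags.all()

    def test_null_calibration(self):
        """Exponential-null p-values are uniform; BH flags stay near the FDR."""
        rng = np.random.default_rng(123)
        lengths = rng.exponential(5e5, size=5000)
        fit = fit_gap_background(lengths, fdr=0.10)
        ks = stats.kstest(fit.pvals, "uniform")
        assert ks.pvalue > 0.01
        assert fit.flags.mean() <= 0.10 + 0.02


class TestClustering:
    def _rpair_js(self, toy_genome):
        # two junctions bounding two short gaps -> cyclic two-gap cluster
        return JunctionSet("s", [
            make_junction("j1", "chr1", 2_000_500, "LEFT", "chr2", 3_000_000, "RIGHT"),
            make_junction("j2", "chr1", 2_000_000, "RIGHT", "chr2", 3_020_000, "LEFT"),
        ], toy_genome)

    def test_cyclic_two_gap_cluster_is_rpair(self, toy_genome):
        js = self._rpair_js(toy_genome)
        gaps = enumerate_gap_candidates(js)
        assert len(gaps) == 2
        (cluster,) = cluster_reciprocal(js, gaps)
        assert cluster.cyclic
        assert cluster.rpair_class is RPairClass.RDUP

    def test_single_gap_cluster_not_cyclic(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 1000, "RIGHT", "chr2", 3_000_000, "LEFT"),
            make_junction("j2", "chr1", 2000, "LEFT", "chr2", 7_000_000, "RIGHT"),
        ], toy_genome)
        gaps = enumerate_gap_candidates(js)
        assert len(gaps) == 1
        (cluster,) = cluster_reciprocal(js, gaps)
        assert not cluster.cyclic
        assert cluster.rpair_class is RPairClass.NA

    def test_disjoint_pairs_make_separate_clusters(self, toy_genome):
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 2_000_500, "LEFT", "chr2", 3_000_000, "RIGHT"),
            make_junction("j2", "chr1", 2_000_000, "RIGHT", "chr2", 3_020_000, "LEFT"),
            make_junction("j3", "chr1", 7_000_500, "LEFT", "chr2", 8_000_000, "RIGHT"),
            make_junction("j4", "chr1", 7_000_000, "RIGHT", "chr2", 8_020_000, "LEFT"),
        ], toy_genome)
        clusters = cluster_reciprocal(js, enumerate_gap_candidates(js))
        assert len(clusters) == 2
        assert all(c.rpair_class is RPairClass.RDUP for c in clusters)

    @pytest.mark.parametrize(
        "orients,expected",
        [
            # (lo orient, hi orient) per gap chosen via junction orientations
            (("RIGHT", "LEFT", "RIGHT", "LEFT"), RPairClass.RDUP),
            (("LEFT", "RIGHT", "LEFT", "RIGHT"), RPairClass.RDEL),
            (("LEFT", "RIGHT", "RIGHT", "LEFT"), RPairClass.RDELDUP),
        ],
    )
    def test_rpair_polarity_rule(self, toy_genome, orients, expected):
        o1, o2, o3, o4 = orients
        js = JunctionSet("s", [
            make_junction("j1", "chr1", 2_000_000, o1, "chr2", 3_020_000, o4),
            make_junction("j2", "chr1", 2_000_500, o2, "chr2", 3_000_000, o3),
        ], toy_genome)
        gaps = enumerate_gap_candidates(js)
        (cluster,) = cluster_reciprocal(js, gaps)
        assert cluster.rpair_class is expected

    def test_pipeline_matches_brute_force(self, toy_genome):
        rng = np.random.default_rng(7_777)
        for _ in range(60):
            js = random_junction_set(rng, int(rng.integers(2, 21)), toy_genome)
            gaps = enumerate_gap_candidates(js)
            got = sorted(
                (sorted(c.junction_ids), c.cyclic, len(c.gap_ids),
                 c.rpair_class)
                for c in cluster_reciprocal(js, gaps)
            )
            want = sorted(
                (sorted(c["junctions"]), c["cyclic"], c["n_gaps"],
                 c["rpair_class"])
                for c in brute_force_clusters(js, brute_force_gaps(js))
            )
            assert got == want


class TestCNValidation:
    def _cluster_and_gaps(self, toy_genome, plus=True):
        if plus:
            js = JunctionSet("s", [
                make_junction("j1", "chr1", 2_000_500, "LEFT", "chr2", 3_000_000, "RIGHT"),
                make_junction("j2", "chr1", 2_000_000, "RIGHT", "chr2", 3_020_000, "LEFT"),
            ], toy_genome)
        else:
            js = JunctionSet("s", [
                make_junction("j1", "chr1", 2_000_000, "LEFT", "chr2", 3_000_000, "LEFT"),
                make_junction("j2", "chr1", 2_000_500, "RIGHT", "chr2", 3_020_000, "RIGHT"),
            ], toy_genome)
        gaps = enumerate_gap_candidates(js)
        (cluster,) = cluster_reciprocal(js, gaps)
        return cluster, {g.id: g for g in gaps}

    @staticmethod
    def _cn(gap_cn: int) -> CNProfile:
        return CNProfile([
            CNSegment("chr1", 1, 1_999_999, 2, 1, 1),
            CNSegment("chr1", 2_000_000, 2_000_500, gap_cn),
            CNSegment("chr1", 2_000_501, 10_000_000, 2, 1, 1),
            CNSegment("chr2", 1, 10_000_000, 2, 1, 1),
        ])

    def test_plus_gain_consistent(self, toy_genome):
        cluster, gaps = self._cluster_and_gaps(toy_genome, plus=True)
        flags = validate_cn_polarity(cluster, gaps, self._cn(3))
        chr1_gap = next(g for g in gaps.values() if g.chrom == "chr1")
        assert flags[chr1_gap.id] is CNConsistency.CONSISTENT

    def test_plus_tie_inconsistent(self, toy_genome):
        cluster, gaps = self._cluster_and_gaps(toy_genome, plus=True)
        flags = validate_cn_polarity(cluster, gaps, self._cn(2))
        chr1_gap = next(g for g in gaps.values() if g.chrom == "chr1")
        assert flags[chr1_gap.id] is CNConsistency.INCONSISTENT

    def test_minus_loss_consistent(self, toy_genome):
        cluster, gaps = self._cluster_and_gaps(toy_genome, plus=False)
        flags = validate_cn_polarity(cluster, gaps, self._cn(1))
        chr1_gap = next(g for g in gaps.values() if g.chrom == "chr1")
        assert flags[chr1_gap.id] is CNConsistency.CONSISTENT

    def test_missing_coverage_unknown(self, toy_genome):
        cluster, gaps = self._cluster_and_gaps(toy_genome, plus=True)
        cn = CNProfile([CNSegment("chr2", 1, 10_000_000, 2, 1, 1)])
        flags = validate_cn_polarity(cluster, gaps, cn)
        chr1_gap = next(g for g in gaps.values() if g.chrom == "chr1")
        assert flags[chr1_gap.id] is CNConsistency.UNKNOWN


def test_call_rpairs_end_to_end(toy_genome):
    js = JunctionSet("s", [
        make_junction("j1", "chr1", 2_000_500, "LEFT", "chr2", 3_000_000, "RIGHT"),
        make_junction("j2", "chr1", 2_000_000, "RIGHT", "chr2", 3_020_000, "LEFT"),
        make_junction("bg", "chr1", 8_000_000, "LEFT", "chr2", 8_000_000, "LEFT"),
    ], toy_genome)
    result = call_rpairs(js)
    assert len(result.rpairs()) == 1
    assert result.rpairs()[0].rpair_class is RPairClass.RDUP
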