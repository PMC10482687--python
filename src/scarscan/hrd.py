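"""Genomic-scar features and BRCA1/BRCA2-deficiency classification.

Per-sample feature vectors collect reciprocal-pair counts (rDup, rDel,
rDelDup), homeologous deletions, size-gated tandem duplications, the fraction
of small deletions with breakpoint microhomology, and the HRD-LOH index
(loss-of-heterozygosity segments longer than 15 Mbp but shorter than their
chromosome). Precomputed mutational-signature exposures (SNV3, SNV8, RS3,
RS5) may be supplied as extra columns; they are inputs, not computed here.

A random-forest classifier over these features outputs per-sample
probabilities of BRCA1-type (B1) and BRCA2-type (B2) deficiency; a sample is
called HR-deficient when B1 + B2 exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .homeology import HomeologyAnnotation, HOMEO_DEL_MIN_SPAN, MIN_HOMEOLOGY_LEN
from .model import CNProfile, CNSegment, GenomeInfo, Junction, JunctionSet, SvClass
from .rpairs import RPairClass, RPairResult

MAX_MICROHOMOLOGY = 25  # bases of 3' flanking sequence searched
HRD_LOH_MIN_LEN = 15_000_000  # LOH segment length floor for the index
DUP_GATE_METHODS = (10_000, 100_000)  # duplication size gate, 10-100 kbp
DUP_GATE_MAIN = (1_000, 100_000)  # alternative 1-100 kbp gate
SMALL_DEL_MAX_SPAN = 10_000  # denominator cut for the microhomology fraction
B12_CUTOFF = 0.5  # B1 + B2 positivity rule

LABELS = ("BRCA1d", "BRCA2d", "HRP")


def microhomology_deletion(ref, j: Junction, max_mh: int = MAX_MICROHOMOLOGY) -> int:
    """Breakpoint microhomology of a deletion junction.

    For a DEL-like junction with break ends p1 < p2 (deleted interval
    [p1, p2 − 1]), returns the largest k <= max_mh with
    ref[p1 .. p1+k−1] == ref[p2 .. p2+k−1]: the number of bases the 3'
    flanking sequence shares with the start of the deleted sequence.
    """
    if j.svclass is not SvClass.DEL_LIKE:
        raise ValueError(f"junction {j.id} is not DEL-like")
    p1, p2 = j.be1.pos, j.be2.pos
    chrom = j.be1.chrom
    contig = ref[chrom]
    if p2 + max_mh - 1 > len(contig):
        raise ValueError(f"junction {j.id}: flank beyond contig end")
    left = str(contig[p1 - 1:p1 + max_mh - 1]).upper()
    right = str(contig[p2 - 1:p2 + max_mh - 1]).upper()
    k = 0
    while k < max_mh and left[k] == right[k]:
        k += 1
    return k


@dataclass
class LOHCalls:
    loh: list[CNSegment]
    homdel: list[CNSegment]
    excluded: int = 0


def call_loh(cn: CNProfile) -> LOHCalls:
    """Call LOH and homozygous-deletion segments from allelic copy number.

    LOH: minor allele CN = 0 and major allele CN > 0. Homozygous deletion:
    total CN = 0 (not counted as LOH). Adjacent same-label segments are
    merged; segments lacking allelic values are excluded.
    """
    loh: list[CNSegment] = []
    homdel: list[CNSegment] = []
    excluded = 0
    for seg in sorted(cn.segments, key=lambda s: (s.chrom, s.start)):
        if seg.major_cn is None or seg.minor_cn is None:
            excluded += 1
            continue
        if seg.major_cn == 0 and seg.minor_cn == 0:
            _merge_append(homdel, seg)
        elif seg.minor_cn == 0 and seg.major_cn > 0:
            _merge_append(loh, seg)
    return LOHCalls(loh=loh, homdel=homdel, excluded=excluded)


def _merge_append(segments: list[CNSegment], seg: CNSegment) -> None:
    if segments:
        prev = segments[-1]
        if prev.chrom == seg.chrom and seg.start == prev.end + 1:
            segments[-1] = CNSegment(prev.chrom, prev.start, seg.end,
                                     seg.total_cn, seg.major_cn, seg.minor_cn)
            return
    segments.append(seg)


def hrd_loh_index(loh_segments: Sequence[CNSegment], genome: GenomeInfo,
                  min_len: int = HRD_LOH_MIN_LEN) -> int:
    """Count LOH segments longer than 15 Mbp but shorter than their chromosome."""
    count = 0
    for seg in loh_segments:
        length = seg.end - seg.start + 1
        if length > min_len and length < genome.length(seg.chrom):
            count += 1
    return count


@dataclass
class FeatureVector:
    sample_id: str
    n_rDup: int = 0
    n_rDel: int = 0
    n_rDelDup: int = 0
    n_homeo_del: int = 0
    n_dup_sizegate: int = 0
    mh_del_fraction: float = float("nan")
    hrd_loh_index: int = 0
    exposures: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        data = {
            "n_rDup": self.n_rDup, "n_rDel": self.n_rDel,
            "n_rDelDup": self.n_rDelDup, "n_homeo_del": self.n_homeo_del,
            "n_dup_sizegate": self.n_dup_sizegate,
            "mh_del_fraction": self.mh_del_fraction,
            "hrd_loh_index": self.hrd_loh_index,
        }
        data.update(self.exposures)
        return pd.Series(data, name=self.sample_id)


def count_sv_features(
    sample_id: str,
    js: JunctionSet,
    rpairs: Optional[RPairResult] = None,
    homeology: Optional[HomeologyAnnotation] = None,
    cn: Optional[CNProfile] = None,
    genome: Optional[GenomeInfo] = None,
    ref=None,
    dup_gate: tuple[int, int] = DUP_GATE_METHODS,
    exposures: Optional[dict[str, float]] = None,
) -> FeatureVector:
    """Assemble a per-sample scar feature vector.

    The duplication size gate defaults to 10-100 kbp (``DUP_GATE_MAIN``
    selects the alternative 1-100 kbp gate). Homeologous deletions are
    DEL-like junctions with span > 1 kbp and homeology length > 10. The
    microhomology fraction is computed over deletions with span at most
    10 kbp when a reference is supplied.
    """
    fv = FeatureVector(sample_id=sample_id)
    if rpairs is not None:
        for cluster in rpairs.clusters:
            if cluster.rpair_class is RPairClass.RDUP:
                fv.n_rDup += 1
            elif cluster.rpair_class is RPairClass.RDEL:
                fv.n_rDel += 1
            elif cluster.rpair_class is RPairClass.RDELDUP:
                fv.n_rDelDup += 1
    if homeology is not None:
        fv.n_homeo_del = sum(
            1 for j in js.junctions
            if j.id in homeology.results
            and homeology.results[j.id].homeology_len > MIN_HOMEOLOGY_LEN
            and j.svclass is SvClass.DEL_LIKE
            and (j.span or 0) > HOMEO_DEL_MIN_SPAN
        )
    lo, hi = dup_gate
    fv.n_dup_sizegate = sum(
        1 for j in js.junctions
        if j.svclass is SvClass.DUP_LIKE and lo <= (j.span or 0) <= hi
    )
    if ref is not None:
        small_dels = [j for j in js.junctions
                      if j.svclass is SvClass.DEL_LIKE
                      and (j.span or 0) <= SMALL_DEL_MAX_SPAN]
        if small_dels:
            with_mh = sum(microhomology_deletion(ref, j) > 0
                          for j in small_dels)
            fv.mh_del_fraction = with_mh / len(small_dels)
    if cn is not None and genome is not None:
        fv.hrd_loh_index = hrd_loh_index(call_loh(cn).loh, genome)
    if exposures:
        fv.exposures = {k: float(v) for k, v in exposures.items()}
    return fv


def features_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([fv.as_series() for fv in vectors])


@dataclass
class ClassifierOutput:
    sample_id: str
    b1_score: float
    b2_score: float

    @property
    def b12_positive(self) -> bool:
        return self.b1_score + self.b2_score > B12_CUTOFF


@dataclass
class HRDModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    seed: int


def train_classifier(
    features: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 500,
) -> HRDModel:
    """Train the random-forest deficiency classifier.

    ``labels`` take values in {BRCA1d, BRCA2d, HRP}; at least two classes
    must be present. Probabilities are tree-vote fractions.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed)
    forest.fit(features.to_numpy(dtype=float), labels)
    return HRDModel(forest=forest, feature_names=list(features.columns),
                    seed=seed)


def predict(model: HRDModel, features: pd.DataFrame) -> list[ClassifierOutput]:
    """Per-sample B1/B2 scores: class probabilities of the deficient classes."""
    probs = model.forest.predict_proba(
        features[model.feature_names].to_numpy(dtype=float))
    classes = list(model.forest.classes_)
    out = []
    for sample_id, row in zip(features.index, probs):
        b1 = row[classes.index("BRCA1d")] if "BRCA1d" in classes else 0.0
        b2 = row[classes.index("BRCA2d")] if "BRCA2d" in classes else 0.0
        out.append(ClassifierOutput(str(sample_id), float(b1), float(b2)))
    return out


def feature_importance(
    model: HRDModel,
    features: pd.DataFrame,
    labels: Sequence[str],
    n_bootstraps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on a held-out set, resampled over bootstraps.

    Returns the per-feature decrease in accuracy for each permutation
    repeat (rows: repeats, columns: features).
    """
    result = permutation_importance(
        model.forest, features[model.feature_names].to_numpy(dtype=float),
        list(labels), n_repeats=n_bootstraps, random_state=seed,
        scoring="accuracy",
    )
    return pd.DataFrame(result.importances.T, columns=model.feature_names)
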