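"""Break-end homeology detection via sliding k-mer edit-distance matrices.

Homeology is inexact (at least 80%) sequence similarity between the two
flanks of a junction — the footprint single-strand annealing leaves when it
anneals degenerate repeats across a resected double-strand break. For every
position in a 200-bp window around each break end, the centred 41-mer is
extracted; all 200 x 200 pairs of 41-mers are compared by Levenshtein edit
distance and converted to similarity 1 − d/41. The binarized (>= 0.8)
similarity matrix is treated as an image: connected pixel components whose
(row, col) indices are strongly linear (Pearson r^2 >= 0.9, i.e. diagonal
runs) mark contiguous homeologous tracts, and the junction's homeology
length is the pixel count of the largest such component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from skimage.measure import label as _label_components

from .model import Junction, JunctionSet, SvClass

logger = logging.getLogger(__name__)

WINDOW = 200  # bases scanned around each break end
BIN = 41  # k-mer size compared between the two windows
SIM_THRESHOLD = 0.8  # binarization cut on 41-mer similarity
LINEARITY_R2 = 0.9  # Pearson r^2 required of a component's pixel indices
MIN_HOMEOLOGY_LEN = 10  # pixels; junctions above this are homeologous
HOMEO_DEL_MIN_SPAN = 1_000  # homeologous-deletion feature requires span > 1 kbp

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Component:
    pixels: np.ndarray  # (n, 2) row/col indices
    r2: float

    @property
    def size(self) -> int:
        return len(self.pixels)

    @property
    def row_extent(self) -> int:
        """Bases of window A the component covers (its diagonal run length)."""
        rows = self.pixels[:, 0]
        return int(rows.max() - rows.min() + 1)


@dataclass
class HomeologyResult:
    """Per-junction homeology summary.

    ``homeology_len`` is the pixel count of the largest sufficiently linear
    component of the binarized similarity matrix; high-identity tracts admit
    near-diagonal (shifted) bin pairs too, so the component can be several
    pixels thick and its pixel count exceeds the tract length.
    ``homeology_span`` is that component's extent along the first window in
    bases — the length of the contiguous stretch of >= 80 %-similar sequence.
    """

    junction_id: str
    matrix: np.ndarray
    components: list[Component] = field(default_factory=list)
    homeology_len: int = 0
    homeology_span: int = 0

    @property
    def is_homeologous(self) -> bool:
        return self.homeology_len > MIN_HOMEOLOGY_LEN


class ReferenceError(ValueError):
    pass


def _fetch(ref, chrom: str, start: int, end: int) -> str:
    """Fetch ref[start..end] (1-based inclusive) from a pyfaidx-like object."""
    if start < 1:
        raise ReferenceError(f"window start {start} < 1 on {chrom}")
    seq = str(ref[chrom][start - 1:end]).upper()
    if len(seq) != end - start + 1:
        raise ReferenceError(
            f"window {chrom}:{start}-{end} extends past contig end")
    return seq


def extract_breakend_windows(
    ref, j: Junction, window: int = WINDOW, bin_size: int = BIN
) -> tuple[str, str]:
    """Extract padded window sequences around the two break ends.

    Each sequence has window + bin − 1 bases so every window position owns a
    complete centred k-mer. When the junction is inversion-like the two
    break-end flanks anneal on opposite strands, so the second window is
    reverse-complemented; all other classes are compared co-directionally.
    """
    half = window // 2
    pad = bin_size // 2

    def one(be) -> str:
        start = be.pos - half - pad + 1
        end = be.pos + half + pad
        return _fetch(ref, be.chrom, start, end)

    seq_a, seq_b = one(j.be1), one(j.be2)
    if j.svclass is SvClass.INV_LIKE or (
        j.svclass is SvClass.TRA and j.be1.orient == j.be2.orient
    ):
        seq_b = revcomp(seq_b)
    return seq_a, seq_b


def similarity_matrix(
    seq_a: str, seq_b: str, bin_size: int = BIN,
    max_dist: int | None = None,
) -> np.ndarray:
    """Pairwise similarity 1 − editdist/bin between sliding k-mers.

    Entry (i, j) compares the k-mer starting at offset i of seq_a with the
    one starting at offset j of seq_b. With ``max_dist`` the edit-distance
    search is capped for speed: pairs farther than the cap are floored at
    1 − (max_dist + 1)/bin, which leaves every entry at or above the
    binarization threshold exact as long as the cap admits it.
    """
    n_a = len(seq_a) - bin_size + 1
    n_b = len(seq_b) - bin_size + 1
    if n_a < 1 or n_b < 1:
        raise ValueError("sequences shorter than one bin")
    kmers_a = [seq_a[i:i + bin_size] for i in range(n_a)]
    kmers_b = [seq_b[i:i + bin_size] for i in range(n_b)]
    k = -1 if max_dist is None else max_dist
    floor = 0.0 if max_dist is None else 1.0 - (max_dist + 1) / bin_size
    mat = np.empty((n_a, n_b), dtype=float)
    align = edlib.align
    for i, ka in enumerate(kmers_a):
        row = mat[i]
        for jdx, kb in enumerate(kmers_b):
            d = align(ka, kb, task="distance", k=k)["editDistance"]
            row[jdx] = floor if d < 0 else 1.0 - d / bin_size
    return mat


def _component_r2(pixels: np.ndarray) -> float:
    """Pearson r^2 of a component's (row, col) indices.

    Single pixels and axis-aligned lines have zero variance in one index;
    Pearson r is undefined there, and such components cannot represent a
    diagonal homeologous run, so they score 0.
    """
    rows = pixels[:, 0].astype(float)
    cols = pixels[:, 1].astype(float)
    if len(pixels) < 2 or rows.std() == 0 or cols.std() == 0:
        return 0.0
    r = np.corrcoef(rows, cols)[0, 1]
    return float(r * r)


def homeology_length(
    matrix: np.ndarray,
    sim_threshold: float = SIM_THRESHOLD,
    linearity_r2: float = LINEARITY_R2,
) -> tuple[int, list[Component]]:
    """Longest linear run of similar k-mer pairs in the similarity matrix.

    Binarizes at >= sim_threshold, labels 8-connected components, and
    returns the pixel count of the largest component whose pixel indices
    have Pearson r^2 >= linearity_r2, together with all components.
    """
    bitmap = matrix >= sim_threshold
    labeled = _label_components(bitmap, connectivity=2)
    components = []
    for lab in range(1, labeled.max() + 1):
        pixels = np.argwhere(labeled == lab)
        components.append(Component(pixels=pixels, r2=_component_r2(pixels)))
    qualifying = [c.size for c in components if c.r2 >= linearity_r2]
    return (max(qualifying) if qualifying else 0), components


def junction_homeology(
    ref, j: Junction,
    window: int = WINDOW, bin_size: int = BIN,
    sim_threshold: float = SIM_THRESHOLD, linearity_r2: float = LINEARITY_R2,
) -> HomeologyResult:
    seq_a, seq_b = extract_breakend_windows(ref, j, window, bin_size)
    # cap the edit-distance search just past the binarization cut: entries at
    # or above sim_threshold are exact, deeper mismatches are floored
    cap = int(bin_size * (1.0 - sim_threshold)) + 1
    mat = similarity_matrix(seq_a, seq_b, bin_size, max_dist=cap)
    hlen, comps = homeology_length(mat, sim_threshold, linearity_r2)
    span = max((c.row_extent for c in comps
                if c.r2 >= linearity_r2 and c.size == hlen), default=0)
    return HomeologyResult(junction_id=j.id, matrix=mat,
                           components=comps, homeology_len=hlen,
                           homeology_span=span)


@dataclass
class HomeologyAnnotation:
    results: dict[str, HomeologyResult]
    skipped: list[str]

    def homeology_len(self, jid: str) -> int:
        return self.results[jid].homeology_len

    def is_homeologous(self, jid: str) -> bool:
        return self.results[jid].is_homeologous


def call_homeologous_junctions(
    js: JunctionSet, ref,
    window: int = WINDOW, bin_size: int = BIN,
    sim_threshold: float = SIM_THRESHOLD, linearity_r2: float = LINEARITY_R2,
    min_len: int = MIN_HOMEOLOGY_LEN,
) -> tuple[HomeologyAnnotation, dict[str, int]]:
    """Annotate every junction with homeology and count per-sample features.

    Returns the per-junction annotation plus summary counts: junctions with
    homeology length above ``min_len`` and homeologous deletions (DEL-like
    junctions with span > 1 kbp and homeology above the cut). Junctions too
    close to a contig end are skipped with a logged count.
    """
    results: dict[str, HomeologyResult] = {}
    skipped: list[str] = []
    for j in js.junctions:
        try:
            results[j.id] = junction_homeology(
                ref, j, window, bin_size, sim_threshold, linearity_r2)
        except ReferenceError:
            skipped.append(j.id)
    if skipped:
        logger.warning("skipped %d junctions too close to contig ends",
                       len(skipped))
    n_homeo = sum(r.homeology_len > min_len for r in results.values())
    n_homeo_del = sum(
        1 for j in js.junctions
        if j.id in results
        and results[j.id].homeology_len > min_len
        and j.svclass is SvClass.DEL_LIKE
        and (j.span or 0) > HOMEO_DEL_MIN_SPAN
    )
    counts = {"n_homeologous": n_homeo, "n_homeologous_deletions": n_homeo_del}
    return HomeologyAnnotation(results=results, skipped=skipped), counts
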