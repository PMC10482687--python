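import numpy as np
import pytest

from scarscan.model import BreakEnd, GenomeInfo, Junction, JunctionSet, Orient


@pytest.fixture
def toy_genome() -> GenomeInfo:
    return GenomeInfo(
        ("chr1", "chr2"),
        {"chr1": 10_000_000, "chr2": 10_000_000},
        {"chr1": (4_990_000, 5_010_000), "chr2": (4_990_000, 5_010_000)},
    )


def make_junction(jid, c1, p1, o1, c2, p2, o2) -> Junction:
    return Junction(jid, BreakEnd(c1, p1, Orient[o1]), BreakEnd(c2, p2, Orient[o2]))


def random_junction_set(rng: np.random.Generator, n_junctions: int,
                        genome: GenomeInfo, max_pos: int = 9_000_000,
                        sample_id: str = "rand") -> JunctionSet:
    """Random junction sets concentrated enough to produce gap candidates."""
    chroms = list(genome.chrom_names)
    junctions = []
    for i in range(n_junctions):
        c1 = chroms[int(rng.integers(len(chroms)))]
        c2 = chroms[int(rng.integers(len(chroms)))]
        # mix of tight and dispersed break ends so some pairs fall under the
        # gap-length cap and some do not
        p1 = int(rng.integers(1_000_000, max_pos))
        if rng.random() < 0.5 and c1 == c2:
            p2 = min(max_pos, p1 + int(rng.integers(1, 2_000_000)))
        else:
            p2 = int(rng.integers(1_000_000, max_pos))
        o1 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        o2 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        junctions.append(Junction(f"j{i}", BreakEnd(c1, p1, o1),
                                  BreakEnd(c2, p2, o2)))
    return JunctionSet(sample_id, junctions, genome)
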