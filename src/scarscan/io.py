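"""Readers and writers for the tabular interchange formats.

Junctions travel as 10-column BEDPE (0-based half-open intervals; each break
end is a single-base interval whose strand encodes orientation). Copy-number
profiles, barcode molecule tables and chromosome sizes are headered TSV;
centromeres are 3-column BED. Internally everything is 1-based inclusive.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    BreakEnd,
    CNProfile,
    CNSegment,
    GenomeInfo,
    Junction,
    JunctionSet,
    Orient,
)

PathLike = Union[str, Path]


class BedpeDialect:
    """Maps BEDPE strand symbols onto retained-side orientations.

    SV callers disagree on strand conventions, so the mapping is explicit.
    The default maps '+' to LEFT (sequence toward lower coordinates retained)
    and '-' to RIGHT.
    """

    def __init__(self, plus: Orient = Orient.LEFT, minus: Orient = Orient.RIGHT):
        if plus == minus:
            raise ValueError("strand symbols must map to distinct orientations")
        self._fwd = {"+": plus, "-": minus}
        self._rev = {plus: "+", minus: "-"}

    def to_orient(self, strand: str) -> Orient:
        try:
            return self._fwd[strand]
        except KeyError:
            raise ValueError(f"unknown strand symbol {strand!r}") from None

    def to_strand(self, orient: Orient) -> str:
        return self._rev[orient]


DEFAULT_DIALECT = BedpeDialect()


class BedpeParseError(ValueError):
    pass


def read_junctions_bedpe(
    path: PathLike,
    sample_id: str = "sample",
    genome: Optional[GenomeInfo] = None,
    dialect: BedpeDialect = DEFAULT_DIALECT,
) -> JunctionSet:
    """Read a 10+ column BEDPE file into a canonical-ordered JunctionSet.

    The 0-based half-open single-base interval [start, end) becomes the
    1-based break-end position start + 1. Malformed rows raise
    :class:`BedpeParseError` naming the offending line.
    """
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise BedpeParseError(
                    f"{path}: line {lineno}: expected >= 10 BEDPE columns, "
                    f"got {len(fields)}"
                )
            try:
                c1, s1 = fields[0], int(fields[1])
                c2, s2 = fields[3], int(fields[4])
                name = fields[6]
                o1 = dialect.to_orient(fields[8])
                o2 = dialect.to_orient(fields[9])
            except ValueError as exc:
                raise BedpeParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
            be1 = BreakEnd(c1, s1 + 1, o1)
            be2 = BreakEnd(c2, s2 + 1, o2)
            if genome is not None:
                be1.validate(genome)
                be2.validate(genome)
            jid = name if name not in (".", "") else f"j{lineno}"
            junctions.append(Junction(jid, be1, be2))
    return JunctionSet(sample_id=sample_id, junctions=junctions, genome=genome)


def write_junctions_bedpe(
    js: JunctionSet,
    path: PathLike,
    dialect: BedpeDialect = DEFAULT_DIALECT,
) -> None:
    """Write a JunctionSet as 10-column BEDPE; inverse of the reader."""
    with open(path, "w") as fh:
        for j in js.junctions:
            row = [
                j.be1.chrom, str(j.be1.pos - 1), str(j.be1.pos),
                j.be2.chrom, str(j.be2.pos - 1), str(j.be2.pos),
                j.id, ".",
                dialect.to_strand(j.be1.orient),
                dialect.to_strand(j.be2.orient),
            ]
            fh.write("\t".join(row) + "\n")


_CN_COLUMNS = ["chrom", "start", "end", "total_cn", "major_cn", "minor_cn"]


def read_cn_tsv(path: PathLike) -> CNProfile:
    """Read a headered TSV copy-number track (1-based inclusive intervals)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _CN_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing CN columns {missing}")
    segments = []
    for rec in df.itertuples(index=False):
        major = getattr(rec, "major_cn", None)
        minor = getattr(rec, "minor_cn", None)
        major = None if major is None or pd.isna(major) else int(major)
        minor = None if minor is None or pd.isna(minor) else int(minor)
        segments.append(
            CNSegment(str(rec.chrom), int(rec.start), int(rec.end),
                      int(rec.total_cn), major, minor)
        )
    return CNProfile(segments)


def write_cn_tsv(cn: CNProfile, path: PathLike) -> None:
    rows = [
        {
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "total_cn": s.total_cn,
            "major_cn": "" if s.major_cn is None else s.major_cn,
            "minor_cn": "" if s.minor_cn is None else s.minor_cn,
        }
        for s in cn.segments
    ]
    pd.DataFrame(rows, columns=_CN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genome_tsv(path: PathLike) -> GenomeInfo:
    """Read chromosome sizes from a two-column TSV (name, length)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            names.append(row[0])
            lengths[row[0]] = int(row[1])
    return GenomeInfo(tuple(names), lengths)


def write_genome_tsv(genome: GenomeInfo, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f"{name}\t{genome.chrom_lengths[name]}\n")


def read_centromeres_bed(path: PathLike, genome: GenomeInfo) -> GenomeInfo:
    """Attach centromere intervals (BED, 0-based half-open) to a genome."""
    cens: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            cens[row[0]] = (int(row[1]) + 1, int(row[2]))
    return GenomeInfo(genome.chrom_names, genome.chrom_lengths, cens)


def write_centromeres_bed(genome: GenomeInfo, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, (start, end) in genome.centromeres.items():
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_barcodes_tsv(path: PathLike) -> pd.DataFrame:
    """Read a barcode molecule table: barcode, chrom, start, end (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "chrom": str})
    required = {"barcode", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing barcode columns {sorted(missing)}")
    return df


def write_barcodes_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
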