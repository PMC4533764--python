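"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
the 1-based closed convention of GFF3 is converted at the file boundary only.
Readers validate strictly and reject malformed records with the offending line
number rather than coercing them.  A missing protein quantification is an empty
cell in the TSV and a ``NaN`` in memory: detection is a first-class concept,
never conflated with a ratio of zero.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")
MATRIX_KINDS = ("counts", "log_ratio", "protein_ratio")

# sample column headers look like  BuOH_high_75_2  (stressor_level_time_rep)
_HEADER_RE = re.compile(r"^([A-Za-z0-9]+)_(control|low|med|high)_(\d+)_(\d+)$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Gene:
    """One CDS with its operon context, 0-based half-open coordinates."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    operon_id: str
    first_in_operon: bool
    cog: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


class AnnotationIndex:
    """Gene annotation indexed by id, ordered by (contig, start)."""

    def __init__(self, genes: list[Gene]):
        self.genes = sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id))
        self.by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise FormatError(f"duplicate gene id {g.gene_id!r}")
            self.by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def first_in_operon_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.first_in_operon]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "contig": [g.contig for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "operon_id": [g.operon_id for g in self.genes],
                "first_in_operon": [g.first_in_operon for g in self.genes],
                "cog": [g.cog for g in self.genes],
            }
        ).set_index("gene_id")


@dataclass
class CoverageTrack:
    """Dense per-nucleotide read depth for one contig strand and library."""

    contig: str
    strand: str
    values: np.ndarray
    library: str = "TEX+"
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in STRANDS:
            raise FormatError("coverage strand must be + or -")
        if np.any(self.values < 0):
            raise FormatError("coverage values must be non-negative")


@dataclass(frozen=True)
class SampleMeta:
    stressor: str
    level: str
    time: int
    replicate: int


def parse_sample_header(header: str) -> SampleMeta:
    """Parse ``<stressor>_<level>_<time>_<rep>`` (e.g. ``BuOH_high_75_2``)."""
    m = _HEADER_RE.match(header)
    if m is None:
        raise FormatError(
            f"malformed sample header {header!r}: expected <stressor>_<level>_<time>_<rep>"
        )
    return SampleMeta(m.group(1), m.group(2), int(m.group(3)), int(m.group(4)))


def sample_table(columns) -> pd.DataFrame:
    """Sample metadata frame (stressor/level/time/replicate) for matrix columns."""
    metas = [parse_sample_header(c) for c in columns]
    return pd.DataFrame(
        {
            "sample": list(columns),
            "stressor": [m.stressor for m in metas],
            "level": [m.level for m in metas],
            "time": [m.time for m in metas],
            "replicate": [m.replicate for m in metas],
        }
    ).set_index("sample")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> AnnotationIndex:
    """Read CDS features with operon attributes into an :class:`AnnotationIndex`.

    Attributes used: ``ID``, ``operon_id``, ``first_in_operon`` (0/1) and
    optionally ``cog``.  Coordinates are converted from 1-based closed to
    0-based half-open.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            attrs = _parse_attributes(attrs_s, path, lineno)
            gene_id = attrs.get("ID")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: CDS lacks an ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                Gene(
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    start=start1 - 1,
                    end=end1,
                    operon_id=attrs.get("operon_id", gene_id),
                    first_in_operon=attrs.get("first_in_operon", "1") == "1",
                    cog=attrs.get("cog", ""),
                )
            )
    return AnnotationIndex(genes)


def _parse_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def write_gff3(annotation: AnnotationIndex, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = (
                f"ID={g.gene_id};operon_id={g.operon_id};"
                f"first_in_operon={int(g.first_in_operon)}"
            )
            if g.cog:
                attrs += f";cog={g.cog}"
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "stressomics",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path,
    contig_lengths: dict[str, int],
    strand: str = "+",
    library: str = "TEX+",
    condition: str = "",
) -> dict[str, CoverageTrack]:
    """Expand a bedGraph into dense per-nt tracks, one per contig.

    Intervals are 0-based half-open.  Unspecified positions are 0.  When
    intervals overlap, the later interval wins and a warning is logged
    (documented dialect choice).
    """
    dense = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            contig, start_s, end_s, value_s = fields
            if contig not in dense:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage {value}")
            if not 0 <= start < end <= contig_lengths[contig]:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside contig bounds"
                )
            if covered[contig][start:end].any():
                log.warning("%s:%d: overlapping bedGraph interval, last wins", path, lineno)
            dense[contig][start:end] = value
            covered[contig][start:end] = True
    return {
        c: CoverageTrack(c, strand, v, library=library, condition=condition)
        for c, v in dense.items()
    }


def write_bedgraph(tracks: dict[str, CoverageTrack] | CoverageTrack, path) -> None:
    """Run-length encode dense tracks; zero runs are omitted."""
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.contig: tracks}
    with open(path, "w", newline="\n") as fh:
        for contig in sorted(tracks):
            values = tracks[contig].values
            if len(values) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(values)]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{_fmt(v)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a feature-by-sample TSV; headers carry the sample design.

    ``counts`` must be non-negative integers; ``protein_ratio`` cells may be
    empty (protein not detected in that sample) and must otherwise be > 0;
    ``log_ratio`` is any float.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_table(df.columns)  # validates headers
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if kind == "counts":
        values = df.to_numpy()
        if np.isnan(values).any():
            raise FormatError(f"{path}: counts matrix contains empty cells")
        if (values < 0).any():
            raise FormatError(f"{path}: negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError(f"{path}: counts must be integers")
        df = df.astype(np.int64)
    elif kind == "protein_ratio":
        if (df.to_numpy() <= 0).any():  # NaN compares False: absent cells pass
            raise FormatError(f"{path}: protein ratios must be positive where present")
        df = df.astype(float)
    else:
        if df.isna().to_numpy().any():
            raise FormatError(f"{path}: log-ratio matrix contains empty cells")
        df = df.astype(float)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", na_rep="")


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", index=index)
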