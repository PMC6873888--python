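"""Readers/writers for FASTA, GFF3, bedGraph and TSV tables.

Internal convention: all coordinates are 0-based, half-open, and every
conversion to/from 1-based external formats (GFF3, report tables) happens
exactly once, at the I/O boundary. bedGraph is already 0-based half-open
and is passed through unchanged.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

from ._seq import revcomp

TAP_PLUS = "TAP_PLUS"
TAP_MINUS = "TAP_MINUS"

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenomeRecord:
    """A named DNA sequence over {A,C,G,T}, optionally circular."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for contig {self.contig_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene/CDS feature in internal 0-based half-open coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id!r}: unknown strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Position of the first transcribed base (start codon's first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EndCoverage:
    """Strand-specific per-position 5'-end read-start counts for one library.

    ``counts`` maps (contig_id, strand) to a dense int array of contig
    length; ``library_size`` is the total count over all contigs/strands.
    """

    library_label: str
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts.values()))

    def array(self, contig_id: str, strand: str) -> np.ndarray:
        return self.counts[(contig_id, strand)]

    def keys(self):
        return self.counts.keys()


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, ambiguity: str = "reject", seed: int = 0) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased. Characters outside {A,C,G,T} raise a
    :class:`FormatError` unless ``ambiguity="randomize"``, in which case each
    offending position is replaced by a fixed random base drawn under
    ``seed`` (deterministic per file).
    """
    records = []
    rng = np.random.default_rng(seed)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            if ambiguity == "randomize":
                seq = "".join(
                    c if c in _VALID_BASES else "ACGT"[rng.integers(4)] for c in seq
                )
            else:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-ACGT characters "
                    f"{sorted(bad)} (strict mode)"
                )
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path, feature_types: Sequence[str] = ("gene", "CDS")) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file.

    GFF's 1-based inclusive [start, end] becomes internal 0-based half-open
    [start-1, end). The gene identifier is taken from the ``ID`` attribute
    (fallback: ``locus_tag``, ``gene_id``, ``Name``); duplicates raise.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in DataIterator(str(path)):
        if feat.featuretype not in feature_types:
            continue
        gid = None
        for key in ("ID", "locus_tag", "gene_id", "Name"):
            if key in feat.attributes:
                gid = feat.attributes[key][0]
                break
        if gid is None:
            raise FormatError(f"{path}: feature at {feat.seqid}:{feat.start} has no ID")
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        if feat.start > feat.end:
            raise FormatError(f"{path}: feature {gid!r} has start > end")
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: feature {gid!r} has unknown strand {feat.strand!r}")
        product = feat.attributes["product"][0] if "product" in feat.attributes else None
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    return genes


def write_gff(genes: Iterable[GeneAnnotation], path, source: str = "tssmotif") -> None:
    """Write gene features as GFF3 (internal 0-based converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def _read_bedgraph_into(path, arrays: dict[str, np.ndarray], lengths: dict[str, int]) -> None:
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["contig", "start", "end", "value"],
            dtype={"contig": str},
        )
    except pd.errors.EmptyDataError:
        return
    df = df[~df["contig"].str.startswith("track")]
    for row in df.itertuples(index=False):
        if row.contig not in arrays:
            raise FormatError(f"{path}: unknown contig {row.contig!r}")
        start, end, value = int(row.start), int(row.end), row.value
        if value < 0 or value != int(value):
            raise FormatError(f"{path}: non-negative integer value required, got {value}")
        if not (0 <= start < end <= lengths[row.contig]):
            raise FormatError(
                f"{path}: interval {start}-{end} outside contig {row.contig!r} "
                f"(length {lengths[row.contig]})"
            )
        arrays[row.contig][start:end] += int(value)


def read_bedgraph_pair(plus_path, minus_path, contigs: Sequence[GenomeRecord], label: str) -> EndCoverage:
    """Read one library's (+ strand, - strand) bedGraph pair into dense arrays."""
    cov = EndCoverage(library_label=label)
    lengths = {c.contig_id: len(c) for c in contigs}
    for strand, path in (("+", plus_path), ("-", minus_path)):
        arrays = {c.contig_id: np.zeros(len(c), dtype=np.int64) for c in contigs}
        _read_bedgraph_into(path, arrays, lengths)
        for c in contigs:
            cov.counts[(c.contig_id, strand)] = arrays[c.contig_id]
    return cov


def write_bedgraph(cov: EndCoverage, plus_path, minus_path) -> None:
    """Write a library back to a (+ strand, - strand) bedGraph file pair.

    Zero runs are omitted; re-reading reproduces the dense arrays exactly.
    """
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for (contig, s), arr in sorted(cov.counts.items()):
                if s != strand:
                    continue
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for a, b in zip(starts, ends):
                    v = int(arr[a])
                    if v:
                        fh.write(f"{contig}\t{a}\t{b}\t{v}\n")


# ---------------------------------------------------------------------------
# TSS tables

_TSS_COLUMNS = [
    "contig_id",
    "position",  # 1-based in the file
    "strand",
    "tap_plus_count",
    "tap_minus_count",
    "p_value",
    "classes",
    "assigned_genes",
]


def write_tss_table(tss, path) -> None:
    """Write TSS records as a TSV with 1-based positions.

    ``classes`` is a comma-joined label set; ``assigned_genes`` is a
    semicolon-joined ``gene_id:class[:utr]`` list.
    """
    rows = []
    for t in tss:
        rows.append(
            {
                "contig_id": t.contig_id,
                "position": t.position + 1,
                "strand": t.strand,
                "tap_plus_count": t.tap_plus_count,
                "tap_minus_count": t.tap_minus_count,
                "p_value": f"{t.p_value:.6g}",
                "classes": ",".join(sorted(t.classes)) if t.classes else ".",
                "assigned_genes": ";".join(
                    f"{gid}:{cls}" + (f":{utr}" if utr is not None else "")
                    for gid, cls, utr in t.assigned_genes
                )
                or ".",
            }
        )
    df = pd.DataFrame(rows, columns=_TSS_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# tssmotif TSS table; position is 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tss_table(path):
    """Read a TSV written by :func:`write_tss_table` back into records."""
    from .tss_calling import TSSRecord  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig_id": str})
    records = []
    for row in df.itertuples(index=False):
        assigned = []
        if row.assigned_genes != ".":
            for item in str(row.assigned_genes).split(";"):
                parts = item.split(":")
                gid, cls = parts[0], parts[1]
                utr = int(parts[2]) if len(parts) > 2 else None
                assigned.append((gid, cls, utr))
        classes = set() if row.classes == "." else set(str(row.classes).split(","))
        records.append(
            TSSRecord(
                contig_id=row.contig_id,
                position=int(row.position) - 1,
                strand=row.strand,
                tap_plus_count=int(row.tap_plus_count),
                tap_minus_count=int(row.tap_minus_count),
                p_value=float(row.p_value),
                classes=classes,
                assigned_genes=assigned,
            )
        )
    return records
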