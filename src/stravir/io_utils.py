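"""Format readers and writers.

Internal coordinates are 0-based half-open everywhere; SAM and GFF3 are
1-based on disk and BED is 0-based half-open, so conversions live here and
only here.  SAM is consumed as text through pysam (no BAM requirement), so
the package has no mandatory binary inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CrisprArray, CrisprSpacer, GeneModel, ProphageRegion

log = logging.getLogger("stravir")

# CIGAR ops we accept: M/=/X consume both, S consumes query only.
_SUPPORTED_CIGAR = set("MS=X")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping.

    Lowercase bases are uppercased (count logged); duplicate ids and empty
    records are errors.
    """
    records: dict[str, str] = {}
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if any(c.islower() for c in seq):
            n_lower += sum(c.islower() for c in seq)
            seq = seq.upper()
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_lower:
        log.info("read_fasta: normalized %d lowercase bases in %s", n_lower, path)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    if isinstance(records, dict):
        records = records.items()
    seen: set[str] = set()
    recs = []
    for rid, seq in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rid!r}")
        seen.add(rid)
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass(frozen=True)
class SamRecord:
    """A light view of one alignment: internal 0-based half-open span."""

    qname: str
    flag: int
    contig: str | None
    start: int | None  # 0-based
    end: int | None  # half-open; CIGAR-derived reference span
    seq: str
    cigar: str | None
    query_offset: int  # leading soft-clipped bases (query index of span start)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_primary(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)


class SamReader:
    """Iterate a SAM file, yielding :class:`SamRecord`.

    Records whose CIGAR contains an op outside {M,=,X,S} (indels, skips,
    hard clips) are skipped and counted in :attr:`skipped` — the pipeline's
    contract is substitution-only alignments.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.skipped = 0
        self.references: tuple[str, ...] = ()

    def __iter__(self) -> Iterator[SamRecord]:
        with pysam.AlignmentFile(self.path, "r") as sam:
            self.references = tuple(sam.references)
            refs = set(self.references)
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped:
                    yield SamRecord(aln.query_name, aln.flag, None, None, None,
                                    aln.query_sequence or "", None, 0)
                    continue
                if aln.reference_name not in refs:  # pragma: no cover - pysam raises first
                    raise ValueError(f"alignment to {aln.reference_name} absent from @SQ header")
                cigar = aln.cigarstring or ""
                ops = set(c for c in cigar if c.isalpha())
                if ops - _SUPPORTED_CIGAR:
                    self.skipped += 1
                    continue
                offset = 0
                if aln.cigartuples and aln.cigartuples[0][0] == 4:  # leading S
                    offset = aln.cigartuples[0][1]
                yield SamRecord(aln.query_name, aln.flag, aln.reference_name,
                                aln.reference_start, aln.reference_end,
                                aln.query_sequence or "", cigar, offset)


def sam_header(contigs: dict[str, int] | Iterable[tuple[str, int]]) -> str:
    """Render a minimal SAM header (@HD + @SQ lines) as text."""
    if isinstance(contigs, dict):
        contigs = contigs.items()
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return "\n".join(lines) + "\n"


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "stravir") -> None:
    """Write CDS gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.contig}\t{source}\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                    contig=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    name=attrs.get("Name", ""),
                )
            )
    return genes


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (contig, start, end, name) intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[ProphageRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            regions.append(ProphageRegion(phage_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                                          contig=f[0], start=int(f[1]), end=int(f[2])))
    return regions


def write_spacers(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    rows = []
    for arr in arrays:
        for sp in arr.spacers:
            rows.append(dict(host_contig=arr.host_contig, start=sp.start, end=sp.end,
                             spacer=sp.sequence))
    pd.DataFrame(rows, columns=["host_contig", "start", "end", "spacer"]).to_csv(
        path, sep="\t", index=False)


def read_spacers(path: str | Path) -> list[CrisprArray]:
    df = pd.read_csv(path, sep="\t")
    arrays: dict[str, CrisprArray] = {}
    for row in df.itertuples(index=False):
        arr = arrays.setdefault(row.host_contig, CrisprArray(row.host_contig, []))
        arr.spacers.append(CrisprSpacer(sequence=row.spacer, start=int(row.start),
                                        end=int(row.end)))
    return list(arrays.values())


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
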