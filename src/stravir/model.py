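"""Core data model for the personal-reference-metagenome (PRM) analysis.

A PRM is a non-redundant set of assembled contigs — bacterial chromosomal
fragments, free (lytic) phage genomes, and prophages embedded inside
bacterial contigs — that represents every microbe observed across one
subject's longitudinal samples.  All coordinates held in memory are 0-based
half-open; conversion to the 1-based conventions of SAM/GFF happens only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    """A reference contig with its origin annotation.

    origin is "viral" for free phage genomes and "bacterial" for host
    chromosomal contigs (which may carry embedded prophages).
    """

    id: str
    sequence: str
    origin: str  # {"viral", "bacterial"}
    taxon: str | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"contig {self.id!r} has invalid bases {sorted(bad)}")
        if self.origin not in ("viral", "bacterial"):
            raise ValueError(f"contig {self.id!r}: origin must be viral or bacterial")
        if set(self.sequence) == {"N"}:
            raise ValueError(f"contig {self.id!r} is all-N")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene (CDS) on a contig; phase-0, strand-aware."""

    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProphageRegion:
    """A prophage integrated in a bacterial contig (0-based half-open)."""

    phage_id: str
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrisprSpacer:
    sequence: str
    start: int  # array coordinate on the host contig
    end: int


@dataclass
class CrisprArray:
    """A CRISPR array on a bacterial contig; spacers are phage-derived."""

    host_contig: str
    spacers: list[CrisprSpacer] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sp in self.spacers:
            if not 20 <= len(sp.sequence) <= 50:
                raise ValueError(
                    f"spacer on {self.host_contig} has length {len(sp.sequence)}, "
                    "outside the plausible 20-50 bp range"
                )


@dataclass
class PhageAnnotation:
    """Lifestyle/host annotation of one phage or prophage."""

    contig_id: str
    lifestyle: str  # {"lytic", "lysogenic"}
    kind: str  # {"phage", "prophage"}
    host_taxon: str | None = None
    prophage_region: ProphageRegion | None = None
    canonical_name: str = ""
    clade: str | None = None  # e.g. "crAssphage" for hostless clade-named phages

    def __post_init__(self) -> None:
        if (self.kind == "prophage") != (self.prophage_region is not None):
            raise ValueError(
                f"{self.contig_id}: kind == prophage iff a prophage region is present"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one longitudinal sample.

    phase is "AP" (active phase of eczema) or "RP" (remission); EASI is the
    Eczema Area and Severity Index score at collection.
    """

    sample_id: str
    day: int
    phase: str
    easi: float

    def __post_init__(self) -> None:
        if self.phase not in ("AP", "RP"):
            raise ValueError(f"sample {self.sample_id}: phase must be AP or RP")
        if self.easi < 0:
            raise ValueError(f"sample {self.sample_id}: EASI must be non-negative")


@dataclass
class ReferenceSet:
    """The PRM data model: contigs plus every annotation layer.

    The feature table (see :meth:`feature_table`) is the quantification
    contract: one row per abundance feature.  A bacterial contig carrying an
    embedded prophage is split into two features — the prophage region and
    the remaining host sequence — so that reads can be attributed to either.
    """

    contigs: dict[str, Contig]
    phages: list[PhageAnnotation] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    arrays: list[CrisprArray] = field(default_factory=list)
    substrain_window: tuple[str, int, int] | None = None  # (contig, start, end)

    @property
    def prophage_regions(self) -> list[ProphageRegion]:
        return [p.prophage_region for p in self.phages if p.prophage_region is not None]

    def feature_table(self) -> pd.DataFrame:
        """One row per quantifiable feature.

        Columns: feature_id, contig, start, end, length, origin, lifestyle,
        taxon, feature_class.  The host feature of a prophage-carrying contig
        has length = contig length minus embedded prophage length.
        """
        pro_by_contig: dict[str, list[ProphageRegion]] = {}
        for region in self.prophage_regions:
            pro_by_contig.setdefault(region.contig, []).append(region)
        ann_by_contig = {p.contig_id: p for p in self.phages if p.kind == "phage"}
        pro_ann = {
            p.prophage_region.phage_id: p for p in self.phages if p.kind == "prophage"
        }

        rows = []
        for cid in sorted(self.contigs):
            contig = self.contigs[cid]
            if contig.origin == "viral":
                ann = ann_by_contig.get(cid)
                rows.append(
                    dict(
                        feature_id=cid,
                        contig=cid,
                        start=0,
                        end=contig.length,
                        length=contig.length,
                        origin="viral",
                        lifestyle=ann.lifestyle if ann else "lytic",
                        taxon=(ann.host_taxon or ann.clade or "") if ann else "",
                        feature_class="lytic_phage" if (ann is None or ann.lifestyle == "lytic") else "lysogenic_phage",
                    )
                )
            else:
                embedded = sorted(pro_by_contig.get(cid, []), key=lambda r: r.start)
                pro_len = sum(r.length for r in embedded)
                rows.append(
                    dict(
                        feature_id=cid,
                        contig=cid,
                        start=0,
                        end=contig.length,
                        length=contig.length - pro_len,
                        origin="bacterial",
                        lifestyle="",
                        taxon=contig.taxon or "",
                        feature_class="bacteria",
                    )
                )
                for region in embedded:
                    ann = pro_ann.get(region.phage_id)
                    rows.append(
                        dict(
                            feature_id=region.phage_id,
                            contig=cid,
                            start=region.start,
                            end=region.end,
                            length=region.length,
                            origin="viral",
                            lifestyle=ann.lifestyle if ann else "lysogenic",
                            taxon=contig.taxon or "",
                            feature_class="prophage",
                        )
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic substitution call (0-based position, top alt only)."""

    contig: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    effect: str | None = None  # {"synonymous", "nonsynonymous", "noncoding"}

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("SNP ref == alt")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError("SNP requires 0 < alt_count <= depth")


@dataclass
class WindowDensity:
    """SNP counts per window tiled/slid along a contig."""

    starts: list[int]
    counts: list[int]
    window: int
    step: int
    contig_length: int
    snp_positions: list[int] = field(default_factory=list)


@dataclass
class SubstrainCall:
    """One haplotype of the hotspot window, with per-sample support."""

    substrain_id: str
    haplotype: str
    protein: str
    support: dict[str, int]  # sample -> spanning-read count
    tpm_within_phage: dict[str, float] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())
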