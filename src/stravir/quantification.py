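"""Read counting and length-normalized abundance estimation.

Relative abundance of feature i in a sample follows the length-corrected
closure

    abun_i = (C_i / L_i) / sum_N (C_i / L_i)

where C_i is the primary-alignment read count and L_i the feature length;
species-level abundance is the sum of its member features.  Gene/fragment
TPM is the same ratio scaled by 1e6.  Counting uses primary alignments only
(secondary 0x100 and supplementary 0x800 excluded); the mapping rate is
mapped / total over all reads in the SAM including unmapped records.

Reads on a bacterial contig that carries an embedded prophage are split
between the prophage feature and the host feature by the position of the
alignment midpoint relative to the prophage interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_utils import SamReader


@dataclass
class ReadCounts:
    """Primary-alignment counts for one sample."""

    counts: dict[str, int]
    total_reads: int
    mapped_reads: int
    skipped_records: int = 0

    @property
    def mapping_rate(self) -> float | None:
        """mapped / total, or None for an empty SAM."""
        if self.total_reads == 0:
            return None
        return self.mapped_reads / self.total_reads


def count_primary_alignments(sam: str | Path | SamReader,
                             features: pd.DataFrame | None = None) -> ReadCounts:
    """Count one primary alignment per read, attributed to features.

    Without a feature table, counts are per contig.  With one (columns
    feature_id, contig, start, end, feature_class), a read on a contig with
    embedded prophage features is attributed to the prophage whose interval
    contains the alignment midpoint, else to the contig's own feature.
    Raises if an alignment names a contig absent from the feature table.
    """
    reader = sam if isinstance(sam, SamReader) else SamReader(sam)
    regions: dict[str, list[tuple[int, int, str]]] = {}
    base_feature: dict[str, str] = {}
    known: set[str] | None = None
    if features is not None:
        known = set(features["contig"])
        for row in features.itertuples(index=False):
            if row.feature_class == "prophage":
                regions.setdefault(row.contig, []).append(
                    (row.start, row.end, row.feature_id))
            else:
                base_feature[row.contig] = row.feature_id
    counts: dict[str, int] = {}
    total = mapped = skipped = 0
    import pysam

    with pysam.AlignmentFile(reader.path, "r") as samfile:
        for aln in samfile.fetch(until_eof=True):
            flag = aln.flag
            if flag & 0x900:  # secondary or supplementary
                continue
            total += 1
            if flag & 0x4:
                continue
            cigar = aln.cigarstring or ""
            if any(op in cigar for op in "IDNHP"):
                skipped += 1
                continue
            mapped += 1
            contig = aln.reference_name
            if known is not None and contig not in known:
                raise ValueError(f"alignment to contig {contig!r} absent from "
                                 "the feature table")
            fid = base_feature.get(contig, contig)
            pro = regions.get(contig)
            if pro:
                mid = (aln.reference_start + aln.reference_end) // 2
                for s, e, pro_id in pro:
                    if s <= mid < e:
                        fid = pro_id
                        break
            counts[fid] = counts.get(fid, 0) + 1
    return ReadCounts(counts=counts, total_reads=total, mapped_reads=mapped,
                      skipped_records=skipped)


def counts_table(per_sample: Mapping[str, ReadCounts],
                 feature_ids: Iterable[str]) -> pd.DataFrame:
    """Samples x features count matrix (zero-filled)."""
    cols = list(feature_ids)
    return pd.DataFrame(
        [[rc.counts.get(f, 0) for f in cols] for rc in per_sample.values()],
        index=list(per_sample), columns=cols, dtype=np.int64)


def mapping_rates(per_sample: Mapping[str, ReadCounts]) -> pd.DataFrame:
    rows = []
    for sample, rc in per_sample.items():
        rate = rc.mapping_rate
        rows.append(dict(sample=sample, total_reads=rc.total_reads,
                         mapped_reads=rc.mapped_reads,
                         mapping_rate=np.nan if rate is None else rate,
                         skipped_records=rc.skipped_records))
    return pd.DataFrame(rows).set_index("sample")


def relative_abundance(counts: pd.DataFrame,
                       lengths: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Length-normalized relative abundance; rows sum to 1.

    Samples with zero mapped reads get an all-zero row, listed in the
    result's attrs["zero_samples"].  Raises on a missing or non-positive
    length.
    """
    lens = pd.Series(lengths, dtype=float)
    missing = [c for c in counts.columns if c not in lens.index]
    if missing:
        raise ValueError(f"missing length for feature(s) {missing[:5]}")
    lens = lens.loc[counts.columns]
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValueError(f"non-positive length for feature(s) {bad[:5]}")
    rate = counts.to_numpy(dtype=float) / lens.to_numpy()
    row_sum = rate.sum(axis=1, keepdims=True)
    zero = row_sum[:, 0] == 0
    row_sum[zero] = 1.0
    abun = pd.DataFrame(rate / row_sum, index=counts.index, columns=counts.columns)
    abun.attrs["zero_samples"] = counts.index[zero].tolist()
    return abun


def aggregate_abundance(abundance: pd.DataFrame,
                        grouping: Mapping[str, str]) -> pd.DataFrame:
    """Sum member features into labeled groups (row sums preserved).

    Features absent from the grouping map to "unassigned".
    """
    labels = [grouping.get(f, "unassigned") for f in abundance.columns]
    return abundance.T.groupby(pd.Index(labels, name="group")).sum().T


def tpm(counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series,
        universe: Iterable[str] | None = None,
        lengths_unit: str = "bp") -> pd.DataFrame:
    """Transcripts-per-million over the stated feature universe.

    TPM_j = (C_j/L_j) * 1e6 / sum(C_j/L_j).  The formula is scale-invariant
    in the length unit provided all features use the same unit ("bp" or
    "kb").  All-zero samples yield a flagged all-zero row.
    """
    if lengths_unit not in ("bp", "kb"):
        raise ValueError("lengths_unit must be 'bp' or 'kb'")
    uni = list(universe) if universe is not None else list(counts.columns)
    if not uni:
        raise ValueError("TPM universe is empty")
    sub = counts.loc[:, uni]
    lens = pd.Series(lengths, dtype=float).loc[uni]
    if (lens <= 0).any():
        raise ValueError("non-positive feature length in TPM universe")
    rate = sub.to_numpy(dtype=float) / lens.to_numpy()
    row_sum = rate.sum(axis=1, keepdims=True)
    zero = row_sum[:, 0] == 0
    row_sum[zero] = 1.0
    out = pd.DataFrame(rate / row_sum * 1e6, index=sub.index, columns=uni)
    out.attrs["zero_samples"] = sub.index[zero].tolist()
    return out


def particle_ratio(viral_fraction: float, bacterial_fraction: float,
                   mean_viral_genome: float = 40_000.0,
                   mean_bacterial_genome: float = 4_000_000.0) -> float:
    """Virus:bacteria particle-count ratio from DNA fractions.

    Particle counts are proportional to DNA fraction over genome size, so
    the ratio is (viral/mean_viral) / (bacterial/mean_bacterial).  Defaults
    use 40 kb phage and 4 Mb bacterial genomes.
    """
    if not 0 < viral_fraction < 1 or not 0 < bacterial_fraction < 1:
        raise ValueError("fractions must be in (0, 1)")
    if mean_viral_genome <= 0 or mean_bacterial_genome <= 0:
        raise ValueError("genome sizes must be positive")
    return (viral_fraction / mean_viral_genome) / (
        bacterial_fraction / mean_bacterial_genome)
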