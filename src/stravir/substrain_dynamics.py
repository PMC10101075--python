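"""Substrain haplotyping from a SNP-dense window.

The substrain signal the pipeline resolves is a short hypervariable window
(≈75 bp in the study system, inside a phage tail-fiber gene) where fixed
nonsynonymous substitutions distinguish co-circulating substrains of one
phage.  The chain is: pileup-based SNP calling → per-window SNP density →
hotspot localisation → extraction of reads that fully span the hotspot →
exact-identity clustering of the spanned substrings into haplotypes.

Clustering at 100% identity over the full window is deliberate: the window
is short enough that sequencing error is rare per read, and fixed substrain
differences must not be merged.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Seq import Seq

from .io_utils import SamReader
from .model import Contig, GeneModel, SnpRecord, SubstrainCall, WindowDensity
from . import quantification

_CODE = {b: i for i, b in enumerate("ACGT")}
_BASE = "ACGT"


def _open_reader(sam: str | Path | SamReader) -> SamReader:
    if isinstance(sam, SamReader):
        return sam
    return SamReader(sam)


def pileup_counts(sam: str | Path | SamReader, contig: Contig) -> np.ndarray:
    """4 x L base-count matrix over the contig from substitution-only reads."""
    counts = np.zeros((4, contig.length), dtype=np.int64)
    reader = _open_reader(sam)
    for rec in reader:
        if not rec.is_primary or rec.contig != contig.id:
            continue
        span = rec.end - rec.start
        seq = rec.seq[rec.query_offset:rec.query_offset + span]
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.full(256, 255, dtype=np.uint8)
        for b, i in _CODE.items():
            lut[ord(b)] = i
        c = lut[codes]
        valid = c < 4
        pos = np.arange(rec.start, rec.end)
        np.add.at(counts, (c[valid], pos[valid]), 1)
    return counts


def call_snps(sam: str | Path | SamReader, contig: Contig,
              min_depth: int = 5, min_alt_frac: float = 0.2) -> list[SnpRecord]:
    """Frequency-threshold pileup SNP caller.

    A site is a SNP iff depth >= min_depth and the most frequent
    non-reference base has frequency >= min_alt_frac.  One record per site
    (top alternative only).  Indel-bearing records were already skipped (and
    counted) by the SAM reader.
    """
    counts = pileup_counts(sam, contig)
    return snps_from_pileup(counts, contig, min_depth, min_alt_frac)


def call_snps_pooled(sams: Iterable[str | Path | SamReader], contig: Contig,
                     min_depth: int = 5, min_alt_frac: float = 0.2
                     ) -> list[SnpRecord]:
    """SNPs from the summed pileup of several samples."""
    counts = None
    for sam in sams:
        c = pileup_counts(sam, contig)
        counts = c if counts is None else counts + c
    if counts is None:
        raise ValueError("call_snps_pooled: no SAM inputs")
    return snps_from_pileup(counts, contig, min_depth, min_alt_frac)


def snps_from_pileup(counts: np.ndarray, contig: Contig,
                     min_depth: int = 5, min_alt_frac: float = 0.2
                     ) -> list[SnpRecord]:
    ref_codes = np.array([_CODE.get(b, 255) for b in contig.sequence])
    depth = counts.sum(axis=0)
    alt_counts = counts.copy()
    ok = ref_codes < 4
    alt_counts[ref_codes[ok], np.flatnonzero(ok)] = 0
    top_alt = alt_counts.argmax(axis=0)
    top_n = alt_counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_n / np.maximum(depth, 1), 0.0)
    is_snp = (depth >= min_depth) & (top_n > 0) & (frac >= min_alt_frac) & ok
    return [
        SnpRecord(contig=contig.id, position=int(p), ref=contig.sequence[p],
                  alt=_BASE[top_alt[p]], depth=int(depth[p]),
                  alt_count=int(top_n[p]))
        for p in np.flatnonzero(is_snp)
    ]


def snp_window_density(snps: Iterable[SnpRecord], contig_length: int,
                       window: int = 100, step: int = 100) -> WindowDensity:
    """SNP count in each window slid across the contig."""
    if window < 1 or not 1 <= step <= window:
        raise ValueError("require window >= 1 and 1 <= step <= window")
    positions = sorted(s.position for s in snps)
    starts = list(range(0, max(contig_length, 1), step))
    pos_arr = np.array(positions, dtype=np.int64)
    counts = []
    for s in starts:
        e = min(s + window, contig_length)
        counts.append(int(((pos_arr >= s) & (pos_arr < e)).sum()) if positions else 0)
    return WindowDensity(starts=starts, counts=counts, window=window, step=step,
                         contig_length=contig_length, snp_positions=positions)


def hotspot_window(density: WindowDensity, span_cap: int = 100) -> tuple[int, int]:
    """Minimal interval containing the SNPs of the densest window.

    Ties between equal-count windows break leftmost; the returned span is
    capped at span_cap.  Raises if no SNPs exist.
    """
    if not density.snp_positions:
        raise ValueError("no SNPs: cannot locate a hotspot window")
    best = int(np.argmax(density.counts))
    ws = density.starts[best]
    we = min(ws + density.window, density.contig_length)
    inside = [p for p in density.snp_positions if ws <= p < we]
    lo, hi = min(inside), max(inside) + 1
    if hi - lo > span_cap:
        hi = lo + span_cap
    return lo, hi


def codon_change(contig_seq: str, gene: GeneModel, position: int,
                 alt: str) -> tuple[str, str]:
    """Amino acids before/after substituting alt at position (strand-aware).

    The gene is phase-0; for minus-strand genes codons are read from the
    gene end on the reverse complement.  Raises if the codon is truncated
    by the contig end.
    """
    if not gene.start <= position < gene.end:
        raise ValueError("position outside the CDS")
    if gene.strand == "+":
        ci = (position - gene.start) // 3
        cs = gene.start + 3 * ci
        ce = cs + 3
    else:
        ci = (gene.end - 1 - position) // 3
        ce = gene.end - 3 * ci
        cs = ce - 3
    if cs < 0 or ce > len(contig_seq):
        raise ValueError("codon truncated by contig end")
    codon = contig_seq[cs:ce]
    mutated = codon[:position - cs] + alt + codon[position - cs + 1:]
    if gene.strand == "-":
        codon = str(Seq(codon).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    return str(Seq(codon).translate()), str(Seq(mutated).translate())


def snp_effect(snp: SnpRecord, gene: GeneModel,
               contig_seq: str) -> str:
    """Classify a substitution as synonymous / nonsynonymous / noncoding."""
    if snp.contig != gene.contig or not gene.start <= snp.position < gene.end:
        return "noncoding"
    aa_ref, aa_alt = codon_change(contig_seq, gene, snp.position, snp.alt)
    return "nonsynonymous" if aa_ref != aa_alt else "synonymous"


def annotate_effects(snps: list[SnpRecord], genes: list[GeneModel],
                     contig_seq: str) -> list[SnpRecord]:
    """Return SNP records with their coding effect filled in."""
    out = []
    for snp in snps:
        effect = "noncoding"
        for gene in genes:
            if gene.contig == snp.contig and gene.start <= snp.position < gene.end:
                effect = snp_effect(snp, gene, contig_seq)
                break
        out.append(SnpRecord(snp.contig, snp.position, snp.ref, snp.alt,
                             snp.depth, snp.alt_count, effect))
    return out


def extract_spanning_reads(sam: str | Path | SamReader, contig_id: str,
                           interval: tuple[int, int]
                           ) -> list[tuple[str, str]]:
    """Reads whose aligned span fully contains the interval.

    Returns (read id, window substring) pairs; the substring is the read's
    own bases projected onto the interval.  Reads that only partially
    overlap, or whose alignment has any clipped base inside the window, are
    excluded.
    """
    lo, hi = interval
    out = []
    for rec in _open_reader(sam):
        if not rec.is_primary or rec.contig != contig_id:
            continue
        if rec.start <= lo and rec.end >= hi:
            q0 = rec.query_offset + (lo - rec.start)
            out.append((rec.qname, rec.seq[q0:q0 + (hi - lo)]))
    return out


def cluster_haplotypes(spanning: dict[str, list[tuple[str, str]]],
                       min_support: int = 1,
                       gene: GeneModel | None = None,
                       contig_seq: str | None = None,
                       interval: tuple[int, int] | None = None,
                       ) -> list[SubstrainCall]:
    """Exact-identity clustering of window substrings into substrains.

    spanning maps sample id -> list of (read id, substring).  Substrains
    are ordered by total support descending (sequence ascending on ties);
    those with total support < min_support are dropped.  When the gene
    model and interval are supplied, each haplotype also carries its
    in-frame amino-acid rendering.  Per-sample TPM over the substrain
    universe (all haplotypes share the window length) is attached.
    """
    lengths = {len(sub) for subs in spanning.values() for _, sub in subs}
    if len(lengths) > 1:
        raise ValueError(f"spanning substrings have mixed lengths {sorted(lengths)}")
    per_sample: dict[str, Counter] = {
        sample: Counter(sub for _, sub in subs) for sample, subs in spanning.items()
    }
    total: Counter = Counter()
    for c in per_sample.values():
        total.update(c)
    ranked = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(seq, n) for seq, n in ranked if n >= min_support]

    calls = []
    for i, (seq, _n) in enumerate(ranked):
        protein = ""
        if gene is not None and contig_seq is not None and interval is not None:
            protein = _window_protein(seq, gene, contig_seq, interval)
        calls.append(SubstrainCall(
            substrain_id=f"substrain_{i + 1:02d}", haplotype=seq, protein=protein,
            support={s: per_sample[s].get(seq, 0) for s in spanning}))

    # within-phage TPM: universe = the haplotypes, counts = spanning support
    if calls:
        wl = lengths.pop() if lengths else 0
        import pandas as pd
        counts = pd.DataFrame({c.substrain_id: [c.support[s] for s in spanning]
                               for c in calls}, index=list(spanning))
        lens = pd.Series(wl, index=[c.substrain_id for c in calls], dtype=float)
        tpm = quantification.tpm(counts, lens)
        for c in calls:
            c.tpm_within_phage = {s: float(tpm.loc[s, c.substrain_id])
                                  for s in spanning}
    return calls


def _window_protein(window_seq: str, gene: GeneModel, contig_seq: str,
                    interval: tuple[int, int]) -> str:
    """Translate the codons the window touches with the haplotype swapped in."""
    lo, hi = interval
    mutated = contig_seq[:lo] + window_seq + contig_seq[hi:]
    if gene.strand == "+":
        c0 = (lo - gene.start) // 3
        c1 = (hi - 1 - gene.start) // 3
        sub = mutated[gene.start + 3 * c0: gene.start + 3 * (c1 + 1)]
        return str(Seq(sub).translate())
    c0 = (gene.end - hi) // 3
    c1 = (gene.end - 1 - lo) // 3
    sub = mutated[gene.end - 3 * (c1 + 1): gene.end - 3 * c0]
    return str(Seq(sub).reverse_complement().translate())


def sam_from_text(text: str) -> SamReader:
    """SamReader over in-memory SAM text (convenience for pipelines/tests)."""
    import tempfile

    tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    tmp.write(text)
    tmp.close()
    return SamReader(tmp.name)
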