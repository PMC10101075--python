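"""Building and annotating the non-redundant personal reference metagenome.

Contigs are dereplicated greedily, longest first, at a nucleotide-identity
threshold (default 0.95 over the shorter sequence, the CD-HIT convention).
Identity is screened with canonical k-mer sharing — the shared-k-mer
fraction f estimates identity as f**(1/k) — and pairs whose estimate falls
within a narrow band of the threshold are confirmed by exact semi-global
alignment (edlib), so the greedy pass stays fast while borderline calls get
alignment-grade accuracy.

Phage hosts come from two signals: CRISPR spacers whose sequence (either
strand) occurs in a phage genome, and, for prophages, the taxon of the
carrying bacterial contig judged by its flanks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .model import Contig, CrisprArray, PhageAnnotation

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmers(seq: str, k: int = 16) -> frozenset[str]:
    """Set of canonical (lexicographic min of strand pair) k-mers."""
    out = set()
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        bwd = rc[n - k - i:n - i]
        out.add(fwd if fwd <= bwd else bwd)
    return frozenset(out)


def kmer_identity(kmers_a: frozenset[str], kmers_b: frozenset[str],
                  k: int = 16) -> float:
    """Identity estimate from the shared canonical k-mer fraction.

    The fraction is taken over the smaller k-mer set (shorter sequence);
    under independent substitutions a fraction f of shared k-mers implies
    per-base identity ~ f**(1/k).
    """
    denom = min(len(kmers_a), len(kmers_b))
    if denom == 0:
        return 0.0
    shared = len(kmers_a & kmers_b) / denom
    return shared ** (1.0 / k)


def alignment_identity(a: str, b: str) -> float:
    """Exact identity of the shorter sequence aligned within the longer."""
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    d_fwd = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    d_rev = edlib.align(revcomp(query), target, mode="HW",
                        task="distance")["editDistance"]
    return 1.0 - min(d_fwd, d_rev) / len(query)


@dataclass
class DereplicationResult:
    representatives: list[str]
    cluster_of: dict[str, str]  # contig id -> representative id
    dropped_short: list[str] = field(default_factory=list)

    def members(self, rep: str) -> list[str]:
        return [c for c, r in self.cluster_of.items() if r == rep]


def dereplicate_contigs(contigs: list[Contig], identity_threshold: float = 0.95,
                        min_length: int = 5000, k: int = 16,
                        confirm_band: float = 0.03) -> DereplicationResult:
    """Greedy longest-first clustering at the identity threshold.

    Contigs shorter than min_length are dropped.  A contig joins the first
    existing representative with estimated identity >= threshold; estimates
    within +-confirm_band of the threshold are confirmed by exact alignment.
    Output order is deterministic (length desc, id asc).
    """
    if not contigs:
        raise ValueError("dereplicate_contigs: empty input")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    survivors = sorted((c for c in contigs if c.length >= min_length),
                       key=lambda c: (-c.length, c.id))
    dropped = sorted(c.id for c in contigs if c.length < min_length)
    reps: list[Contig] = []
    rep_kmers: list[frozenset[str]] = []
    cluster_of: dict[str, str] = {}
    for contig in survivors:
        km = canonical_kmers(contig.sequence, k)
        assigned = None
        for rep, rkm in zip(reps, rep_kmers):
            est = kmer_identity(km, rkm, k)
            if abs(est - identity_threshold) <= confirm_band:
                est = alignment_identity(contig.sequence, rep.sequence)
            if est >= identity_threshold:
                assigned = rep.id
                break
        if assigned is None:
            reps.append(contig)
            rep_kmers.append(km)
            assigned = contig.id
        cluster_of[contig.id] = assigned
    return DereplicationResult(representatives=[r.id for r in reps],
                               cluster_of=cluster_of, dropped_short=dropped)


@dataclass(frozen=True)
class SpacerMatch:
    host_taxon: str | None
    host_contig: str
    spacer: str
    strand: str  # "+" if the spacer occurs as-is in the phage, "-" if revcomp
    position: int  # 0-based position of the protospacer in the phage


def _scan(phage_seq: str, pattern: str, max_mismatch: int) -> list[int]:
    """All 0-based start positions where pattern matches with <= mismatches."""
    if max_mismatch == 0:
        hits, start = [], 0
        while True:
            i = phage_seq.find(pattern, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1
    arr = np.frombuffer(phage_seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    m, n = len(pat), len(arr)
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = (windows != pat).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch).tolist()


def predict_phage_host(phage: Contig, arrays: list[CrisprArray],
                       max_mismatch: int = 0,
                       taxon_of: dict[str, str] | None = None
                       ) -> list[SpacerMatch]:
    """CRISPR-spacer host prediction: every spacer hit on either strand.

    Matches are ranked by the number of matching spacers per host (ties
    broken by taxon label, then contig id).  An empty list — no identifiable
    host — is a legitimate outcome.
    """
    if phage.origin != "viral":
        raise ValueError(f"{phage.id}: host prediction requires a viral contig")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    taxon_of = taxon_of or {}
    matches: list[SpacerMatch] = []
    for arr in arrays:
        taxon = taxon_of.get(arr.host_contig)
        for sp in arr.spacers:
            for strand, pattern in (("+", sp.sequence), ("-", revcomp(sp.sequence))):
                for pos in _scan(phage.sequence, pattern, max_mismatch):
                    matches.append(SpacerMatch(taxon, arr.host_contig,
                                               sp.sequence, strand, pos))
    per_host = Counter((m.host_taxon or "", m.host_contig) for m in matches)
    order = {h: (-(n), h[0], h[1]) for h, n in per_host.items()}
    matches.sort(key=lambda m: (order[(m.host_taxon or "", m.host_contig)],
                                m.position, m.strand))
    return matches


def rank_hosts(matches: list[SpacerMatch]) -> list[tuple[str, int]]:
    """(host label, n matching spacers) ranked; ties reported, never dropped."""
    per_host = Counter(m.host_taxon or m.host_contig for m in matches)
    return sorted(per_host.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_prophage_host(annotation: PhageAnnotation, contigs: dict[str, Contig],
                         flank_bp: int = 5000) -> tuple[str, bool]:
    """Host taxon of a prophage from its carrying contig's flanks.

    Returns (taxon, high_confidence): confidence is high only when both
    flanks hold at least flank_bp of bacterial sequence.
    """
    if annotation.kind != "prophage" or annotation.prophage_region is None:
        raise ValueError("assign_prophage_host requires a prophage annotation")
    region = annotation.prophage_region
    contig = contigs[region.contig]
    if not (0 <= region.start < region.end <= contig.length):
        raise ValueError(
            f"prophage {region.phage_id}: region [{region.start},{region.end}) "
            f"outside contig {contig.id} bounds [0,{contig.length})")
    if contig.taxon is None:
        raise ValueError(f"contig {contig.id} carries no taxon label; cannot "
                         f"attribute host for prophage {region.phage_id}")
    left = region.start
    right = contig.length - region.end
    high_confidence = left >= flank_bp and right >= flank_bp
    return contig.taxon, high_confidence


def abbreviate_taxon(taxon: str) -> str:
    """'Faecalibacterium prausnitzii' -> 'F.prausnitzii' (whitespace removed)."""
    parts = taxon.replace(".", ". ").split()
    if len(parts) >= 2:
        genus = parts[0].rstrip(".")
        return f"{genus[0]}.{''.join(parts[1:])}"
    return taxon.replace(" ", "")


def phage_name(host: str | None, kind: str, genome_length: int,
               clade: str | None = None) -> str:
    """Canonical "host-phage/prophage-<size>kb" name.

    The host prefix is the genus initial plus species epithet; hostless
    phages with a clade label (e.g. crAssphage) use the clade alone as the
    name stem; hostless phages without one are "circular".  The separator
    is normalized to "-" throughout.
    """
    if genome_length < 1000:
        raise ValueError("phage_name expects genome_length >= 1000")
    size = f"{round(genome_length / 1000)}kb"
    if clade:
        return f"{clade}-{size}"
    prefix = abbreviate_taxon(host) if host else "circular"
    return f"{prefix}-{kind}-{size}"


NAME_ALIASES = {"_": "-"}


def normalize_name(name: str) -> str:
    """Map alias separators (underscore) onto the canonical hyphen form."""
    for old, new in NAME_ALIASES.items():
        name = name.replace(old, new)
    return name


def annotate_reference(contigs: dict[str, Contig],
                       phages: list[PhageAnnotation],
                       arrays: list[CrisprArray],
                       max_mismatch: int = 0,
                       flank_bp: int = 5000) -> pd.DataFrame:
    """Full annotation pass: hosts + canonical names for every phage.

    Returns a table with one row per phage/prophage: contig, kind,
    lifestyle, predicted host (or none), confidence, canonical name.
    """
    taxon_of = {cid: c.taxon for cid, c in contigs.items() if c.taxon}
    rows = []
    for ann in phages:
        if ann.kind == "prophage":
            region = ann.prophage_region
            taxon, high = assign_prophage_host(ann, contigs, flank_bp)
            name = phage_name(taxon, "prophage", region.length)
            rows.append(dict(phage_id=region.phage_id, contig=region.contig,
                             kind="prophage", lifestyle=ann.lifestyle,
                             host_taxon=taxon, n_spacer_hits=0,
                             high_confidence=high, canonical_name=name))
        else:
            phage = contigs[ann.contig_id]
            matches = predict_phage_host(phage, arrays, max_mismatch, taxon_of)
            ranked = rank_hosts(matches)
            host = ranked[0][0] if ranked else None
            name = phage_name(host, "phage", phage.length, clade=ann.clade)
            rows.append(dict(phage_id=ann.contig_id, contig=ann.contig_id,
                             kind="phage", lifestyle=ann.lifestyle,
                             host_taxon=host or "",
                             n_spacer_hits=len(matches),
                             high_confidence=bool(ranked),
                             canonical_name=name))
    return pd.DataFrame(rows)
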