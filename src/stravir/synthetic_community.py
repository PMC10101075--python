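"""Seeded synthetic longitudinal metagenome with full truth tables.

The generator emulates the study design the analysis modules assume: a
~24-sample longitudinal series from one subject split into an active phase
(AP) and a remission phase (RP); free lytic phages whose abundance rises in
RP and embedded prophages that fall; one designated lytic phage (a
crAssphage stand-in) carrying a tail-fiber gene with a short hypervariable
window in which substrain haplotypes differ only by nonsynonymous
substitutions; CRISPR arrays on host contigs holding exact protospacer
copies from their phages; an EASI severity score high in AP and near zero
in RP; and metabolite concentrations with a configured subset shifted
upward in AP.

Read sampling per feature is multinomial with probability proportional to
abundance x feature length, so the length-corrected quantifier is the exact
inverse of the generative model.  Random streams are split per emitter
(reference / substrains / abundance / reads / metadata) so that e.g.
changing sequencing depth never perturbs the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_utils
from .model import (Contig, CrisprArray, CrisprSpacer, GeneModel, PhageAnnotation,
                    ProphageRegion, ReferenceSet)
from .substrain_dynamics import codon_change

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_TAXA = [
    "Faecalibacterium prausnitzii",
    "Bacteroides uniformis",
    "Blautia producta",
    "Parabacteroides distasonis",
    "Fusobacterium nucleatum",
    "Bacteroides fragilis",
    "Anaerobutyricum hallii",
    "Ruminococcus gnavus",
]

_STOPS = {"TAA", "TAG", "TGA"}


def _seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class SubstrainSpec:
    """How many substrain haplotypes exist and their per-phase frequencies.

    Defaults emulate the study: 11 substrains in a 75-bp window; few
    substrains present in AP, all of them in RP.
    """

    n_substrains: int = 11
    window_length: int = 75
    freq_ap: tuple[float, ...] | None = None
    freq_rp: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = self.n_substrains
        if n < 1:
            raise ValueError("n_substrains must be >= 1")
        if not 1 <= self.window_length <= 100:
            raise ValueError("window_length must be in [1, 100] bp")
        if self.freq_ap is None:
            # AP: only the three major substrains circulate
            f = np.zeros(n)
            k = min(3, n)
            f[:k] = np.array([0.5, 0.3, 0.2][:k])
            self.freq_ap = tuple(f / f.sum())
        if self.freq_rp is None:
            # RP: all substrains present, geometrically decaying frequency
            f = 0.75 ** np.arange(n)
            self.freq_rp = tuple(f / f.sum())
        for label, f in (("freq_ap", self.freq_ap), ("freq_rp", self.freq_rp)):
            if len(f) != n:
                raise ValueError(f"{label} must have length n_substrains={n}")
            if abs(sum(f) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1 +- 1e-9")


@dataclass
class CommunityConfig:
    """All knobs of the synthetic community, with study-like defaults."""

    n_bacteria: int = 5
    n_lytic_phages: int = 3
    n_prophages: int = 2
    contig_length_range: tuple[int, int] = (40_000, 80_000)
    phage_length_range: tuple[int, int] = (20_000, 60_000)
    prophage_length_range: tuple[int, int] = (12_000, 25_000)
    n_samples: int = 24
    n_ap: int = 11
    n_rp: int = 13
    phase_fold_changes: dict = field(
        default_factory=lambda: {"lytic": 3.0, "lysogenic": 3.0})
    substrain_spec: SubstrainSpec = field(default_factory=SubstrainSpec)
    depth: int = 20_000
    read_length: int = 150
    error_rate: float = 0.001
    unmapped_fraction: float = 0.005
    baseline_sigma: float = 0.4
    feature_sigma: float = 0.5
    class_weights: dict = field(
        default_factory=lambda: {"bacteria": 1.0, "lytic_phage": 0.08,
                                 "prophage": 0.03})
    flank_bp: int = 5_000
    spacers_per_host: int = 2
    spacer_length: int = 32
    n_metabolites: int = 30
    n_shifted_metabolites: int = 5
    metabolite_fold: float = 3.0
    easi_ap_mean: float = 20.0
    easi_noise: float = 2.0
    bacterial_gc: float = 0.47
    lytic_gc: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ap + self.n_rp != self.n_samples:
            raise ValueError("n_ap + n_rp must equal n_samples")
        if min(self.n_bacteria, self.n_samples, self.n_ap, self.n_rp,
               self.depth, self.read_length) < 1:
            raise ValueError("n_bacteria, n_samples, n_ap, n_rp, depth, "
                             "read_length must all be >= 1")
        if self.n_lytic_phages < 0 or self.n_prophages < 0:
            raise ValueError("phage counts must be >= 0")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if not 0 <= self.unmapped_fraction < 1:
            raise ValueError("unmapped_fraction must be in [0, 1)")
        for key, fc in self.phase_fold_changes.items():
            if fc <= 0:
                raise ValueError(f"phase fold change for {key!r} must be > 0")
        if self.n_prophages > self.n_bacteria:
            raise ValueError("need at least one bacterial contig per prophage")

    def streams(self) -> dict[str, np.random.Generator]:
        ref, sub, abun, reads, meta = np.random.SeedSequence(self.seed).spawn(5)
        return dict(
            reference=np.random.default_rng(ref),
            substrain=np.random.default_rng(sub),
            abundance=np.random.default_rng(abun),
            reads=np.random.default_rng(reads),
            metadata=np.random.default_rng(meta),
        )


@dataclass
class TruthTable:
    """Ground truth of one simulation run."""

    read_origins: pd.DataFrame  # sample, read_id, contig, start, substrain
    true_abundances: pd.DataFrame  # samples x features
    true_substrain_freqs: pd.DataFrame  # samples x substrains
    true_hosts: dict[str, str]  # phage contig id -> host taxon
    haplotypes: list[str] = field(default_factory=list)
    shifted_metabolites: list[str] = field(default_factory=list)


def phase_labels(config: CommunityConfig) -> list[str]:
    """RP samples bracket the AP block: up to 2 before, the rest after."""
    before = 2 if config.n_rp >= 3 else max(0, config.n_rp - 1)
    return ["RP"] * before + ["AP"] * config.n_ap + ["RP"] * (config.n_rp - before)


def sample_ids(config: CommunityConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_samples)]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _codes_to_seq(rng.choice(4, size=length, p=p).astype(np.uint8))


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """A CDS body without in-frame stop codons (ATG start, sense codons)."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def build_reference(config: CommunityConfig) -> ReferenceSet:
    """Build the synthetic PRM: contigs, prophages, tail gene, CRISPR arrays.

    Deterministic for a fixed seed.  Raises ValueError naming the contig if
    a drawn bacterial contig cannot hold its prophage plus two flanks.
    """
    rng = config.streams()["reference"]
    contigs: dict[str, Contig] = {}
    phages: list[PhageAnnotation] = []
    genes: list[GeneModel] = []
    arrays: list[CrisprArray] = []

    bact_ids = [f"bacteria_{i + 1:02d}" for i in range(config.n_bacteria)]
    taxa = [_TAXA[i % len(_TAXA)] for i in range(config.n_bacteria)]
    lo, hi = config.contig_length_range
    bact_seqs = {}
    for cid in bact_ids:
        bact_seqs[cid] = _random_seq(rng, int(rng.integers(lo, hi + 1)),
                                     config.bacterial_gc)

    phage_ids = [f"phage_{i + 1:02d}" for i in range(config.n_lytic_phages)]
    plo, phi = config.phage_length_range
    phage_seqs = {pid: _random_seq(rng, int(rng.integers(plo, phi + 1)),
                                   config.lytic_gc)
                  for pid in phage_ids}

    # Embed prophages into the first n_prophages bacterial contigs.
    regions: dict[str, ProphageRegion] = {}
    rlo, rhi = config.prophage_length_range
    for i in range(config.n_prophages):
        cid = bact_ids[i]
        host_seq = bact_seqs[cid]
        plen = int(rng.integers(rlo, rhi + 1))
        if len(host_seq) < plen + 2 * config.flank_bp:
            raise ValueError(
                f"contig {cid} (length {len(host_seq)}) is too short to hold a "
                f"{plen} bp prophage with {config.flank_bp} bp flanks")
        start = int(rng.integers(config.flank_bp,
                                 len(host_seq) - plen - config.flank_bp + 1))
        pro_seq = _random_seq(rng, plen, config.bacterial_gc)
        bact_seqs[cid] = host_seq[:start] + pro_seq + host_seq[start + plen:]
        pro_id = f"prophage_{i + 1:02d}"
        regions[pro_id] = ProphageRegion(pro_id, cid, start, start + plen)

    # Tail-fiber gene with the substrain window on the first lytic phage.
    substrain_window = None
    if config.n_lytic_phages >= 1:
        pid = phage_ids[0]
        seq = phage_seqs[pid]
        n_codons = 400
        glen = 3 * n_codons
        gstart = int(rng.integers(1000, len(seq) - glen - 1000))
        strand = str(rng.choice(["+", "-"]))
        cds = _random_cds(rng, n_codons, config.lytic_gc)
        body = cds if strand == "+" else str(_revcomp(cds))
        phage_seqs[pid] = seq[:gstart] + body + seq[gstart + glen:]
        genes.append(GeneModel("tail_fiber_1", pid, gstart, gstart + glen,
                               strand, name="tail-fiber"))
        wl = config.substrain_spec.window_length
        woff = int(rng.integers(0, glen - wl + 1))
        substrain_window = (pid, gstart + woff, gstart + woff + wl)

    # CRISPR arrays: each lytic phage is assigned a host round-robin; its
    # spacers are exact copies (or reverse complements) of phage sequence.
    repeat = _random_seq(rng, 28, 0.5)
    host_of = true_host_assignment(config)
    arr_by_contig: dict[str, list[str]] = {}
    for pid in phage_ids:
        arr_by_contig.setdefault(host_of[pid], []).append(pid)
    for i, cid in enumerate(bact_ids):
        if cid not in arr_by_contig:
            continue
        spacer_seqs = []
        for pid in arr_by_contig[cid]:
            pseq = phage_seqs[pid]
            for j in range(config.spacers_per_host):
                pos = int(rng.integers(0, len(pseq) - config.spacer_length + 1))
                proto = pseq[pos:pos + config.spacer_length]
                # half of the spacers are stored reverse-complemented, so the
                # predictor must scan both strands
                spacer_seqs.append(proto if j % 2 == 0 else _revcomp(proto))
        array_seq = repeat + repeat.join(spacer_seqs) + repeat
        a_start = 2000  # inside the first flank, before any prophage
        region = next((r for r in regions.values() if r.contig == cid), None)
        if region is not None and a_start + len(array_seq) > region.start:
            raise ValueError(f"contig {cid}: CRISPR array would overlap prophage")
        seq = bact_seqs[cid]
        bact_seqs[cid] = (seq[:a_start] + array_seq
                          + seq[a_start + len(array_seq):])
        spacers = []
        off = a_start + len(repeat)
        for sp in spacer_seqs:
            spacers.append(CrisprSpacer(sp, off, off + len(sp)))
            off += len(sp) + len(repeat)
        arrays.append(CrisprArray(cid, spacers))

    for cid, taxon in zip(bact_ids, taxa):
        contigs[cid] = Contig(cid, bact_seqs[cid], "bacterial", taxon=taxon)
    for i, pid in enumerate(phage_ids):
        contigs[pid] = Contig(pid, phage_seqs[pid], "viral")
        phages.append(PhageAnnotation(pid, "lytic", "phage",
                                      clade="crAssphage" if i == 0 else None))
    for i, (pro_id, region) in enumerate(regions.items()):
        phages.append(PhageAnnotation(region.contig, "lysogenic", "prophage",
                                      host_taxon=contigs[region.contig].taxon,
                                      prophage_region=region))

    return ReferenceSet(contigs=contigs, phages=phages, genes=genes,
                        arrays=arrays, substrain_window=substrain_window)


def true_host_assignment(config: CommunityConfig) -> dict[str, str]:
    """Deterministic phage -> host-contig assignment (round-robin)."""
    bact_ids = [f"bacteria_{i + 1:02d}" for i in range(config.n_bacteria)]
    return {f"phage_{i + 1:02d}": bact_ids[i % config.n_bacteria]
            for i in range(config.n_lytic_phages)}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_abundance_series(config: CommunityConfig,
                              reference: ReferenceSet) -> pd.DataFrame:
    """Per-sample true relative abundances (rows sum to 1).

    Log-normal baselines; lytic features multiplied and lysogenic features
    divided by the configured fold change in RP samples.
    """
    rng = config.streams()["abundance"]
    feats = reference.feature_table()
    n_f = len(feats)
    phases = phase_labels(config)
    class_w = np.array([config.class_weights.get(c, 1.0)
                        for c in feats["feature_class"]])
    scale = class_w * rng.lognormal(0.0, config.feature_sigma, n_f)
    mat = scale * rng.lognormal(0.0, config.baseline_sigma,
                                (config.n_samples, n_f))
    fc_lytic = config.phase_fold_changes.get("lytic", 1.0)
    fc_lyso = config.phase_fold_changes.get("lysogenic", 1.0)
    is_rp = np.array([p == "RP" for p in phases])
    lytic = (feats["feature_class"] == "lytic_phage").to_numpy()
    lyso = feats["feature_class"].isin(["prophage", "lysogenic_phage"]).to_numpy()
    mat[np.ix_(is_rp, lytic)] *= fc_lytic
    mat[np.ix_(is_rp, lyso)] /= fc_lyso
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(mat, index=sample_ids(config),
                        columns=feats["feature_id"].tolist())


def simulate_substrains(config: CommunityConfig, reference: ReferenceSet
                        ) -> tuple[list[str], pd.DataFrame]:
    """Generate substrain window haplotypes and per-sample frequencies.

    Every haplotype differs from the reference window by >= 1 substitution
    and every substitution is nonsynonymous in the tail gene's frame and
    strand.  Raises if the window cannot supply enough nonsynonymous sites.
    """
    if reference.substrain_window is None:
        raise ValueError("reference carries no substrain window (no lytic phage)")
    rng = config.streams()["substrain"]
    spec = config.substrain_spec
    cid, wstart, wend = reference.substrain_window
    gene = next(g for g in reference.genes if g.contig == cid)
    if not (gene.start <= wstart and wend <= gene.end):
        raise ValueError("substrain window is not fully coding")
    contig_seq = reference.contigs[cid].sequence
    ref_window = contig_seq[wstart:wend]
    wl = wend - wstart

    haplotypes: list[str] = []
    seen = {ref_window}
    for k in range(spec.n_substrains):
        for _attempt in range(200):
            n_sub = 1 + int(rng.integers(0, min(3, wl)))
            hap = _draw_nonsyn_haplotype(rng, contig_seq, gene, wstart, wend, n_sub)
            if hap is not None and hap not in seen:
                haplotypes.append(hap)
                seen.add(hap)
                break
        else:
            raise ValueError(
                f"window exhausted: could not draw distinct nonsynonymous "
                f"haplotype {k + 1} of {spec.n_substrains}")

    phases = phase_labels(config)
    freq = np.array([spec.freq_ap if p == "AP" else spec.freq_rp for p in phases])
    freq_df = pd.DataFrame(freq, index=sample_ids(config),
                           columns=[f"substrain_{i + 1:02d}"
                                    for i in range(spec.n_substrains)])
    return haplotypes, freq_df


def _draw_nonsyn_haplotype(rng: np.random.Generator, contig_seq: str,
                           gene: GeneModel, wstart: int, wend: int,
                           n_sub: int) -> str | None:
    """One haplotype with n_sub nonsynonymous substitutions, or None."""
    window = list(contig_seq[wstart:wend])
    positions = list(range(wstart, wend))
    rng.shuffle(positions)
    placed = 0
    for pos in positions:
        if placed == n_sub:
            break
        ref_base = contig_seq[pos]
        alts = [b for b in "ACGT" if b != ref_base]
        rng.shuffle(alts)
        for alt in alts:
            aa_ref, aa_alt = codon_change(contig_seq, gene, pos, alt)
            if aa_ref != aa_alt:
                window[pos - wstart] = alt
                placed += 1
                break
    return "".join(window) if placed == n_sub else None


def emit_metadata_and_metabolites(config: CommunityConfig
                                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Sample metadata (day, phase, EASI) and metabolite concentrations.

    Returns (metadata, metabolites, shifted metabolite names).  Days are
    strictly increasing; EASI is high in AP and near zero in RP; the first
    n_shifted_metabolites metabolites are multiplied by metabolite_fold in
    AP samples, the remainder are null.
    """
    rng = config.streams()["metadata"]
    phases = phase_labels(config)
    gaps = rng.integers(4, 10, size=config.n_samples)
    days = np.cumsum(gaps) - gaps[0] + 3
    easi = np.where(
        np.array(phases) == "AP",
        np.maximum(0.0, config.easi_ap_mean
                   + config.easi_noise * rng.standard_normal(config.n_samples)),
        np.abs(config.easi_noise * 0.1 * rng.standard_normal(config.n_samples)),
    )
    meta = pd.DataFrame(dict(day=days.astype(int), phase=phases,
                             easi=np.round(easi, 3)),
                        index=sample_ids(config))
    meta.index.name = "sample_id"

    names = [f"metab_{i + 1:02d}" for i in range(config.n_metabolites)]
    conc = rng.lognormal(0.0, config.baseline_sigma,
                         (config.n_samples, config.n_metabolites))
    shifted = names[:config.n_shifted_metabolites]
    is_ap = (np.array(phases) == "AP")
    conc[np.ix_(is_ap, np.arange(len(shifted)))] *= config.metabolite_fold
    metab = pd.DataFrame(np.round(conc, 6), index=sample_ids(config), columns=names)
    metab.index.name = "sample_id"
    return meta, metab, shifted


def emit_alignments(reference: ReferenceSet, abundances: pd.DataFrame,
                    config: CommunityConfig,
                    haplotypes: list[str] | None = None,
                    substrain_freqs: pd.DataFrame | None = None,
                    make_fastq: bool = True,
                    ) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Emit per-sample SAM (and FASTQ) text plus the read-origin truth.

    Returns (sam_texts, fastq_texts, read_origins).  Read counts per feature
    are multinomial with probability proportional to abundance x feature
    length; substitution errors at error_rate; a binomial fraction of reads
    is emitted unmapped (FLAG 4).  Byte-identical for a fixed seed.
    """
    rng_parent = config.streams()["reads"]
    sample_rngs = [np.random.default_rng(s)
                   for s in rng_parent.bit_generator.seed_seq.spawn(config.n_samples)]
    feats = reference.feature_table()
    rl = config.read_length
    codes = {cid: _seq_to_codes(c.sequence) for cid, c in reference.contigs.items()}
    header = io_utils.sam_header({cid: c.length for cid, c in
                                  sorted(reference.contigs.items())})
    window = reference.substrain_window
    hap_codes = ([_seq_to_codes(h) for h in haplotypes] if haplotypes else [])

    # valid read-start segments per feature (host features avoid prophages)
    segments: dict[str, list[tuple[int, int]]] = {}
    for row in feats.itertuples(index=False):
        contig_len = reference.contigs[row.contig].length
        if row.feature_class == "bacteria":
            embedded = sorted(
                (r.start, r.end) for r in reference.prophage_regions
                if r.contig == row.contig)
            segs, cur = [], 0
            for s, e in embedded:
                if s - rl >= cur:
                    segs.append((cur, s - rl + 1))
                cur = e
            if contig_len - rl >= cur:
                segs.append((cur, contig_len - rl + 1))
            segments[row.feature_id] = segs
        elif row.feature_class == "prophage":
            segments[row.feature_id] = [(row.start, row.end - rl + 1)]
        else:
            segments[row.feature_id] = [(0, contig_len - rl + 1)]

    sam_texts: dict[str, str] = {}
    fastq_texts: dict[str, str] = {}
    origin_frames = []
    phases = dict(zip(sample_ids(config), phase_labels(config)))
    for sample, rng in zip(abundances.index, sample_rngs):
        abun = abundances.loc[sample].to_numpy()
        lens = feats["length"].to_numpy(dtype=float)
        probs = abun * lens
        probs /= probs.sum()
        n_unmapped = int(rng.binomial(config.depth, config.unmapped_fraction))
        counts = rng.multinomial(config.depth - n_unmapped, probs)

        all_contig, all_start, all_codes, all_sub = [], [], [], []
        for fi, row in enumerate(feats.itertuples(index=False)):
            cnt = int(counts[fi])
            if cnt == 0:
                continue
            segs = segments[row.feature_id]
            widths = np.array([e - s for s, e in segs])
            if widths.sum() <= 0:
                raise ValueError(f"feature {row.feature_id} shorter than read length")
            u = rng.integers(0, widths.sum(), size=cnt)
            starts = np.empty(cnt, dtype=np.int64)
            off = 0
            for (s, e), w in zip(segs, widths):
                m = (u >= off) & (u < off + w)
                starts[m] = s + (u[m] - off)
                off += w
            reads = codes[row.contig][starts[:, None] + np.arange(rl)].copy()
            subs = np.full(cnt, -1, dtype=np.int64)
            if (window is not None and hap_codes
                    and row.contig == window[0] and row.feature_class != "prophage"):
                wc, ws, we = window
                overlap = (starts < we) & (starts + rl > ws)
                idx = np.flatnonzero(overlap)
                if idx.size:
                    freq = substrain_freqs.loc[sample].to_numpy()
                    drawn = rng.choice(len(hap_codes), size=idx.size, p=freq)
                    subs[idx] = drawn
                    for i, k in zip(idx, drawn):
                        s0 = starts[i]
                        lo, hi = max(s0, ws), min(s0 + rl, we)
                        reads[i, lo - s0:hi - s0] = hap_codes[k][lo - ws:hi - ws]
            if config.error_rate > 0:
                err = rng.random(reads.shape) < config.error_rate
                n_err = int(err.sum())
                if n_err:
                    reads[err] = (reads[err] + rng.integers(1, 4, n_err)) % 4
            all_contig.append(np.full(cnt, fi))
            all_start.append(starts)
            all_codes.append(reads)
            all_sub.append(subs)

        contig_names = feats["contig"].tolist()
        qual = "I" * rl
        sam_body: list[str] = []
        fq_parts: list[str] = []
        rec_ids: list[str] = []
        rec_contig: list[str] = []
        rec_start: list[int] = []
        rec_sub: list[int] = []
        rid = 0
        if all_codes:
            cat_fi = np.concatenate(all_contig)
            cat_start = np.concatenate(all_start)
            cat_codes = np.concatenate(all_codes)
            cat_sub = np.concatenate(all_sub)
            n = len(cat_fi)
            blob = _BASES[cat_codes].tobytes().decode()
            seqs = [blob[i * rl:(i + 1) * rl] for i in range(n)]
            names = [f"{sample}.r{i:07d}" for i in range(n)]
            pos = (cat_start + 1).tolist()
            cnames = [contig_names[i] for i in cat_fi.tolist()]
            cig = f"{rl}M"
            sam_body = [
                f"{nm}\t0\t{cn}\t{p}\t60\t{cig}\t*\t0\t0\t{sq}\t{qual}"
                for nm, cn, p, sq in zip(names, cnames, pos, seqs)]
            if make_fastq:
                fq_parts = [f"@{nm}\n{sq}\n+\n{qual}\n"
                            for nm, sq in zip(names, seqs)]
            rec_ids, rec_contig = names, cnames
            rec_start = cat_start.tolist()
            rec_sub = cat_sub.tolist()
            rid = n
        if n_unmapped:
            um = rng.integers(0, 4, size=(n_unmapped, rl)).astype(np.uint8)
            blob = _BASES[um].tobytes().decode()
            useqs = [blob[i * rl:(i + 1) * rl] for i in range(n_unmapped)]
            unames = [f"{sample}.r{rid + i:07d}" for i in range(n_unmapped)]
            sam_body += [f"{nm}\t4\t*\t0\t0\t*\t*\t0\t0\t{sq}\t{qual}"
                         for nm, sq in zip(unames, useqs)]
            if make_fastq:
                fq_parts += [f"@{nm}\n{sq}\n+\n{qual}\n"
                             for nm, sq in zip(unames, useqs)]
            rec_ids = rec_ids + unames
            rec_contig = rec_contig + ["*"] * n_unmapped
            rec_start = rec_start + [-1] * n_unmapped
            rec_sub = rec_sub + [-1] * n_unmapped
        sam_texts[sample] = header + "\n".join(sam_body) + ("\n" if sam_body else "")
        fastq_texts[sample] = "".join(fq_parts)
        origin_frames.append(pd.DataFrame(dict(
            sample=sample, read_id=rec_ids, contig=rec_contig,
            start=rec_start, substrain=rec_sub)))

    origins = (pd.concat(origin_frames, ignore_index=True) if origin_frames
               else pd.DataFrame(columns=["sample", "read_id", "contig",
                                          "start", "substrain"]))
    return sam_texts, fastq_texts, origins


@dataclass
class SimulationResult:
    config: CommunityConfig
    reference: ReferenceSet
    truth: TruthTable
    sam_texts: dict[str, str]
    fastq_texts: dict[str, str]
    metadata: pd.DataFrame
    metabolites: pd.DataFrame


def simulate_community(config: CommunityConfig,
                       make_fastq: bool = True) -> SimulationResult:
    """Run every emitter in memory and assemble the truth table."""
    reference = build_reference(config)
    abund = simulate_abundance_series(config, reference)
    if config.n_lytic_phages >= 1 and config.substrain_spec.n_substrains >= 1:
        haplotypes, freqs = simulate_substrains(config, reference)
    else:
        haplotypes, freqs = [], pd.DataFrame(index=sample_ids(config))
    sam_texts, fastq_texts, origins = emit_alignments(
        reference, abund, config, haplotypes, freqs, make_fastq=make_fastq)
    meta, metab, shifted = emit_metadata_and_metabolites(config)
    truth = TruthTable(read_origins=origins, true_abundances=abund,
                       true_substrain_freqs=freqs,
                       true_hosts={p: reference.contigs[c].taxon
                                   for p, c in true_host_assignment(config).items()},
                       haplotypes=haplotypes, shifted_metabolites=shifted)
    return SimulationResult(config, reference, truth, sam_texts, fastq_texts,
                            meta, metab)


def write_simulation(result: SimulationResult, outdir: str | Path,
                     write_fastq: bool = True) -> dict[str, Path]:
    """Write FASTA/GFF/BED/TSV/SAM/FASTQ outputs of a simulation to disk."""
    out = Path(outdir)
    (out / "sam").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    ref = result.reference
    paths: dict[str, Path] = {}

    paths["reference"] = out / "reference.fasta"
    io_utils.write_fasta({cid: c.sequence for cid, c in sorted(ref.contigs.items())},
                         paths["reference"])
    paths["genes"] = out / "genes.gff3"
    io_utils.write_gff3(ref.genes, paths["genes"])
    paths["prophages"] = out / "prophages.bed"
    io_utils.write_bed([(r.contig, r.start, r.end, r.phage_id)
                        for r in ref.prophage_regions], paths["prophages"])
    if ref.substrain_window is not None:
        paths["window"] = out / "substrain_window.bed"
        cid, s, e = ref.substrain_window
        io_utils.write_bed([(cid, s, e, "substrain_window")], paths["window"])
    paths["spacers"] = out / "spacers.tsv"
    io_utils.write_spacers(ref.arrays, paths["spacers"])
    paths["features"] = out / "features.tsv"
    io_utils.write_tsv(ref.feature_table(), paths["features"], index=False)
    paths["metadata"] = out / "metadata.tsv"
    io_utils.write_tsv(result.metadata, paths["metadata"])
    paths["metabolites"] = out / "metabolites.tsv"
    io_utils.write_tsv(result.metabolites, paths["metabolites"])
    for sample, text in result.sam_texts.items():
        p = out / "sam" / f"{sample}.sam"
        p.write_text(text)
        paths[f"sam:{sample}"] = p
    if write_fastq:
        (out / "fastq").mkdir(exist_ok=True)
        for sample, text in result.fastq_texts.items():
            p = out / "fastq" / f"{sample}.fastq"
            p.write_text(text)
            paths[f"fastq:{sample}"] = p

    io_utils.write_tsv(result.truth.true_abundances, out / "truth" / "abundances.tsv")
    io_utils.write_tsv(result.truth.true_substrain_freqs,
                       out / "truth" / "substrain_freqs.tsv")
    io_utils.write_tsv(result.truth.read_origins, out / "truth" / "read_origins.tsv",
                       index=False)
    if result.truth.haplotypes:
        io_utils.write_fasta(
            {f"substrain_{i + 1:02d}": h
             for i, h in enumerate(result.truth.haplotypes)},
            out / "truth" / "haplotypes.fasta")
    hosts = pd.DataFrame(sorted(result.truth.true_hosts.items()),
                         columns=["phage", "host_taxon"])
    io_utils.write_tsv(hosts, out / "truth" / "hosts.tsv", index=False)
    paths["truth"] = out / "truth"
    return paths
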