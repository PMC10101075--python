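"""SNP calling, hotspot localization, coding effects and haplotyping."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from stravir import substrain_dynamics as ssd
from stravir.model import Contig, GeneModel, SnpRecord, WindowDensity
from stravir.synthetic_community import SubstrainSpec, simulate_community

from conftest import phage_rich_config, small_config


def _sam_path(tmp_path, contig, reads, name="t.sam"):
    """reads: list of (qname, start0, seq)."""
    header = (f"@HD\tVN:1.6\tSO:unsorted\n"
              f"@SQ\tSN:{contig.id}\tLN:{contig.length}\n")
    body = "".join(
        f"{q}\t0\t{contig.id}\t{s + 1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
        for q, s, seq in reads)
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestCallSnps:
    def _contig(self):
        rng = np.random.default_rng(0)
        return Contig("c", "".join(rng.choice(list("ACGT"), size=300)), "viral")

    def test_six_ref_four_alt_called(self, tmp_path):
        contig = self._contig()
        site = 100
        alt = "A" if contig.sequence[site] != "A" else "C"
        reads = []
        for i in range(6):
            reads.append((f"ref{i}", 60, contig.sequence[60:160]))
        mutated = (contig.sequence[60:site] + alt
                   + contig.sequence[site + 1:160])
        for i in range(4):
            reads.append((f"alt{i}", 60, mutated))
        snps = ssd.call_snps(_sam_path(tmp_path, contig, reads), contig)
        assert len(snps) == 1
        snp = snps[0]
        assert (snp.position, snp.alt, snp.depth, snp.alt_count) == \
            (site, alt, 10, 4)

    def test_depth_below_threshold_no_call(self, tmp_path):
        contig = self._contig()
        site = 100
        alt = "A" if contig.sequence[site] != "A" else "C"
        mutated = contig.sequence[60:site] + alt + contig.sequence[site + 1:160]
        reads = [(f"r{i}", 60, mutated) for i in range(4)]  # depth 4 < 5
        assert ssd.call_snps(_sam_path(tmp_path, contig, reads), contig) == []

    def test_alt_fraction_threshold(self, tmp_path):
        contig = self._contig()
        site = 100
        alt = "A" if contig.sequence[site] != "A" else "C"
        mutated = contig.sequence[60:site] + alt + contig.sequence[site + 1:160]
        reads = ([(f"ref{i}", 60, contig.sequence[60:160]) for i in range(9)]
                 + [("alt0", 60, mutated)])  # 1/10 = 0.1 < 0.2
        assert ssd.call_snps(_sam_path(tmp_path, contig, reads), contig) == []

    def test_planted_haplotype_sites_called_exactly(self, tmp_path):
        """Error-free half-frequency haplotype: exactly the planted window
        sites are called, nothing else."""
        cfg = phage_rich_config(
            seed=3, depth=30_000,
            substrain_spec=SubstrainSpec(n_substrains=1, window_length=30,
                                         freq_ap=(1.0,), freq_rp=(1.0,)))
        sim = simulate_community(cfg, make_fastq=False)
        cid, ws, we = sim.reference.substrain_window
        contig = sim.reference.contigs[cid]
        (hap,) = sim.truth.haplotypes
        planted = {ws + i for i in range(len(hap))
                   if hap[i] != contig.sequence[ws + i]}
        sam = tmp_path / "s.sam"
        sam.write_text(sim.sam_texts["S01"])
        called = ssd.call_snps(sam, contig, min_alt_frac=0.2)
        # haplotype frequency 1.0: every planted site fixed in the reads
        assert {s.position for s in called} == planted


class TestWindowDensity:
    def test_no_snps_all_zero(self):
        d = ssd.snp_window_density([], 1000)
        assert all(c == 0 for c in d.counts)

    def test_clustered_snps_fall_in_one_tile(self):
        snps = [SnpRecord("c", p, "A", "C", 10, 5)
                for p in range(100, 160, 6)]  # 10 SNPs in [100, 160)
        d = ssd.snp_window_density(snps, 1000, window=100, step=100)
        assert d.counts[1] == 10
        assert sum(d.counts) == 10

    def test_sliding_step_overlaps_cover_all(self):
        snps = [SnpRecord("c", p, "A", "C", 10, 5)
                for p in range(100, 160, 6)]
        d = ssd.snp_window_density(snps, 1000, window=100, step=50)
        hits = [c for s, c in zip(d.starts, d.counts) if c >= 1]
        assert len(hits) >= 2
        assert max(d.counts) == 10

    def test_invalid_window_step(self):
        with pytest.raises(ValueError):
            ssd.snp_window_density([], 1000, window=100, step=150)


class TestHotspot:
    def test_75bp_span_recovered(self):
        snps = [SnpRecord("c", p, "A", "C", 10, 5) for p in (1000, 1030, 1074)]
        d = ssd.snp_window_density(snps, 5000, window=100, step=100)
        lo, hi = ssd.hotspot_window(d)
        assert (lo, hi) == (1000, 1075)
        assert hi - lo == 75

    def test_single_snp_gives_length_one(self):
        snps = [SnpRecord("c", 42, "A", "C", 10, 5)]
        d = ssd.snp_window_density(snps, 1000)
        assert ssd.hotspot_window(d) == (42, 43)

    def test_tie_broken_leftmost(self):
        snps = [SnpRecord("c", p, "A", "C", 10, 5) for p in (10, 20, 510, 520)]
        d = ssd.snp_window_density(snps, 1000, window=100, step=100)
        assert ssd.hotspot_window(d) == (10, 21)

    def test_no_snps_raises(self):
        d = ssd.snp_window_density([], 1000)
        with pytest.raises(ValueError, match="no SNPs"):
            ssd.hotspot_window(d)


class TestSnpEffect:
    def test_known_codon_changes(self):
        # gene GCT AAA ...: GCT(Ala) pos1 C->G = GGT(Gly) nonsyn;
        # pos2 T->C = GCC(Ala) synonymous
        seq = "GCTAAATTTGGG"
        gene = GeneModel("g", "c", 0, 12, "+")
        nonsyn = SnpRecord("c", 1, "C", "G", 10, 5)
        syn = SnpRecord("c", 2, "T", "C", 10, 5)
        assert ssd.snp_effect(nonsyn, gene, seq) == "nonsynonymous"
        assert ssd.snp_effect(syn, gene, seq) == "synonymous"

    def test_upstream_site_noncoding(self):
        seq = "A" * 30 + "GCTAAA"
        gene = GeneModel("g", "c", 30, 36, "+")
        snp = SnpRecord("c", 20, "A", "C", 10, 5)
        assert ssd.snp_effect(snp, gene, seq) == "noncoding"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_against_whole_gene_translation(self, strand):
        """All 9 single-base variants of every codon in a test gene agree
        with an independent oracle that re-translates the entire CDS."""
        rng = np.random.default_rng(7)
        n_codons = 40
        body = []
        while len(body) < n_codons:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if c not in ("TAA", "TAG", "TGA"):
                body.append(c)
        cds = "".join(body)
        gene_seq = cds if strand == "+" else str(Seq(cds).reverse_complement())
        seq = "ACGT" * 5 + gene_seq + "TTTT"
        gene = GeneModel("g", "c", 20, 20 + 3 * n_codons, strand)

        def oracle(position, alt):
            mutated = seq[:position] + alt + seq[position + 1:]
            sub = mutated[gene.start:gene.end]
            if strand == "-":
                sub = str(Seq(sub).reverse_complement())
            before = str(Seq(cds).translate())
            after = str(Seq(sub).translate())
            return "nonsynonymous" if before != after else "synonymous"

        for pos in range(gene.start, gene.end):
            ref = seq[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                snp = SnpRecord("c", pos, ref, alt, 10, 5)
                assert ssd.snp_effect(snp, gene, seq) == oracle(pos, alt), \
                    (strand, pos, ref, alt)

    def test_truncated_codon_raises(self):
        seq = "GCTAA"  # gene claims 6 bp but contig ends at 5
        gene = GeneModel("g", "c", 0, 6, "+")
        snp = SnpRecord("c", 4, "A", "C", 10, 5)
        with pytest.raises(ValueError, match="truncated"):
            ssd.codon_change(seq, gene, snp.position, snp.alt)


class TestSpanningReads:
    def _contig(self):
        rng = np.random.default_rng(9)
        return Contig("c", "".join(rng.choice(list("ACGT"), size=2000)), "viral")

    def test_containment_rule(self, tmp_path):
        contig = self._contig()
        interval = (1000, 1075)
        reads = [("full", 990, contig.sequence[990:1140]),
                 ("late", 1010, contig.sequence[1010:1160]),
                 ("early", 900, contig.sequence[900:1050])]
        sam = _sam_path(tmp_path, contig, reads)
        got = ssd.extract_spanning_reads(sam, "c", interval)
        assert [g[0] for g in got] == ["full"]
        assert got[0][1] == contig.sequence[1000:1075]
        assert len(got[0][1]) == 75

    def test_error_free_substrings_equal_planted_haplotypes(self, tmp_path):
        sim = simulate_community(phage_rich_config(seed=5), make_fastq=False)
        ref = sim.reference
        cid, ws, we = ref.substrain_window
        allowed = set(sim.truth.haplotypes) | {ref.contigs[cid].sequence[ws:we]}
        found = set()
        for sample, text in sim.sam_texts.items():
            p = tmp_path / f"{sample}.sam"
            p.write_text(text)
            for _, sub in ssd.extract_spanning_reads(p, cid, (ws, we)):
                assert sub in allowed
                found.add(sub)
        assert found  # some spanning reads existed


class TestClusterHaplotypes:
    def test_exact_grouping_with_supports(self):
        spanning = {"s1": [("r%d" % i, "AAAA") for i in range(5)]
                    + [("q%d" % i, "CCCC") for i in range(3)],
                    "s2": [("p%d" % i, "GGGG") for i in range(2)]}
        calls = ssd.cluster_haplotypes(spanning)
        assert [c.haplotype for c in calls] == ["AAAA", "CCCC", "GGGG"]
        assert [c.total_support for c in calls] == [5, 3, 2]
        assert calls[0].support == {"s1": 5, "s2": 0}

    def test_all_identical_is_one_substrain(self):
        spanning = {"s": [(f"r{i}", "ACGT") for i in range(7)]}
        calls = ssd.cluster_haplotypes(spanning)
        assert len(calls) == 1 and calls[0].total_support == 7

    def test_min_support_drops_singletons(self):
        spanning = {"s": [("a", "AAAA"), ("b", "AAAA"), ("c", "CCCC")]}
        calls = ssd.cluster_haplotypes(spanning, min_support=2)
        assert [c.haplotype for c in calls] == ["AAAA"]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ssd.cluster_haplotypes({"s": [("a", "AAAA"), ("b", "AAAAA")]})

    def test_matches_counter_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            pool = ["".join(rng.choice(list("ACGT"), size=6))
                    for _ in range(int(rng.integers(1, 5)))]
            spanning = {
                f"s{j}": [(f"r{j}.{i}", pool[int(rng.integers(len(pool)))])
                          for i in range(int(rng.integers(0, 30)))]
                for j in range(3)}
            calls = ssd.cluster_haplotypes(spanning)
            oracle = Counter(sub for subs in spanning.values()
                             for _, sub in subs)
            assert {c.haplotype: c.total_support for c in calls} == dict(oracle)
            supports = [c.total_support for c in calls]
            assert supports == sorted(supports, reverse=True)
            # per-sample supports partition the spanning reads
            for j in range(3):
                sample = f"s{j}"
                assert sum(c.support[sample] for c in calls) == \
                    len(spanning[sample])

    def test_within_phage_tpm_equals_support_fraction(self):
        """All haplotypes share the window length, so within-phage TPM is
        just the support fraction times 1e6."""
        spanning = {"s": [("a", "AAAA")] * 3 + [("b", "CCCC")] * 1}
        calls = ssd.cluster_haplotypes(spanning)
        assert calls[0].tpm_within_phage["s"] == pytest.approx(750_000.0)
        assert calls[1].tpm_within_phage["s"] == pytest.approx(250_000.0)


class TestElevenSubstrainRecovery:
    def test_deep_error_free_recovery(self, tmp_path):
        """11 planted substrains at 200x spanning coverage, error-free:
        all 11 recovered with frequencies within 3 binomial SE."""
        rng = np.random.default_rng(1)
        freq = rng.dirichlet(np.full(11, 10.0))
        cfg = phage_rich_config(
            seed=1, depth=80_000, read_length=150,
            substrain_spec=SubstrainSpec(n_substrains=11, window_length=75,
                                         freq_ap=tuple(freq),
                                         freq_rp=tuple(freq)))
        sim = simulate_community(cfg, make_fastq=False)
        cid, ws, we = sim.reference.substrain_window
        spanning = {}
        for sample, text in sim.sam_texts.items():
            p = tmp_path / f"{sample}.sam"
            p.write_text(text)
            spanning[sample] = ssd.extract_spanning_reads(p, cid, (ws, we))
        n_span = sum(len(v) for v in spanning.values())
        assert n_span >= 200
        calls = ssd.cluster_haplotypes(spanning)
        assert len(calls) == 11
        assert {c.haplotype for c in calls} == set(sim.truth.haplotypes)
        hap_freq = {h: f for h, f in zip(sim.truth.haplotypes, freq)}
        for c in calls:
            f_true = hap_freq[c.haplotype]
            se = np.sqrt(f_true * (1 - f_true) / n_span)
            assert abs(c.total_support / n_span - f_true) <= 3 * se
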