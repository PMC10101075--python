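"""End-to-end run: simulate -> annotate -> quantify -> substrain -> stats.

Every stage writes plain-text outputs under the run directory and the run
ends with a machine-readable report (parameters, per-stage counters, sha256
checksums of every output).  Re-running with the same config and seed
reproduces all outputs byte-identically; the report deliberately carries no
wall-clock information.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io_utils, prm_annotation, quantification
from . import stats_dynamics as stats
from . import substrain_dynamics as ssd
from .synthetic_community import (CommunityConfig, SubstrainSpec,
                                  simulate_community, write_simulation)


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    community: dict[str, Any] = field(default_factory=dict)
    annotate: dict[str, Any] = field(default_factory=dict)
    substrain: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    sam_dir: str | None = None  # optional external alignments (else simulated)
    log_level: str = "INFO"

    _COMMUNITY_TUPLES = ("contig_length_range", "phage_length_range",
                         "prophage_length_range", "freq_ap", "freq_rp")

    def community_config(self) -> CommunityConfig:
        kw = dict(self.community)
        sub_kw = kw.pop("substrain_spec", None)
        for key in self._COMMUNITY_TUPLES:
            if key in kw:
                kw[key] = tuple(kw[key])
        if sub_kw is not None:
            for key in ("freq_ap", "freq_rp"):
                if key in sub_kw and sub_kw[key] is not None:
                    sub_kw[key] = tuple(sub_kw[key])
            kw["substrain_spec"] = SubstrainSpec(**sub_kw)
        kw["seed"] = self.seed
        try:
            return CommunityConfig(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        self.community_config()
        if self.sam_dir is not None and not Path(self.sam_dir).is_dir():
            raise ConfigError(f"sam_dir {self.sam_dir!r} does not exist")
        for block, allowed in (
            (self.annotate, {"identity_threshold", "min_length", "k",
                             "max_mismatch", "flank_bp"}),
            (self.substrain, {"min_depth", "min_alt_frac", "window", "step",
                              "span_cap", "min_support"}),
            (self.stats, {"fdr", "rho_cut", "p_cut"}),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ConfigError(f"unknown parameter(s) {sorted(unknown)}")


def load_config(path: str | Path, outdir: str | None = None,
                seed: int | None = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if outdir is not None:
        raw["outdir"] = outdir
    if seed is not None:
        raw["seed"] = seed
    if "outdir" not in raw:
        raise ConfigError("config must set outdir (or pass --outdir)")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "tool": "stravir", "version": __version__, "seed": config.seed,
        "parameters": {"community": config.community,
                       "annotate": config.annotate,
                       "substrain": config.substrain,
                       "stats": config.stats},
        "stages": [],
    }
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        ccfg = config.community_config()
        sim = simulate_community(ccfg)
        write_simulation(sim, out / "simulate")
        report["stages"].append({
            "name": "simulate",
            "n_contigs": len(sim.reference.contigs),
            "n_samples": ccfg.n_samples,
            "n_reads_total": int(len(sim.truth.read_origins)),
            "n_substrains_planted": len(sim.truth.haplotypes),
        })

        # --- annotate -----------------------------------------------------
        stage = "annotate"
        ann_dir = out / "annotate"
        ann_dir.mkdir(exist_ok=True)
        akw = config.annotate
        derep = prm_annotation.dereplicate_contigs(
            list(sim.reference.contigs.values()),
            identity_threshold=akw.get("identity_threshold", 0.95),
            min_length=akw.get("min_length", 5000),
            k=akw.get("k", 16))
        cluster_df = pd.DataFrame(sorted(derep.cluster_of.items()),
                                  columns=["contig", "representative"])
        io_utils.write_tsv(cluster_df, ann_dir / "clusters.tsv", index=False)
        annotation = prm_annotation.annotate_reference(
            sim.reference.contigs, sim.reference.phages, sim.reference.arrays,
            max_mismatch=akw.get("max_mismatch", 0),
            flank_bp=akw.get("flank_bp", 5000))
        io_utils.write_tsv(annotation, ann_dir / "phage_annotation.tsv",
                           index=False)
        report["stages"].append({
            "name": "annotate",
            "n_clusters": len(derep.representatives),
            "n_dropped_short": len(derep.dropped_short),
            "n_phages_annotated": len(annotation),
            "n_hosts_predicted": int((annotation["host_taxon"] != "").sum()),
        })

        # --- quantify -----------------------------------------------------
        stage = "quantify"
        q_dir = out / "quantify"
        q_dir.mkdir(exist_ok=True)
        feats = sim.reference.feature_table()
        sam_dir = Path(config.sam_dir) if config.sam_dir else out / "simulate" / "sam"
        per_sample = {}
        for sam_path in sorted(sam_dir.glob("*.sam")):
            per_sample[sam_path.stem] = quantification.count_primary_alignments(
                sam_path, feats)
        if not per_sample:
            raise FileNotFoundError(f"no SAM files under {sam_dir}")
        counts = quantification.counts_table(per_sample, feats["feature_id"])
        lengths = feats.set_index("feature_id")["length"]
        abundance = quantification.relative_abundance(counts, lengths)
        rates = quantification.mapping_rates(per_sample)
        by_class = quantification.aggregate_abundance(
            abundance, dict(zip(feats["feature_id"], feats["feature_class"])))
        by_taxon = quantification.aggregate_abundance(
            abundance, {f: t for f, t in zip(feats["feature_id"], feats["taxon"])
                        if t})
        io_utils.write_tsv(counts, q_dir / "counts.tsv")
        io_utils.write_tsv(abundance, q_dir / "abundance.tsv")
        io_utils.write_tsv(by_class, q_dir / "abundance_by_class.tsv")
        io_utils.write_tsv(by_taxon, q_dir / "abundance_by_taxon.tsv")
        io_utils.write_tsv(rates, q_dir / "mapping_rates.tsv")
        viral = by_class.filter(
            [c for c in by_class.columns if c != "bacteria"]).sum(axis=1)
        report["stages"].append({
            "name": "quantify",
            "n_samples": len(per_sample),
            "mean_mapping_rate": round(float(rates["mapping_rate"].mean()), 6),
            "mean_viral_fraction": round(float(viral.mean()), 6),
        })

        # --- substrain ----------------------------------------------------
        stage = "substrain"
        s_dir = out / "substrain"
        s_dir.mkdir(exist_ok=True)
        skw = config.substrain
        window_contig = (sim.reference.substrain_window[0]
                         if sim.reference.substrain_window else None)
        stage_report = {"name": "substrain"}
        if window_contig is None:
            stage_report["skipped"] = "no lytic phage in the community"
        else:
            contig = sim.reference.contigs[window_contig]
            sam_paths = sorted(sam_dir.glob("*.sam"))
            snps = ssd.call_snps_pooled(
                sam_paths, contig, min_depth=skw.get("min_depth", 5),
                min_alt_frac=skw.get("min_alt_frac", 0.2))
            snps = ssd.annotate_effects(snps, sim.reference.genes,
                                        contig.sequence)
            snp_df = pd.DataFrame(
                [dict(contig=s.contig, position_1based=s.position + 1,
                      ref=s.ref, alt=s.alt, depth=s.depth,
                      alt_count=s.alt_count, effect=s.effect) for s in snps])
            io_utils.write_tsv(snp_df, s_dir / "snps.tsv", index=False)
            density = ssd.snp_window_density(snps, contig.length,
                                             window=skw.get("window", 100),
                                             step=skw.get("step", 100))
            io_utils.write_bed(
                [(contig.id, s, min(s + density.window, contig.length), str(c))
                 for s, c in zip(density.starts, density.counts)],
                s_dir / "snp_density.bed")
            stage_report["n_snps"] = len(snps)
            stage_report["n_nonsynonymous"] = sum(
                s.effect == "nonsynonymous" for s in snps)
            if snps:
                hotspot = ssd.hotspot_window(density,
                                             span_cap=skw.get("span_cap", 100))
                spanning = {p.stem: ssd.extract_spanning_reads(p, contig.id,
                                                               hotspot)
                            for p in sam_paths}
                gene = next((g for g in sim.reference.genes
                             if g.contig == contig.id), None)
                calls = ssd.cluster_haplotypes(
                    spanning, min_support=skw.get("min_support", 1),
                    gene=gene, contig_seq=contig.sequence, interval=hotspot)
                io_utils.write_fasta(
                    {c.substrain_id: c.haplotype for c in calls},
                    s_dir / "substrains.fasta")
                support = pd.DataFrame({c.substrain_id: c.support
                                        for c in calls}).sort_index()
                support.index.name = "sample"
                io_utils.write_tsv(support, s_dir / "substrain_support.tsv")
                tpm_df = pd.DataFrame({c.substrain_id: c.tpm_within_phage
                                       for c in calls}).sort_index()
                tpm_df.index.name = "sample"
                io_utils.write_tsv(tpm_df, s_dir / "substrain_tpm_within_phage.tsv")
                stage_report["hotspot"] = list(hotspot)
                stage_report["n_substrains"] = len(calls)
        report["stages"].append(stage_report)

        # --- stats ----------------------------------------------------------
        stage = "stats"
        t_dir = out / "stats"
        t_dir.mkdir(exist_ok=True)
        tkw = config.stats
        meta = sim.metadata
        phase_feats = stats.compare_phase_groups(abundance, meta,
                                                 fdr=tkw.get("fdr", 0.05))
        phase_class = stats.compare_phase_groups(by_class, meta,
                                                 fdr=tkw.get("fdr", 0.05))
        phase_metab = stats.compare_phase_groups(sim.metabolites, meta,
                                                 fdr=tkw.get("fdr", 0.05))
        corr = stats.easi_correlation(abundance, meta,
                                      rho_cut=tkw.get("rho_cut", 0.5),
                                      p_cut=tkw.get("p_cut", 0.01))
        io_utils.write_tsv(phase_feats, t_dir / "phase_features.tsv", index=False)
        io_utils.write_tsv(phase_class, t_dir / "phase_classes.tsv", index=False)
        io_utils.write_tsv(phase_metab, t_dir / "phase_metabolites.tsv",
                           index=False)
        io_utils.write_tsv(corr, t_dir / "easi_correlation.tsv", index=False)
        report["stages"].append({
            "name": "stats",
            "n_features_tested": len(phase_feats),
            "n_significant_features": int(phase_feats["significant"].sum()),
            "n_significant_metabolites": int(phase_metab["significant"].sum()),
            "n_easi_correlates": int(corr["passes_threshold"].sum()),
        })
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_report.json":
            checksums[str(path.relative_to(out))] = _sha256(path)
    report["checksums"] = checksums
    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
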