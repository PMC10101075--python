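"""Self-validation experiments: recover planted truth from simulated data.

Each function runs one end-to-end experiment against the synthetic
community generator and returns the measured quantities.  They power both
the acceptance test suite and ``scripts/acceptance.py``; problem sizes are
chosen so every experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantification
from . import stats_dynamics as stats
from . import substrain_dynamics as ssd
from .prm_annotation import predict_phage_host
from .synthetic_community import (CommunityConfig, SubstrainSpec,
                                  build_reference, simulate_community,
                                  true_host_assignment)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _write_sams(sim, directory: Path) -> list[Path]:
    paths = []
    for sample, text in sim.sam_texts.items():
        p = directory / f"{sample}.sam"
        p.write_text(text)
        paths.append(p)
    return paths


# ------------------------------------------------------------ formulas
def formula_fidelity(n_tables: int = 20, seed: int = 0) -> dict:
    """Worst relative deviation of the abundance/TPM code from a literal,
    loop-written evaluation of the normalization formulas."""
    rng = np.random.default_rng(seed)
    worst_abun = worst_tpm = 0.0
    for _ in range(n_tables):
        n_f = int(rng.integers(2, 15))
        n_s = int(rng.integers(1, 5))
        counts = pd.DataFrame(
            rng.integers(0, 2000, size=(n_s, n_f)),
            index=[f"s{i}" for i in range(n_s)],
            columns=[f"f{i}" for i in range(n_f)])
        counts.iloc[:, 0] += 1  # keep every sample non-empty
        lengths = {f"f{i}": float(rng.integers(100, 50_000))
                   for i in range(n_f)}
        abun = quantification.relative_abundance(counts, lengths)
        tpm = quantification.tpm(counts, lengths)
        for s in counts.index:
            rates = [counts.loc[s, f] / lengths[f] for f in counts.columns]
            total = sum(rates)
            for f, rate in zip(counts.columns, rates):
                expect_a = rate / total
                expect_t = rate * 1e6 / total
                if expect_a > 0:
                    worst_abun = max(worst_abun,
                                     abs(abun.loc[s, f] - expect_a) / expect_a)
                    worst_tpm = max(worst_tpm,
                                    abs(tpm.loc[s, f] - expect_t) / expect_t)
    return {"max_rel_err_abundance": worst_abun, "max_rel_err_tpm": worst_tpm,
            "n_tables": n_tables}


# ------------------------------------------------------------ substrains
def substrain_recovery(seed: int = 1, error_rate: float = 0.0,
                       min_support: int = 1, depth: int = 45_000) -> dict:
    """Recover 11 planted substrains from ~200x window-spanning coverage.

    Frequencies come from one fixed Dirichlet(10) draw (its own seed 1, so
    the planted composition is a constant of the experiment); read emission
    uses ``seed``.  Returns the recovered count, the worst frequency error
    in binomial-SE units, and recovery of substrains at >= 5% frequency.
    """
    freq = np.random.default_rng(1).dirichlet(np.full(11, 10.0))
    cfg = CommunityConfig(
        n_bacteria=1, n_lytic_phages=1, n_prophages=0,
        contig_length_range=(15_000, 18_000),
        phage_length_range=(12_000, 12_000),
        n_samples=2, n_ap=1, n_rp=1, depth=depth, read_length=150,
        error_rate=error_rate, unmapped_fraction=0.0,
        baseline_sigma=0.0, feature_sigma=0.0,
        class_weights={"bacteria": 1.0, "lytic_phage": 1.0},
        substrain_spec=SubstrainSpec(n_substrains=11, window_length=75,
                                     freq_ap=tuple(freq),
                                     freq_rp=tuple(freq)),
        seed=seed)
    sim = simulate_community(cfg, make_fastq=False)
    cid, ws, we = sim.reference.substrain_window
    with tempfile.TemporaryDirectory() as tmp:
        spanning = {}
        for p in _write_sams(sim, Path(tmp)):
            spanning[p.stem] = ssd.extract_spanning_reads(p, cid, (ws, we))
    calls = ssd.cluster_haplotypes(spanning, min_support=min_support)
    n_span = sum(len(v) for v in spanning.values())
    truth = dict(zip(sim.truth.haplotypes, freq))
    recovered = {c.haplotype for c in calls}
    worst_se = 0.0
    for hap, f_true in truth.items():
        support = next((c.total_support for c in calls if c.haplotype == hap), 0)
        se = np.sqrt(f_true * (1 - f_true) / n_span)
        worst_se = max(worst_se, abs(support / n_span - f_true) / se)
    major = {h for h, f in truth.items() if f >= 0.05}
    return {
        "n_planted": 11,
        "n_recovered": len(recovered & set(truth)),
        "n_called": len(calls),
        "n_spanning_reads": n_span,
        "spanning_coverage": n_span,  # one read = one window observation
        "max_freq_err_se_units": float(worst_se),
        "major_substrains_recovered": len(recovered & major),
        "n_major_substrains": len(major),
    }


# ------------------------------------------------------------ abundance
def abundance_recovery(n_seeds: int = 50, depth: int = 100_000,
                       seed: int = 0) -> dict:
    """Simulate -> quantify round trip at 30 features.

    Counts the fraction of feature-sample abundance estimates within three
    binomial standard errors of the planted truth (on the read-fraction
    scale, where the multinomial sampling error is exactly binomial per
    feature)."""
    n_ok = n_tot = 0
    for child in _spawn_seeds(seed, n_seeds):
        cfg = CommunityConfig(
            n_bacteria=18, n_lytic_phages=8, n_prophages=4,
            contig_length_range=(17_000, 22_000),
            phage_length_range=(8_000, 14_000),
            prophage_length_range=(6_000, 6_500),
            n_samples=2, n_ap=1, n_rp=1, depth=depth,
            error_rate=0.0, unmapped_fraction=0.0, seed=child)
        sim = simulate_community(cfg, make_fastq=False)
        feats = sim.reference.feature_table()
        lengths = feats.set_index("feature_id")["length"]
        truth = sim.truth.true_abundances
        with tempfile.TemporaryDirectory() as tmp:
            per = {p.stem: quantification.count_primary_alignments(p, feats)
                   for p in _write_sams(sim, Path(tmp))}
        counts = quantification.counts_table(per, feats["feature_id"])
        for sample in counts.index:
            mapped = per[sample].mapped_reads
            p_true = (truth.loc[sample] * lengths).to_numpy()
            p_true = p_true / p_true.sum()
            p_hat = counts.loc[sample].to_numpy() / mapped
            se = np.sqrt(p_true * (1 - p_true) / mapped)
            n_ok += int(np.sum(np.abs(p_hat - p_true) <= 3 * se))
            n_tot += len(p_true)
    return {"fraction_within_3se": n_ok / n_tot, "n_estimates": n_tot,
            "n_seeds": n_seeds, "n_features": 30, "depth": depth}


# ------------------------------------------------------------ statistics
def fdr_null_control(n_reps: int = 200, n_features: int = 50,
                     n_ap: int = 11, n_rp: int = 13, sigma: float = 0.4,
                     seed: int = 0) -> dict:
    """Mean false-discovery count at FDR < 0.05 on fully null tables."""
    rng = np.random.default_rng(seed)
    meta = _phase_meta(n_ap, n_rp)
    false_total = 0
    for _ in range(n_reps):
        table = pd.DataFrame(
            rng.lognormal(0, sigma, size=(n_ap + n_rp, n_features)),
            index=meta.index, columns=[f"f{i}" for i in range(n_features)])
        res = stats.compare_phase_groups(table, meta)
        false_total += int(res["significant"].sum())
    return {"mean_false_discoveries": false_total / n_reps, "n_reps": n_reps,
            "n_features": n_features}


def phase_effect_power(n_reps: int = 100, n_features: int = 50,
                       n_ap: int = 11, n_rp: int = 13, fold: float = 3.0,
                       sigma: float = 0.4, seed: int = 0) -> dict:
    """Power to recover 4 lysogenic-down + 2 lytic-up planted effects.

    Counts replicates in which all six planted features are significant at
    FDR < 0.05 with the correct direction."""
    rng = np.random.default_rng(seed)
    meta = _phase_meta(n_ap, n_rp)
    is_rp = (meta["phase"] == "RP").to_numpy()
    down = [f"f{i}" for i in range(4)]  # lysogenic-like: reduced in RP
    up = [f"f{i}" for i in range(4, 6)]  # lytic-like: increased in RP
    all_six = 0
    for _ in range(n_reps):
        table = pd.DataFrame(
            rng.lognormal(0, sigma, size=(n_ap + n_rp, n_features)),
            index=meta.index, columns=[f"f{i}" for i in range(n_features)])
        table.loc[is_rp, down] /= fold
        table.loc[is_rp, up] *= fold
        res = stats.compare_phase_groups(table, meta).set_index("feature")
        ok = all(res.loc[f, "significant"] and res.loc[f, "direction"] == d
                 for f, d in [(f, "down_RP") for f in down]
                 + [(f, "up_RP") for f in up])
        all_six += ok
    return {"fraction_all_six_recovered": all_six / n_reps, "n_reps": n_reps}


def _phase_meta(n_ap: int, n_rp: int) -> pd.DataFrame:
    phases = ["AP"] * n_ap + ["RP"] * n_rp
    return pd.DataFrame(
        dict(day=range(1, n_ap + n_rp + 1), phase=phases,
             easi=[20.0 if p == "AP" else 0.0 for p in phases]),
        index=[f"S{i + 1:02d}" for i in range(n_ap + n_rp)])


# ------------------------------------------------------------ hosts
def host_prediction_recovery(n_seeds: int = 50, seed: int = 0) -> dict:
    """Planted CRISPR spacer -> phage links recovered at zero mismatches.

    Every planted spacer (forward or reverse-complement placement) must hit
    its assigned phage; phages that received no spacer from an array must
    draw zero links to it."""
    n_links = n_found = n_false = 0
    for child in _spawn_seeds(seed, n_seeds):
        cfg = CommunityConfig(
            n_bacteria=3, n_lytic_phages=3, n_prophages=0,
            contig_length_range=(12_000, 15_000),
            phage_length_range=(8_000, 10_000),
            n_samples=2, n_ap=1, n_rp=1, depth=1,
            substrain_spec=SubstrainSpec(n_substrains=1, window_length=30),
            seed=child)
        ref = build_reference(cfg)
        host_of = true_host_assignment(cfg)
        spacer_home = {}
        for pid, host_contig in host_of.items():
            arr = next(a for a in ref.arrays if a.host_contig == host_contig)
            phage_seq = ref.contigs[pid].sequence
            from .prm_annotation import revcomp
            for sp in arr.spacers:
                if sp.sequence in phage_seq or revcomp(sp.sequence) in phage_seq:
                    spacer_home.setdefault(pid, set()).add(sp.sequence)
        for pid in host_of:
            phage = ref.contigs[pid]
            matches = predict_phage_host(phage, ref.arrays, max_mismatch=0)
            hit_spacers = {m.spacer for m in matches}
            planted = spacer_home.get(pid, set())
            n_links += len(planted)
            n_found += len(planted & hit_spacers)
            n_false += len(hit_spacers - planted)
    return {"n_planted_links": n_links,
            "fraction_recovered": n_found / n_links if n_links else float("nan"),
            "n_false_links": n_false, "n_seeds": n_seeds}


# ------------------------------------------------------------ determinism
def demo_determinism(seed: int = 7, workdir: str | Path | None = None) -> dict:
    """Run the bundled demo twice; compare output checksums byte-for-byte."""
    from .cli import demo_config_path
    from .pipeline import load_config, run_pipeline

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        reports = []
        for name in ("run1", "run2"):
            cfg = load_config(demo_config_path(),
                              outdir=os.path.join(tmp, name), seed=seed)
            reports.append(run_pipeline(cfg))
    identical = reports[0]["checksums"] == reports[1]["checksums"]
    return {"identical": identical,
            "n_outputs_compared": len(reports[0]["checksums"]),
            "n_stages": len(reports[0]["stages"])}
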