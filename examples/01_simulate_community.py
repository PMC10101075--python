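"""Simulate a longitudinal gut community with planted virome dynamics.

Builds the default study-like design — 24 samples (2 remission, 11 active,
11 remission), lytic phages boosted and prophages suppressed in remission —
at a reduced sequencing depth, and prints what was planted.
"""

from stravir.synthetic_community import (CommunityConfig, phase_labels,
                                         simulate_community)

config = CommunityConfig(depth=4000, seed=7)
sim = simulate_community(config, make_fastq=False)

ref = sim.reference
print(f"reference: {len(ref.contigs)} contigs "
      f"({sum(c.origin == 'viral' for c in ref.contigs.values())} free phage, "
      f"{len(ref.prophage_regions)} embedded prophage)")
cid, ws, we = ref.substrain_window
print(f"substrain window: {we - ws} bp at {cid}:{ws}-{we} "
      f"inside the tail-fiber gene")
print(f"planted substrains: {len(sim.truth.haplotypes)}")
print(f"samples: {config.n_samples} "
      f"({phase_labels(config).count('AP')} AP / "
      f"{phase_labels(config).count('RP')} RP), "
      f"{len(sim.truth.read_origins)} reads total")

by_class = sim.truth.true_abundances.T.groupby(
    ref.feature_table().set_index("feature_id")["feature_class"]).sum().T
print("\nmean true abundance by class and phase:")
phases = phase_labels(config)
for cls in by_class.columns:
    ap = by_class.loc[[p == "AP" for p in phases], cls].mean()
    rp = by_class.loc[[p == "RP" for p in phases], cls].mean()
    print(f"  {cls:15s} AP {ap:.4f}  RP {rp:.4f}")

# Lytic phages rise and prophages fall in remission: that asymmetry is the
# planted signal the phase-comparison statistics are meant to detect.
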