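"""Predict phage hosts from CRISPR spacers and prophage flanks.

Builds a small reference in which each bacterium's CRISPR array stores
spacers copied from its phage (some reverse-complemented), then asks the
predictor to find them, and attributes the embedded prophage to its host
via the flanking bacterial sequence.
"""

from stravir import prm_annotation as ann
from stravir.synthetic_community import CommunityConfig, build_reference

config = CommunityConfig(n_bacteria=3, n_lytic_phages=3, n_prophages=1,
                         seed=5)
ref = build_reference(config)
taxon_of = {cid: c.taxon for cid, c in ref.contigs.items() if c.taxon}

for phage_ann in ref.phages:
    if phage_ann.kind != "phage":
        continue
    phage = ref.contigs[phage_ann.contig_id]
    matches = ann.predict_phage_host(phage, ref.arrays, max_mismatch=0,
                                     taxon_of=taxon_of)
    ranked = ann.rank_hosts(matches)
    host = ranked[0][0] if ranked else None
    name = ann.phage_name(host, "phage", phage.length, clade=phage_ann.clade)
    hits = ", ".join(f"{h} ({n} spacers)" for h, n in ranked) or "none"
    print(f"{phage.id} -> {name}; spacer hits: {hits}")

for phage_ann in ref.phages:
    if phage_ann.kind != "prophage":
        continue
    taxon, high = ann.assign_prophage_host(phage_ann, ref.contigs)
    region = phage_ann.prophage_region
    name = ann.phage_name(taxon, "prophage", region.length)
    conf = "high" if high else "low"
    print(f"{region.phage_id} -> {name} ({conf}-confidence flank assignment)")
# A spacer match (either strand) implicates the carrying bacterium as the
# phage's host; prophages inherit the taxon of their flanking sequence.
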