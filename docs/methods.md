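# Methods

## The model

The unit of analysis is one subject's longitudinal stool series, mapped
against a personal reference metagenome (PRM): a dereplicated set of
contigs covering every bacterium, free phage and embedded prophage the
subject carries. Three layers of signal are modelled on top of the PRM:

1. **Abundance.** Read counts per feature, corrected for feature length
   and closed to 1 per sample: `abun_i = (C_i/L_i) / Σ(C_j/L_j)`. The
   closure means abundances are compositional — only ratios are
   meaningful, and a genome assembled in k pieces contributes the sum of
   k per-contig rates, which up-weights fragmented genomes relative to a
   single-contig assembly (the price of the formula; see Limitations).
   TPM is the same quantity scaled by 10⁶ and is unit-invariant in L as
   long as all features share a unit.
2. **Substrains.** Within one phage, co-circulating substrains are assumed
   to differ only at substitution sites concentrated in one short window
   (≤100 bp) of a tail-fiber gene — no indels, no recombination, fixed
   differences. Under that assumption a read that fully spans the window
   is a complete haplotype observation, and exact-identity clustering of
   spanned substrings (the meaning of 100%-identity clustering here) both
   separates all substrains and estimates their frequencies as support
   fractions.
3. **Phase structure.** Samples belong to an active phase (AP) or
   remission phase (RP) of eczema. Lytic phage abundance is modelled as
   elevated in RP and prophage abundance as reduced; metabolite
   concentrations and the EASI severity score carry the same phase
   signal. All group comparisons are rank-based (Mann-Whitney U with
   Benjamini-Hochberg FDR across features at 0.05; Spearman against EASI
   with the joint |ρ| > 0.5, p < 0.01 rule), so only orderings matter.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_depth` / `min_alt_frac` (SNP caller) | 5 / 0.2 | reads / fraction | a site is a SNP iff depth ≥ 5 and the top non-reference base reaches 20%; deep fixed substrain differences pass easily, isolated sequencing errors need ≥ depth×0.2 co-occurrences. At the depth-5 boundary a single error is exactly 0.2 and can create a stray call; raise `min_depth` for shallow data. |
| `window` / `step` (SNP density) | 100 / 100 bp | tiling windows; `step < window` gives sliding windows. |
| `span_cap` (hotspot) | 100 bp | caps the reported hotspot interval; ties between equal-count windows break leftmost. |
| `min_support` (haplotype clustering) | 1 | reads | 1 retains singletons (exact-identity clustering keeps every distinct read); 2 is recommended for noisy data and removes almost all error-generated singleton haplotypes at per-base error ≤ 0.1%. |
| `identity_threshold` / `min_length` (dereplication) | 0.95 / 5000 bp | identity is defined over the shorter sequence; the k-mer estimate `f^(1/k)` (k = 16) is confirmed by exact semi-global alignment when within ±0.03 of the threshold. |
| `max_mismatch` (spacer matching) | 0 | exact protospacer matching on either strand; the tolerance is exposed because real spacer-protospacer pairs can carry mismatches. |
| `flank_bp` (prophage host) | 5000 bp | both flanks must hold this much bacterial sequence for a high-confidence host call; shorter flanks still return the taxon, flagged low-confidence. |
| exact-test switchovers | n₁+n₂ ≤ 12 (MW), n ≤ 9 (Spearman) | enumeration is exact and cheap at these sizes; above them the normal/t approximations with tie and continuity corrections take over. Flags force either mode. |

## The synthetic community

The generator is first-class, tested code; its defaults are the study
conditions the analysis assumes. Sample design: 24 samples, 11 AP and 13
RP with the RP samples bracketing the AP block (2 before, 11 after);
collection days strictly increasing with 4–9-day gaps (≈170-day span).
Community: 5 bacterial contigs (40–80 kb, GC 0.47), 3 lytic phages
(20–60 kb, GC 0.41 — lytic phages in this system run AT-richer than
lysogenic ones), 2 prophages (12–25 kb) embedded with ≥5 kb flanks. The
first lytic phage is the crAssphage stand-in: it carries a 1200-bp
tail-fiber CDS (random sense codons, either strand) containing a 75-bp
window with 11 substrain haplotypes whose every substitution is
nonsynonymous by construction (verified against the standard code at draw
time and independently in tests). AP frequencies put all mass on 3
substrains; RP frequencies are geometrically decaying over all 11 —
emulating the observed post-diarrhoea diversification.

Abundance: per-feature scale = class weight × lognormal(0, 0.5), with
class weights 1 : 0.08 : 0.03 (bacteria : lytic phage : prophage), giving
a viral DNA fraction around 6–12%; per-sample noise is lognormal with
σ = 0.4. Neither the within-subject variability nor per-sample depth is
published for the motivating study, so both are package choices: σ = 0.4
is a moderate repeat-sampling spread under which a 3-fold phase effect is
a ≈2.75 σ shift on the log scale — detectable but not trivial at n = 11/13
— and the default depth is 20,000 reads/sample (scaled per experiment).
Phase effects multiply lytic features by 3 and divide lysogenic features
by 3 in RP, then rows are renormalized.

Reads: counts per feature are multinomial with probability ∝ abundance ×
feature length, so the quantifier's C/L correction is the exact inverse of
the generative model and parameter recovery is a sharp test. Host reads
are placed only outside embedded prophage regions and prophage reads only
inside, with the host feature length reduced by the embedded length — this
keeps the midpoint-attribution rule exact rather than approximately right
at region boundaries. Reads overlapping the substrain window draw a
haplotype from the sample's frequency vector and carry its bases.
Substitution errors are uniform at the configured rate; a binomial
fraction of reads is emitted unmapped (FLAG 4). CIGARs are full-length
matches (no indels), which is also the analysis modules' contract —
indel-bearing records in real SAM are skipped and counted. Random streams
are split per emitter (reference / substrains / abundance / reads /
metadata), so changing depth never perturbs the reference; all emitters
are byte-identical for a fixed seed.

What the generator does *not* emulate — and hence what green tests do not
show about real data: mapping ambiguity between homologous contigs
(every read is emitted at its true locus, so the ~99% mapping rates here
are by construction, not an alignment benchmark), indels and structural
variation, quality-score-correlated errors, GC or position coverage bias,
strain recombination, and compositional coupling beyond the closure.

## Validation experiment sizes

`stravir.validation` fixes the problem sizes: substrain recovery uses a
12-kb phage plus one bacterium with deterministic composition
(σ = 0 both levels) so that depth 45,000 × 2 samples yields ~200–350
window-spanning reads; the planted frequency vector is one fixed
Dirichlet(10·1) draw (its own seed), keeping every substrain ≥ 5% so
recovery is not left to chance at this coverage. Abundance recovery uses
30 features (18 bacteria + 8 lytic + 4 prophages, 6–22 kb contigs) at
depth 100,000 over 2 samples × 50 seeds, comparing estimates to truth on
the read-fraction scale where multinomial error is exactly binomial per
feature. FDR/power experiments use 50-feature lognormal tables at the
study group sizes (11 vs 13). The demo pipeline runs 24 samples at depth
5000 — deep enough to call the major substrain SNPs, shallow enough to
finish in seconds per stage.

## Numerical and design choices

- Coordinates are 0-based half-open internally; SAM/GFF3 convert at the
  I/O boundary, BED stays 0-based. All tables are TSV (taxon labels
  contain commas).
- Counting is primary-alignment-only (secondary/supplementary excluded);
  the mapping rate denominator is all reads including unmapped records.
  An empty SAM reports mapping rate as not-available rather than 0.
- BH q-values use the step-up rule `q_(i) = min_{j≥i} m·p_(j)/j` mapped
  back to input order; features all-zero across samples are excluded
  before adjustment so m counts only testable features.
- Degenerate inputs are flagged, not silently computed: two identical
  constant groups give p = 1 (degenerate), a constant vector gives
  ρ = not-available, an all-zero sample gives a flagged zero row.
- The haplotype substring is taken from the read's own bases (not
  reference-corrected): clustering read sequences is the operation being
  modelled. Reads with any clip or indel inside the window are excluded
  from "fully spanning".
- Substrain TPM is emitted both within-phage (universe = the haplotypes;
  equal lengths make it the support fraction × 10⁶) and whole-sample,
  labeled, because either normalization is defensible.
- The increment analysis emits both an unpaired Mann-Whitney of t1 vs t2
  within each group and a paired Wilcoxon signed-rank, labeled.
- Canonical phage names use "-" throughout; underscore variants are
  accepted via an alias map when parsing.
- The particle-ratio calibration is reported as computed from the
  supplied fractions and mean genome sizes; it is a rough calibration,
  sensitive to the averaging scheme used for the input fractions.

## Known limitations

- The abundance formula's fragmentation bias (above) means species
  abundances depend on assembly contiguity; comparisons are valid within
  one PRM, not across differently assembled references.
- Exact-identity haplotype clustering treats every sequencing error in a
  spanning read as a new haplotype; `min_support` mitigates but does not
  model errors. At error rates well above ~1% per window a
  probabilistic clusterer would be needed.
- The SNP caller reports one alternative allele per site; a site where
  two substrains carry different alternatives is summarized by the more
  frequent one (haplotyping, which sees whole windows, is unaffected).
- Host prediction ranks hosts by spacer hit counts only; it does not
  weight spacer age or array position, and reports ties rather than
  resolving them.
- No multi-mapper handling: reads are counted where the aligner put their
  primary alignment. With homologous prophage/phage pairs in a real PRM,
  upstream mapping choices will shape the counts.
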