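# Methods

## Scope and data model

`mnvkit` analyses decomposed, normalized, biallelic records of phased
multi-sample VCFs (GT with `|`/`/` separators, PS phase sets, GQ/DP/AD).
Coordinates are 1-based inclusive internally (VCF convention); all BED
interfaces are 0-based half-open.  The model is diploid-autosome only:
restricting to autosomes keeps zygosity homogeneous across samples, and an
`--autosomes-only` flag enforces it at scan time.

## Discovery

A windowed scan pairs variants within `max_dist` bp (default 10; a 2 bp
window reproduces exome-style analyses).  Distance is `d = pos2 − pos1`, so
"within 2 bp" means `d ≤ 2` and adjacent means `d = 1`.  Cis-ness per
sample:

* hom-alt × hom-alt — cis on both haplotypes; no phase needed (zygosity
  forces it).  Contributes 2 to `AC_mnv` and one homozygous carrier.
* het × hom-alt — the het's alternate haplotype necessarily carries the
  hom-alt allele; counted cis (1 haplotype) without requiring phase.
* het × het — requires both genotypes phased in the same phase set; same
  haplotype side is cis (1), opposite is trans (0), anything else is
  unphased and contributes nothing.

Pairs in which either call fails QC (`FILTER=PASS`, non-LCR, GQ ≥ 20,
DP ≥ 10, AB > 0.2 for hets; missing GQ/DP fails) are dropped entirely
rather than demoted.  `AC1`/`AC2` are cohort alternate-allele counts over
all called genotypes; `AC_mnv` counts haplotypes, and `n_indiv` counts
carrier individuals, because released cohort tables are ambiguous about
which unit they report — both are emitted.  SNV-pair and indel-pair scans
are separate passes; mixed pairs are out of scope.

## Pattern algebra

A pattern is the ordered pair of changed bases (`ref`, `alt`) with the
inter-SNV distance; reverse complements are collapsed to the
lexicographically smaller form.  The adjacent space is 16 × 9 = 144 ordered
patterns → 78 canonical, 12 self-complementary.  Origin classes used for
regional summaries partition the 78: CpG signal {CA→TG, AC→GT, CC→TT,
GA→AG}, pol-zeta {GC→AA, GA→TT}, repeat {AA→TT, TA→AT, AT→TA},
transversion {TA→GC, CG→AT, AT→CG, CG→GC, GC→CG, CG→AC}, and 63 others.

## Mechanism inference

**One-step MNVs.**  `AC1 = AC2` marks a candidate single-generation event;
strict mode additionally requires `AC_mnv/AC1 ≥ 0.9`, which suppresses
chance equality of unrelated allele counts.  Comparisons are cohort-wide.

**Repeat contexts.**  The ±4 bp context is scanned for gapped, overlapping
occurrences of the reference pair (in the reference context) and the
alternate pair (in the mutated context); a gap of `d − 1` bases sits between
the unit's two characters.  An MNV is repetitive when both counts exceed 1
and either exceeds 2; for adjacent MNVs whose reference and/or alternate
pair is a mononucleotide run, the thresholds on that side rise by one to
compensate for the run overlapping itself.  Note this demands repeats on
*both* sides: a substitution that destroys the repeat (CA→TG inside a CA
tract) is not repetitive, which is consistent with the repeat-prone pattern
set {AA→TT, AT→TA, TA→AT} — exactly the substitutions that preserve repeat
structure.  Contexts that run off a contig edge are skipped (classified
non-repetitive) rather than padded.

**Independent-SNV null.**  The two temporal orders of an adjacent doublet
give `p(WX→YZ) ∝ p(WX→YX)·p(YX→YZ) + p(WX→WZ)·p(WZ→YZ)`, each step a
3-mer-context SNV rate (192-entry table).  The bases flanking the
dinucleotide are marginalized over a flank distribution (uniform by
default; any composition, or exact flanks, can be supplied) — the
marginalization factorizes because each path's two rates depend on disjoint
flanks.  The model is defined for adjacent patterns; at `d > 1` the two
contexts decouple and no doublet-specific null is needed.

**Excess factor q.**  Observed non-repeat counts are modelled as
`N_p = E_p + Q_p` with `E_p = C · p_null(p) · N_WX(p) · n_individuals`.
The single scale `C` is fitted by least squares in log space over a
calibration set — all canonical patterns outside the pol-zeta and repeat
classes with nonzero counts — which is robust to the heavy-tailed spectrum;
the calibration strategy is isolated so a total-count-matching alternative
can be swapped in.  `q̂_p = max(0, 1 − E_p/N_p)` is the fraction of the
pattern's non-repeat MNVs attributed to single-event mechanisms.  Origin
fractions per pattern (summing to 1 exactly): repeat = repeat-context share
of all the pattern's MNVs; the remainder splits into snv_combination
(`1 − q̂`) and other (`q̂`).

**Predicted mechanism labels** follow an ordered rule: pol-zeta for
{GA→TT, GC→AA}; repeat when the repeat-context fraction exceeds 10%;
otherwise a composition label (Ti at CpG / Ti / Ti at CpG + Tv / Ti + Tv /
Tv combination) derived from the two substitution steps, using only the
pattern-internal neighbour bases to decide CpG status (a C→T step is "at
CpG" if either the reference or the post-first-step neighbour provides the
3' G).  Flank-dependent CpG status is deliberately not guessed.

**Mutation rates.**  Following a Watterson-style argument (no recurrent
mutation, so one-step MNV sites are single origination events),
`μ_MNV = (n_MNV_sites / n_SNV_sites) · μ_SNV` per 2 bp per generation, with
`μ_SNV = 1.2 × 10⁻⁸` by default.  The per-pattern rate redistributes the
global rate by each pattern's share of one-step sites and the inverse of
its dinucleotide opportunity count, times a user-supplied scalar
`coverage_factor` (default 1.0 — the published coverage correction is not
specified, so it is left explicit).  The split conserves the global rate:
Σ_p r_p·N_WX(p) = μ_MNV·Σ N_WX.  Expected events per generation per
pattern are `r_p · N_WX(p)`.

## Coding impact

Consequences are codon-level on the canonical transcript: the reference
codon, both single-mutant codons and the double-mutant codon are translated
with the standard genetic code (strand-aware for − transcripts).  The
category decision table, in order: gained_nonsense (MNV is a stop, neither
SNV is); rescued_nonsense (an SNV is a stop, the MNV is not); gained_missense
(both SNVs synonymous, MNV not); unchanged (the MNV amino acid already
produced by an individual SNV); changed_missense (MNV differs from both
individual outcomes, MNV and at least one SNV missense); other_changed (the
rest, e.g. the MNV restoring the reference amino acid).  The boundary
between changed_missense and other is a design reading and is isolated in
one function (`classify_consequence`) for easy revision.  Cross-codon pairs
are counted but not categorized; start-codon and splice effects and
three-SNV codons are out of scope.  Rescued-nonsense records carry a
`fully_rescued` flag (`AC_mnv` equals the nonsense SNV's allele count), and
per-gene tallies can be restricted to fully rescued events.  Constraint
enrichment is a two-sided Fisher's exact test of category membership against
a constrained-gene set, with a Haldane half-count on the odds ratio only
when a cell is zero (flagged).

Frame-restoring indel pairs require each constituent out-of-frame (length
change ≢ 0 mod 3) and the sum in-frame, within 30 bp; two individually
in-frame indels restore nothing and are excluded.

## Phasing evaluation

Read-based relative phase of a het pair is cis/trans when both genotypes are
phased in one phase set, else unphased.  Phase-by-transmission assigns each
child alternate allele to a parent when the configuration forces it (a
parent without the alternate, or without the reference, at that site);
cis iff both alternates trace to one parent; both-parents-het (or missing
parents) is inherently uninformative; Mendelian-inconsistent sites flag the
pair as a violation and exclude it.  Sensitivity is the assigned fraction
among het pairs; because the published specificity denominator is
ambiguous, the summary reports both cis-call concordance (among
trio-informative read-cis pairs) and overall agreement (among
trio-informative, read-assigned pairs), per distance bin (1–10 bp singly,
then decades to 100 bp).

## Synthetic cohorts

Samples are two explicit haplotype variant sets, so cis/trans truth is
exact and the VCF (GT:PS:GQ:DP:AD) is derived, not simulated from reads.
Planted mechanisms: independent-SNV events draw their pattern from the
null spectrum (path probability × opportunity) and their two allele counts
independently; pol-zeta events use the doublet motifs with one shared
allele count; slippage events swap a unit inside a planted dinucleotide
tract (XY→YX), verified against the repeat classifier at plant time.
Planting orientation is balanced between a pattern and its reverse
complement.  Allele counts are geometric (p = 0.5 by default) — no
generative allele-frequency model is standard here, so the choice is
recorded in the truth-manifest metadata.  Events are spaced ≥ 12 bp apart
so no unintended pairs enter a 10 bp scan window.  One phase set spans the
contig by default; a fragmentation rate starts new phase sets between
consecutive variants to emulate incomplete read-backed phasing, and an
unphased-noise rate degrades individual het genotypes.  Trio cohorts
transmit whole parental haplotypes (no recombination), covering
transmission-forced, inherently uninformative and de-novo (violation)
configurations.  All output is byte-deterministic for a fixed seed.

What the generator does **not** emulate: read-level errors and coverage
variation (GQ/DP/AD are fixed nominal values), genotyping error,
recombination, population structure, recurrent mutation, and realistic
allele-frequency spectra.  Passing recovery tests therefore demonstrates
the correctness of the pipeline's logic and estimator calibration under the
stated generative model, not robustness to real-data artefacts.

## Recovery experiments and problem sizes

The drivers in `mnvkit.experiments` run the full plant → VCF → scan →
classify → estimate loop on cohorts of 1000 diploid samples.  The
excess-recovery experiment plants ~3000 null events plus a controlled
pol-zeta doublet excess and uses a flat (context-independent) rate table so
every pattern receives a comparable null count — that is what gives the q
estimator measurable precision at this cohort size; spectral skew is
exercised separately with the three-level table (transversion 2×10⁻⁹,
transition 8×10⁻⁹, CpG transition 8×10⁻⁸ per bp per generation, a
conventional rate hierarchy averaging near the global SNV rate).  The
recovery standard error uses the Poisson delta method on the expected and
observed pooled counts.  Density uniformity is checked per annotation tile
with all patterns pooled (the per-tile aggregate has expectation 1 under
opportunity-proportional planting); methylation dependence is planted by
accepting CpG-class event positions with probability equal to the local
tile's methylation level.

## Numerical and degenerate-input conventions

Zero allele counts in one-step classification are an error (such a record
cannot be observed).  An all-zero spectrum or empty calibration set makes q
undefined and raises.  Patterns with zero observed non-repeat count get
`q̂ = 0` with an `undefined` flag.  Zero dinucleotide opportunities flag the
density as undefined (NaN) rather than raising.  Constant vectors in the
methylation correlation yield NaN r.  Ratios use exact integer counts until
the final division.  All randomness flows through `numpy.random.default_rng`
with explicit seeds.

## Known limitations

* The q normalization constant is reconstructed (log-space least squares on
  a calibration set); published per-pattern rate constants need not be
  reproducible from this choice.
* Indel-rate-versus-repeat-length modelling, population-stratified one-step
  comparison, LOFTEE-style LoF confidence, CADD, and statistical
  (population) phasing are out of scope.
* The 3-mer rate model assumes context rates are invariant across the
  genome; regional rate variation is not modelled.
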