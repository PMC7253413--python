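# mnvkit

Multi-nucleotide variants (MNVs) are pairs of nearby variants carried on the
same haplotype of one individual.  Standard per-site annotation mis-reads
them: two SNVs in one codon can jointly create a stop codon that neither
creates alone, or cancel a stop codon that one of them would create.  Their
population distribution also encodes mutational mechanism — CpG deamination,
error-prone polymerase-zeta doublet errors, and polymerase slippage at short
tandem repeats each favour characteristic substitution patterns.

`mnvkit` is a pipeline for cohort geneticists working with phased
multi-sample VCFs.  It

* **discovers** in-cis variant pairs within a scan window (default 10 bp),
  applying genotype QC (site `PASS`, outside low-complexity regions,
  GQ ≥ 20, DP ≥ 10, allele balance > 0.2 for hets) and aggregating cohort
  allele counts `AC1`, `AC2`, `AC_mnv`;
* **canonicalizes** substitution patterns over strands — the 16 × 9 ordered
  adjacent patterns collapse to 78, of which 12 are self-complementary;
* **re-annotates** codon-level combined consequences (gained/rescued
  nonsense, gained/changed missense, …) and frame-restoring indel pairs;
* **scores phasing** by comparing read-based phase (GT/PS) with
  phase-by-transmission in trios;
* **infers mechanism**: one-step MNVs (equal constituent allele counts),
  repeat contexts (±4 bp gapped repeat-unit counting), and the excess
  fraction *q* of each pattern over an independent-SNV null in which

  p(WX→YZ) ∝ p(WX→YX)·p(YX→YZ) + p(WX→WZ)·p(WZ→YZ) + q(WX→YZ),

  with each step a 3-mer-context SNV rate;
* **estimates mutation rates** Watterson-style:
  μ_MNV = (MNV sites / SNV sites) · μ_SNV, redistributed per pattern by
  one-step share and dinucleotide opportunity, and
* **profiles density** D(WX→YZ | I) = N(WX→YZ | I) / N(WX | I) across
  annotation interval sets, with methylation correlation and per-region
  origin-class fractions.

A synthetic-cohort generator plants MNVs of known mechanism on explicit
haplotypes (with trio families, unphased-genotype noise and phase-set
fragmentation), so every stage is testable without cohort data.

## Worked example

```python
from mnvkit import (CohortSpec, generate_reference, plant_cohort, scan_mnvs,
                    genome_dinuc_counts, MutationRateTable)
from mnvkit.mechanism import estimate_q, partition_by_context
from mnvkit.synthetic import RepeatSpec

tracts = [RepeatSpec("TA" if i % 2 else "CA", 8, 2000 + 150 * i) for i in range(40)]
bundle = generate_reference(60_000, repeat_spec=tracts, seed=0)
spec = CohortSpec(
    n_samples=100, n_events=300,
    mechanism_mix={"independent_snv": 0.6, "pol_zeta": 0.3, "slippage": 0.1},
)
manifest = plant_cohort(bundle, spec, "cohort.vcf", seed=0)
records = scan_mnvs("cohort.vcf", max_dist=10)
print(f"{len(records)} MNVs discovered ({len(manifest.events)} planted)")

table = MutationRateTable.default()
nonrep, rep, onestep = partition_by_context(records, bundle.contigs)
stats = estimate_q(nonrep, table, genome_dinuc_counts(bundle.contigs),
                   n_individuals=100, repeat_counts=rep, one_step_counts=onestep)
for s in stats:
    if s.pattern.label in ("GA->TT", "GC->AA", "CA->TG", "TA->AT"):
        print(f"{s.pattern.label}: n={s.n_obs:3d} one-step={s.n_one_step:3d} "
              f"repeat={s.n_repeat:2d} q={s.q_hat:.2f} -> {s.predicted_mechanism}")
```

prints

```
300 MNVs discovered (300 planted)
CA->TG: n= 23 one-step=  9 repeat= 0 q=0.00 -> Ti at CpG
GA->TT: n= 39 one-step= 39 repeat= 0 q=0.99 -> pol_zeta
GC->AA: n= 44 one-step= 41 repeat= 0 q=0.95 -> pol_zeta
TA->AT: n= 16 one-step= 16 repeat=16 q=0.00 -> repeat
```

Every planted event is recovered.  The CpG pattern CA→TG is fully explained
by the two-SNV null (q ≈ 0) and only a third of its MNVs are one-step,
whereas the polymerase-zeta patterns are almost entirely excess (q ≈ 0.95–1)
with every event one-step, and the TA→AT events sit in repeat tracts — the
three planted mechanisms are read back from the cohort.

The same stages are available from the shell:

```bash
mnv synth --length 60000 --samples 100 --events 300 \
    --mix independent_snv=0.6,pol_zeta=0.3,slippage=0.1 --seed 0 --out-dir run/
mnv scan --vcf run/cohort.vcf --max-dist 10 --out run/mnv.tsv
mnv mechanism --mnv run/mnv.tsv --ref run/ref.fa --n-individuals 100 --out run/stats.tsv
mnv phase-eval --vcf run/trios.vcf --ped run/trios.ped --out run/phase.tsv
mnv density --mnv run/mnv.tsv --bed run/ann.bed --ref run/ref.fa --out run/dens.tsv
```

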