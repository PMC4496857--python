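# Methods

## The prioritization model

`panelprio` operationalizes the diagnostic triage used in gene-panel testing
of Mendelian retinal dystrophy. The unit of analysis is a *case unit*: a
family (pedigree with ≥ 2 members, ≥ 1 affected) or a simplex patient
(single affected individual, no informative relatives). Inputs are decomposed
single-alt variant records with per-sample genotypes
(`hom_ref/het/hom_alt/hemi/missing`), an annotation table keyed by normalized
variant (chrom, pos, ref, alt), a known-pathogenic variant table, and a panel
definition with per-gene inheritance capability (AD, AR, XL, digenic).
Coordinates are 1-based VCF convention throughout; multi-allelic sites are
decomposed and indels reduced to minimal representation before keying, so
annotation joins are exact.

### Filter cascade

Three total-function stages; a variant survives only by passing all three.

| parameter | default | meaning |
|---|---|---|
| `max_af` | 0.01 | rarity bound applied to **each reported** population frequency |
| `min_qual` | 20 | site-quality floor (`qual >= 20` passes; missing quality fails) |
| `splice_window` | 2 bp | canonical splice-site window around exon boundaries |

Absent frequencies carry no veto — a variant reported in none of the three
databases is treated as novel and passes. The rarity bound is applied
per-database, to the annotated alternate-allele frequency (not a folded
minor-allele frequency): candidates of interest are rare alternate alleles,
and folding would require allele-number data the annotation rows do not
carry. The quality boundary keeps `qual == 20` (the exclusion rule is
"below 20"), configurable.

### Inheritance engine

Model inference reads the affection pattern classically:

* **AD** — affected individuals in every generation (generation = founder
  depth; married-in founders sit at depth 0, so a skipped generation breaks
  dominance);
* **XL** — at least one affected male and no affected-father→affected-son
  transmission; under the default *variable* female-penetrance policy,
  heterozygous females may be affected or unaffected (X-linked families with
  manifesting carriers look dominant — both models are returned, dominant
  first, and the panel's per-gene modes disambiguate downstream);
* **AR** — an affected individual whose two in-pedigree parents are both
  unaffected.

Several rules can hold at once; inference returns all compatible models in
fixed precedence (AD, XL, AR) and the prioritizer iterates. Pedigrees with a
single member or < 2 generations constrain nothing and fall back to the
simplex path.

Cosegregation checks genotype/affection compatibility per genotyped member;
members without genotypes are skipped and listed as untested, which makes
the test monotone in missing data (masking a member can never turn a
consistent candidate inconsistent). For recessive pairs, affected members
must carry both alleles and unaffected members must not. Autosomal models
assume complete penetrance by default; a penetrance-exception budget
(`penetrance_exceptions`, default 0) can tolerate a configured number of
violations.

Compound-heterozygote detection pairs distinct heterozygous survivors in one
AR-capable gene. With parental genotypes the phase is resolved by
enumerating parental-origin assignments consistent with carrier status:
all-trans → `resolved_trans`, all-cis → `resolved_cis` (rejected),
mixed or parentless → `assumed_trans`. Simplex pairs can never be phased and
are flagged accordingly.

### Classification

Class I requires a known-table match by gene + HGVS (c. or p.) or by dbSNP
id. Class II covers truncating consequences and ensemble-supported missense.
The ensemble counts votes: PolyPhen-2 ∈ {probably, possibly damaging}, SIFT
damaging, MutPred strictly > 0.5 (a score of exactly 0.5 is not a vote);
missing predictors contribute nothing, so truncating variants — which have
no missense scores — never error. Canonical ±2 bp splice variants are
treated as truncating-equivalents and hence Class II-eligible
(`splice_class2`, on by default): a null allele via lost splicing is
mechanistically equivalent to a stopgain for these genes. Classes attach per
allele; a call's class is the best (lowest) member class, and recessive
pairs keep both member classes for reporting.

### Prioritization and summary

Familial: for each inferred model in precedence order, candidates in genes
supporting that model are classified and cosegregation-tested; the first
model yielding a consistent Class I/II call wins, multiple calls under that
model are ranked (best class, then truncating over missense, then lower
maximum frequency, then gene name) with the top call flagged primary.
Simplex: the genotypes, not the pedigree, suggest the model — qualifying
heterozygote in a dominant-capable gene, homozygote or in-trans pair in a
recessive gene, hemizygote in an X-linked gene; all paths are evaluated and
a single-allele call subsumed by a recessive pair in the same gene is
dropped in the pair's favour. A qualifying single allele in a recessive-only
gene without a qualifying counter-allele is demoted to a carrier finding.
Every cascade survivor ends in exactly one of call / carrier / discard-trace
(conservation, tested).

Summary rates are percentages truncated (not rounded) at one decimal —
7/16 prints as 43.7 — matching the reporting convention of diagnostic-yield
tables. The novel fraction is computed over globally distinct candidate
variant keys across all calls (an allele shared by two unrelated patients
counts once). Per-gene shares divide solved units containing the gene by
solved units, overall and stratified by the primary call's model.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
sequencing reads:

* **Pedigrees** — 3–4 generations, truncated-Poisson sibships (mean 2.5),
  married-in spouses never carry the planted allele. One carrier per
  generation is forced, so a dominant plant is affected in every generation,
  a recessive plant produces an affected biallelic child of unaffected
  carrier parents, and an X-linked plant can never show male-to-male
  transmission. Heterozygous females under XL are affected with probability
  `female_penetrance` (default 0.5; the manifesting-carrier phenomenon).
* **Planted causals** — `known` (registered in the run's known-table copy →
  Class I), `novel_truncating` (→ Class II), `novel_missense` (≥ 2 damaging
  votes with probability `predictor_fidelity`, default 1.0). Recessive units
  receive two alleles placed in trans by construction.
* **Background** — `background_rate` (default 30) variant sites per unit
  across panel genes; allele frequencies from a mixture (80 % common
  U(0.05, 0.5), 20 % rare U(0, 0.009)); founder genotypes Hardy–Weinberg at
  the site frequency, descendants by Mendelian drop (so every configuration
  is transmission-reachable, which is tested by enumeration). Site qualities
  are drawn from a surrogate scale N(146.2, 26.2) truncated at 0 — the
  panel's reported mean read depth reused as a plausible QUAL scale, since
  no site-quality distribution is available — with a `low_qual_fraction`
  (default 0.05) of sites given sub-threshold qualities so the quality
  filter is exercised. Rare on-panel background is never truncating and its
  predictor profile is capped below the ensemble quorum: an unsolved case is
  *defined* by the absence of a qualifying allele, and this constraint is
  what makes frozen fixtures reproduce solved/unsolved tallies
  deterministically. Consequently the generator understates two features of
  real data: rare benign truncating polymorphisms and predictor false
  positives — passing tests therefore demonstrate pipeline correctness on
  cohorts where class labels are clean, not classifier robustness to noisy
  predictors (that axis is exercised separately via `predictor_fidelity`).
* **Negatives** — made negative by mechanism (off-panel causal gene, or an
  intronic allele removed at the functional stage), never by deleting the
  causal variant, so negative units still carry realistic background.

Identical `SimulationConfig` (including seed) gives byte-identical
materialized cohorts.

## Packaged fixture cohort

`load_fixture_cohort("full_cohort")` assembles 18 familial + 16 simplex
units. Seventeen units carry the curated candidate variants shipped as
package data (gene, exon, HGVS, consequence, reference status, and the one
recorded in-house frequency are verbatim from the source report tables);
the other 8 + 9 units carry background only, with family shapes keeping the
cohort's 10 dominant / 5 recessive / 3 X-linked mix. Pedigree structures
are minimal reconstructions consistent with each family's described
affection pattern (the original drawings are not machine-readable), and
genomic coordinates are synthetic — each gene owns a 1-Mb block on its
cytoband's chromosome and a variant sits at block start + HGVS coding
offset, with invented anchor bases for indels. Predictor outputs for the
curated missense candidates are synthesized to be consistent with their
recorded classes (the numeric scores were not published) and are documented
as such. Background is regenerated on every load from a recorded seed
rather than committed as files, keeping the package text-only and small;
load determinism is tested byte-for-byte.

Coverage and capture metrics (read depth, 1X/10X breadth, target size)
require raw reads and are out of scope; the depth figure appears only as
the simulator's surrogate quality scale above.

## Problem sizes and numerical choices

The default test run uses small cohorts (1–4 families per simulated cohort,
background rate 8–20; 200 seeds for the recovery property), which the
pipeline's pure-Python hot path handles in seconds while still covering all
three models and both causal-allele shapes. Ties in call ranking break
lexicographically by gene for determinism. Report writers sort by (unit,
gene, position) and emit `repr`-round-trippable floats so write→read is
identity and re-runs are byte-identical. Degenerate inputs fail loudly:
empty pedigrees, dangling parents, ancestry cycles, duplicate annotation
keys, frequencies outside [0, 1], hemizygous genotypes under autosomal
models, and recessive cosegregation without a pair are all contract errors,
not silent drops.

## Known limitations

* Digenic inheritance (the PRPH2/ROM1 pair on the panel) is represented in
  the panel table but never tested for; no joint two-gene model exists.
* Linkage/LOD computation, population-panel haplotype phasing, de novo and
  mitochondrial models, CNV and UTR analysis are out of scope.
* The known-variant table matches by exact HGVS string or rsid; no HGVS
  normalization (e.g., p.Ser187fs vs p.S187Tfs*31) is attempted.
* Simplex "inheritance" labels describe what the genotypes suggest, not a
  pedigree inference, and a simplex compound het can never be proven in
  trans without parental data.
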