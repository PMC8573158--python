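# Methods

## Scope and data flow

`couplescreen` operates downstream of sequencing, alignment and variant
calling: its inputs are per-partner genotype calls (VCF 4.x), a gene-panel
table in the Clinical-Genomic-Database dialect
(`GENE/CONDITION/OMIM/INHERITANCE/LOF_MECHANISM`), a ClinVar-like
classification table, and optional allele-frequency tables. Annotation
(gene symbol, HGVS c./p.) is expected on the VCF `INFO` fields
(`GENE`/`HGVSC`/`HGVSP`, names configurable); the package deliberately does
not run an annotation engine. Classification lookups try the genomic key
`(chrom, pos, ref, alt)` first and fall back to `(gene, hgvs_c)` for table
rows without coordinates.

The per-couple pipeline is: read and decompose both partners' genotypes →
parsimony-normalize → intersect on the genomic key → attach the maximum
allele frequency over all sources → classify the HGVS consequence → look
up the clinical assertion → apply the triage tree → report retained
variants plus a full audit trail.

## Variant representation

Multi-allelic records are decomposed to one alternate allele each;
zygosity is computed per allele from the GT field only (phase ignored,
half-calls such as `./1` count as heterozygous because the alternate
allele was observed). Parsimony trimming removes shared trailing bases
first, then shared leading bases, always keeping at least one base per
allele; this is idempotent and sufficient to match calls produced by a
single caller. Full left-alignment through repetitive sequence is
performed only when local reference context is supplied, since it cannot
be done correctly without one; by default no cross-flank shifting is
attempted.

**Carrier definition.** Any genotype with ≥1 alternate allele counts as a
carrier. Screening narratives usually speak of shared *heterozygosity*,
but a homozygous-alternate partner transmits the allele with certainty, so
excluding such sites would understate risk; they are retained and flagged
(`has_hom_alt`) so reports can present them separately.

## Consequence classification

`classify_consequence` applies ordered rules to the HGVS pair: protein
`fs` → frameshift; protein substitution to a stop (`*`/`Ter`) → nonsense;
intronic offset of magnitude 1–2 in the coding description → canonical
splice; c.-level del/dup/ins with affected length divisible by 3 →
in-frame indel (a non-multiple-of-3 length with *no* protein description
is called frameshift from the nucleotide arithmetic); single amino-acid
substitution → missense; anything else → `other`. Truncating ≡
{frameshift, nonsense, canonical splice}. The protein-level call wins when
coding- and protein-level notations disagree (e.g. a single-base
duplication annotated as a direct stop gain is classed nonsense — still
truncating, so triage is unaffected). A 4-nt deletion annotated with a
delins protein change matches no rule and falls to `other`
(non-truncating); such a variant is retained only through a clinical
assertion, which is how the one such row of the reference cohort flows
through. Unparseable strings never raise — they classify as `other` with a
logged warning, because a parsing artifact must not crash a screening run.

## Triage

Ordered rules, first match wins:

1. `max_af ≥ 0.01` → exclude (`common_variant`). The comparison is strict
   (`< 0.01` is rare) and a variant absent from every population source is
   treated as rare — absence from large population databases is itself
   evidence of rarity.
2. gene not in the AR panel → exclude (`not_ar_gene`). The panel filter
   keeps any gene whose inheritance tokens include `AR` (so `AD,AR` genes
   stay); X-linked entries are not retained.
3. pathogenic / likely pathogenic / combined P-LP assertion → include
   (`clinvar_plp`), whatever the consequence class. `Conflicting
   interpretations` and unrecognized significance strings do **not** count
   (mapped to VUS): the protocol is deliberately conservative because a
   false-positive result burdens a couple with an unnecessary
   intervention. Review status is recorded but not used as a filter.
4. truncating consequence and panel `LOF_MECHANISM = yes` → include
   (`lof_rule`).
5. otherwise exclude (`insufficient_evidence`).

Compound heterozygosity (different variants of the same gene in the two
partners) is not reported; the screen targets homozygosity-by-descent risk
from a single shared allele. This is a documented possible extension.

## Pedigree math and the risk model

Kinship is computed by the standard recursion (founders unrelated,
φ(a,a) = ½(1+φ(father,mother)), recursion through the later-generation
member), with cycle detection; CGR = 2 × kinship, assuming the partners
themselves are non-inbred. The six supported relationship labels are
backed by canonical pedigrees, so their CGRs (0.25, 0.25, 0.125, 0.125,
0.0625, 0.03125) are *derived*, not tabulated. Pedigree labels taken from
family history are estimates; a wrong or incomplete pedigree shifts the
CGR and hence every derived quantity.

The at-risk-couple model treats each of a couple's PLP carrier variants as
shared through common ancestry independently with probability CGR:
`ARC = 1 − (1 − CGR)^PLP`, inverted as `PLP = ln(1−ARC)/ln(1−CGR)`. PLP is
real-valued (it is a cohort mean); no rounding to integers. Independence
would fail for variants in linkage, which is ignored (exome-wide carrier
variants are overwhelmingly unlinked). The gene-dropping simulator
justifies the per-variant sharing probability mechanistically: founders
receive unique alleles, alleles segregate Mendelianly through the
canonical pedigree, one founder allele is designated uniformly at random
as the tracked rare variant, and conditional on partner 1 carrying it the
frequency with which partner 2 carries it converges to CGR. The uniform
prior over founder alleles matters: it encodes that a rare variant is a
priori equally likely to have entered through any founder chromosome.

Cohort summaries report positive fractions with exact Clopper–Pearson
binomial intervals (conservative by construction; a reporting aid, since
observed rates at n ≈ 25–40 carry substantial sampling noise), counts of
couples with ≥2 shared PLPs, the truncating fraction among retained
variants, and the formula-inverted PLP estimate per CGR and per
relationship stratum. A stratum in which every couple is positive has a
divergent PLP point estimate, reported as infinite (JSON `null`).

## Synthetic data

The couple generator plants variants with designed truth labels on a toy
chromosome (sequential positions, substitution alleles; no attempt at
realistic human coordinates or sequence context, which the screening logic
never inspects). Shared PLP plants alternate between the two inclusion
routes: a rare asserted missense (AF 0.0005 in the companion frequency
table) and an unlisted truncating variant in a loss-of-function gene
(absent from both tables, i.e. AF missing). Each decoy class violates
exactly one rule: a rare asserted-benign missense, a pathogenic variant
carried by one partner only, a pathogenic variant at AF 0.05, and a
truncating variant in an off-panel gene. Output is byte-for-byte
reproducible for a given seed; all generators take explicit seeds and no
global random state is touched.

What passing these tests shows — and does not. The synthetic couples
exercise decomposition, normalization, intersection, annotation lookups
and the decision tree exactly, but they do not emulate sequencing error,
missed calls at low coverage, annotation disagreement between transcript
choices, or structural/repeat variation invisible to exome data; a clean
pass here is a statement about the pipeline's logic, not about assay
sensitivity.

The cohort simulator draws each couple's shared-PLP count from
Binomial(pool, CGR) — the model's own sharing assumption — screens every
couple through the real pipeline, and lets the summary invert the formula;
over 200 seeds of 40-couple cohorts the recovered pool size is centred on
the planted value of 2 (observed median ≈ 1.9: the inversion is convex in
the observed fraction, so the median sits slightly below the mean).

## Numerical and design choices

* Problem sizes: Monte-Carlo checks use 2×10⁵ gene-drop replicates
  (standard error ≈ 0.0015 at CGR 0.125, giving 3-SE bands well inside a
  0.01 absolute tolerance), 10⁵ couples for ARC convergence, and 200-seed
  by 40-couple grids for parameter recovery — sizes at which each check
  resolves its target without waste.
* Allele-frequency threshold: default 0.01, configurable in (0, 1];
  lowering it can only shrink the retained set (tested monotonicity).
* Chromosome names are compared verbatim after stripping an optional
  `chr` prefix (configurable off).
* Duplicate panel genes keep the first row; duplicate classification keys
  keep the most pathogenic assertion; duplicate variant keys within one
  partner keep the first call — each with a warning.
* HGVS strings in the reference cohort are stored with internal spaces
  removed relative to typeset sources (`c.1456C>T`).
* The reference cohort's classification fixture asserts exactly the
  non-truncating retained variants as pathogenic, mirroring the protocol's
  requirement that such variants be externally asserted; truncating
  variants are left unlisted and must flow through the loss-of-function
  rule. The cohort table does not record X-linked screening; the panel
  filter retains autosomal-recessive (including AD/AR) genes only.

## Known limitations

Single shared variants only (no compound heterozygosity, no digenic
pairs); no CNV/repeat-expansion awareness; triage is only as good as the
supplied classification table and panel flags; the independence assumption
of the ARC formula ignores linkage; relationship labels outside the six
supported ones require an explicit pedigree or CGR.
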