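# couplescreen

Preconceptional carrier screening for consanguineous couples from exome
data: find the variants both partners carry, keep only those that could
cause an autosomal-recessive (AR) disease in a homozygous child, and turn
the counts into a quantitative risk statement.

## Who this is for

Clinical genetics groups counselling related couples (uncle–niece through
second cousins). The excess reproductive risk of such couples is almost
entirely the risk of AR disease through alleles inherited from a shared
ancestor, so the only question that matters is: *do the two partners carry
the same pathogenic variant in the same AR gene?* `couplescreen` answers it
from a pair of annotated VCFs, an AR gene-panel table, and a ClinVar-style
classification table — no live database access, no incidental findings
outside the panel.

## The model

* **Shared-carrier detection.** Genotypes are decomposed to one alternate
  allele per record, parsimony-trimmed, and intersected on
  `(chrom, pos, ref, alt)`; a site is shared when both partners carry at
  least one alternate allele (homozygous carriers are flagged).
* **Conservative triage.** A shared variant is retained as pathogenic or
  likely pathogenic (PLP) only if it is rare (allele frequency < 0.01 in
  every population source; unknown frequency counts as rare), lies in a
  panel gene with AR inheritance, and either (a) carries a
  pathogenic/likely-pathogenic clinical assertion — required for missense
  and in-frame indels — or (b) is truncating (frameshift, nonsense,
  canonical ±1/±2 splice) in a gene where loss of function is a known
  disease mechanism.
* **Risk.** With CGR the coefficient of genetic relationship of the couple
  (twice the kinship coefficient: 0.125 for first cousins, computed here by
  pedigree recursion) and PLP the number of shared pathogenic carrier
  variants, the probability that a couple is *at risk* is

  ```
  ARC = 1 − (1 − CGR)^PLP        ⇔        PLP = ln(1 − ARC) / ln(1 − CGR)
  ```

  assuming each variant is shared through common ancestry independently
  with probability CGR — an assumption the package itself validates by
  Mendelian gene-dropping simulation on the canonical pedigrees.

## Worked example

Generate a synthetic couple with two planted shared PLP variants and one
decoy per failure class, screen it, and inspect the result:

```sh
couplescreen simulate couple --n-shared 2 --n-decoys 1 --seed 7 --out-dir demo
couplescreen screen --vcf demo/couple1.vcf \
    --partner1-sample P1 --partner2-sample P2 \
    --panel panel.tsv --clinvar demo/couple1.classification.tsv \
    --af demo/couple1.frequency.tsv --relationship first_cousins \
    --out report.tsv --audit audit.tsv
# couple1  PLP=2  positive=yes
```

The audit trail shows each of the five shared variants with its verdict:
the asserted missense (`clinvar_plp`) and the unlisted nonsense in a
loss-of-function gene (`lof_rule`) are retained; the benign missense
(`insufficient_evidence`), the 5%-frequency variant (`common_variant`) and
the off-panel variant (`not_ar_gene`) are excluded.

Risk arithmetic for a first-cousin stratum in which 52% of couples share
at least one PLP variant:

```
$ couplescreen risk --cgr 0.125 --arc 0.52
CGR=0.125 ARC=0.52 -> PLP=5.50
```

The built-in reference cohort of 39 consanguineous couples reproduces its
published outcome end to end through the same triage code:

```
$ couplescreen summarize --fixture
couples: 39  positive: 21 (53.8%)  95% CI [37.2%, 69.9%]
couples with >=2 shared PLPs: 8
truncating among retained variants: 17/30 (57%)
  CGR 0.25: 2/2 positive (100.0%), implied PLP inf
  CGR 0.125: 13/26 positive (50.0%), implied PLP 5.19
  CGR 0.0625: 2/3 positive (66.7%), implied PLP 17.02
  CGR 0.03125: 4/8 positive (50.0%), implied PLP 21.83
  ...
  first_cousins: 13/25 positive (52.0%), implied PLP 5.50
```

Here 21/39 couples (53.8%) share at least one PLP variant; among the 25
first-cousin couples 13 (52%) do, which the inverted formula converts into
an implied mean of 5.5 shared PLP carrier variants per couple. (Implied
PLP is reported as `inf` for a stratum in which every couple is positive:
the point estimate diverges; the confidence interval remains informative.)

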