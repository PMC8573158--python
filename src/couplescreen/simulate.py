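"""Synthetic data generation and Monte-Carlo validation of the risk model.

Two kinds of simulation live here:

* **Couple generators** plant variants with known truth labels (shared
  pathogenic, shared benign, common, off-panel, unshared) and emit either
  in-memory couple variant sets or a two-sample VCF plus matching
  classification and frequency tables, so the whole screening pipeline can
  be validated against a designed truth table.

* **Gene dropping** transmits founder alleles through canonical pedigrees
  by Mendelian segregation and measures the probability that the second
  partner carries an allele carried by the first.  This probability equals
  the coefficient of genetic relationship, which is the mechanistic basis
  of the at-risk-couple formula ``ARC = 1 - (1 - CGR)^PLP`` (one
  independent sharing trial per carrier variant).

All generators take explicit seeds; none touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .annotation_panel import ClassificationTable, FrequencyTable, GenePanelEntry
from .errors import CoupleScreenError
from .risk import Pedigree, canonical_pedigree, cgr_from_relationship
from .triage import (
    CLINVAR_PLP,
    COMMON_VARIANT,
    EXCLUDE,
    INCLUDE_PLP,
    INSUFFICIENT_EVIDENCE,
    LOF_RULE,
    NOT_AR_GENE,
    CoupleScreenResult,
    screen_couple,
)
from .vcf_couple import (
    HET,
    REF,
    CoupleVariantSet,
    GenotypeCall,
    SharedVariant,
    Variant,
)

# truth-table categories
SHARED_PLP = "shared_plp"
SHARED_BENIGN = "shared_benign"
UNSHARED_PLP = "unshared_plp"
COMMON = "common"
OFF_PANEL = "off_panel"
DECOY_CATEGORIES = (SHARED_BENIGN, UNSHARED_PLP, COMMON, OFF_PANEL)

_RARE_AF = 0.0005   # planted "rare" frequency, well under the 0.01 threshold
_COMMON_AF = 0.05   # planted "common" frequency, above the threshold


@dataclass(frozen=True)
class Plant:
    """One planted variant with its designed truth."""

    category: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    clnsig: str            # "" when absent from the classification table
    af: Optional[float]    # None when absent from every frequency source
    zygosity1: str
    zygosity2: str
    expected_decision: Optional[str]   # None when never reaching triage
    expected_reason: Optional[str]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_shared(self) -> bool:
        return self.zygosity1 == HET and self.zygosity2 == HET


@dataclass
class TruthTable:
    """The designed truth for one synthetic couple."""

    plants: list

    def __post_init__(self) -> None:
        keys = [p.key for p in self.plants]
        if len(keys) != len(set(keys)):
            raise CoupleScreenError("truth table contains duplicate variant keys")

    def expected_shared_keys(self) -> set:
        return {p.key for p in self.plants if p.is_shared}

    def expected_included_keys(self) -> set:
        return {p.key for p in self.plants if p.expected_decision == INCLUDE_PLP}

    def expected_reasons(self) -> dict:
        """reason per shared variant key (includes the accepted ones)."""
        return {
            p.key: p.expected_reason for p in self.plants if p.is_shared
        }


def _pick_genes(panel: dict, n_needed: int, rng: np.random.Generator) -> list[str]:
    lof_genes = sorted(g for g, e in panel.items() if e.lof_mechanism == "yes")
    if n_needed > len(lof_genes):
        raise CoupleScreenError(
            f"requested {n_needed} planted variants but the panel has only "
            f"{len(lof_genes)} loss-of-function genes"
        )
    picked = rng.choice(len(lof_genes), size=n_needed, replace=False)
    return [lof_genes[i] for i in picked]


def plan_couple(
    n_shared_plp: int,
    n_decoys_per_class: int,
    panel: dict,
    rng: np.random.Generator,
) -> list:
    """Design the planted variants for one synthetic couple.

    Shared pathogenic plants alternate between the two inclusion routes:
    a clinically asserted (ClinVar-like) rare missense, and an unlisted
    truncating variant in a gene with a known loss-of-function mechanism.
    Each decoy class violates exactly one triage rule.
    """
    if n_shared_plp < 0 or n_decoys_per_class < 0:
        raise CoupleScreenError("plant counts must be non-negative")
    n_in_panel = n_shared_plp + 3 * n_decoys_per_class  # benign, unshared, common
    genes = _pick_genes(panel, n_in_panel, rng)
    plants: list[Plant] = []
    pos = 10_000

    def add(category, gene, hgvs_c, hgvs_p, clnsig, af, zyg2,
            expected_decision, expected_reason) -> None:
        nonlocal pos
        ref, alt = hgvs_c[-3], hgvs_c[-1]  # plants are substitutions "c.NX>Y"
        plants.append(
            Plant(
                category=category, chrom="1", pos=pos, ref=ref, alt=alt,
                gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, clnsig=clnsig,
                af=af, zygosity1=HET, zygosity2=zyg2,
                expected_decision=expected_decision,
                expected_reason=expected_reason,
            )
        )
        pos += 1_000

    gene_iter = iter(genes)
    for i in range(n_shared_plp):
        gene = next(gene_iter)
        n = 300 + 3 * i
        if i % 2 == 0:  # clinically asserted rare missense
            add(SHARED_PLP, gene, f"c.{n}A>G", f"p.(Lys{n // 3}Glu)",
                "Pathogenic", _RARE_AF, HET, INCLUDE_PLP, CLINVAR_PLP)
        else:           # unlisted truncating variant, LoF-mechanism gene
            add(SHARED_PLP, gene, f"c.{n}C>T", f"p.(Arg{n // 3}*)",
                "", None, HET, INCLUDE_PLP, LOF_RULE)
    for i in range(n_decoys_per_class):
        n = 600 + 3 * i
        add(SHARED_BENIGN, next(gene_iter), f"c.{n}A>G", f"p.(Ile{n // 3}Val)",
            "Benign", _RARE_AF, HET, EXCLUDE, INSUFFICIENT_EVIDENCE)
    for i in range(n_decoys_per_class):
        n = 700 + 3 * i
        add(UNSHARED_PLP, next(gene_iter), f"c.{n}A>G", f"p.(Gly{n // 3}Asp)",
            "Pathogenic", _RARE_AF, REF, None, None)
    for i in range(n_decoys_per_class):
        n = 800 + 3 * i
        add(COMMON, next(gene_iter), f"c.{n}A>G", f"p.(Thr{n // 3}Met)",
            "Pathogenic", _COMMON_AF, HET, EXCLUDE, COMMON_VARIANT)
    for i in range(n_decoys_per_class):
        n = 900 + 3 * i
        add(OFF_PANEL, f"OFFPANEL{i + 1}", f"c.{n}C>T", f"p.(Gln{n // 3}*)",
            "", None, HET, EXCLUDE, NOT_AR_GENE)
    return plants


def build_couple_tables(
    plants: Sequence[Plant],
) -> tuple[ClassificationTable, FrequencyTable]:
    """In-memory classification and frequency tables matching the plants."""
    classification = ClassificationTable()
    frequency = FrequencyTable()
    for p in plants:
        if p.clnsig:
            classification.add_record(
                chrom=p.chrom, pos=p.pos, ref=p.ref, alt=p.alt,
                gene=p.gene, hgvs_c=p.hgvs_c, clnsig=p.clnsig,
                review_status="criteria provided",
            )
        if p.af is not None:
            frequency.add_record(p.chrom, p.pos, p.ref, p.alt, p.af, p.af / 2)
    return classification, frequency


def build_couple_set(plants: Sequence[Plant], couple_id: str) -> CoupleVariantSet:
    """The couple's shared-carrier variant set implied by the plants."""
    shared = []
    for p in plants:
        if not p.is_shared:
            continue
        shared.append(
            SharedVariant(
                variant=Variant(
                    chrom=p.chrom, pos=p.pos, ref=p.ref, alt=p.alt,
                    gene=p.gene, hgvs_c=p.hgvs_c, hgvs_p=p.hgvs_p,
                ),
                partner1=GenotypeCall("P1", p.zygosity1),
                partner2=GenotypeCall("P2", p.zygosity2),
            )
        )
    return CoupleVariantSet(couple_id=couple_id, shared=shared)


# --- file emission -------------------------------------------------------------

_GT = {REF: "0/0", HET: "0/1", "hom_alt": "1/1", "missing": "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=couplescreen-simulate
##contig=<ID=1,length=249250621>
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=HGVSC,Number=A,Type=String,Description="HGVS coding description">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="HGVS protein description">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2
"""


@dataclass
class GeneratedCouple:
    """Paths of a generated synthetic couple plus its truth table."""

    vcf: Path
    classification: Path
    frequency: Path
    truth: TruthTable


def generate_couple_vcf(
    n_shared_plp: int,
    n_decoys_per_class: int,
    panel: dict,
    seed: int,
    out_dir: Union[str, Path],
    couple_id: str = "couple1",
) -> GeneratedCouple:
    """Write a two-sample VCF plus annotation tables with a known truth.

    Output is byte-for-byte reproducible for a given seed.  The VCF carries
    gene and HGVS annotations in INFO fields; allele frequencies live only
    in the companion frequency TSV so that the table-lookup path is
    exercised end to end.
    """
    rng = np.random.default_rng(seed)
    plants = plan_couple(n_shared_plp, n_decoys_per_class, panel, rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vcf_path = out_dir / f"{couple_id}.vcf"
    lines = [_VCF_HEADER]
    for p in plants:
        info = f"GENE={p.gene}"
        if p.hgvs_c:
            info += f";HGVSC={p.hgvs_c}"
        if p.hgvs_p:
            info += f";HGVSP={p.hgvs_p}"
        lines.append(
            f"{p.chrom}\t{p.pos}\t.\t{p.ref}\t{p.alt}\t.\tPASS\t{info}\tGT\t"
            f"{_GT[p.zygosity1]}\t{_GT[p.zygosity2]}\n"
        )
    vcf_path.write_text("".join(lines))

    clf_path = out_dir / f"{couple_id}.classification.tsv"
    rows = ["CHROM\tPOS\tREF\tALT\tGENE\tHGVS_C\tCLNSIG\tREVIEW_STATUS\n"]
    for p in plants:
        if p.clnsig:
            rows.append(
                f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}\t{p.gene}\t{p.hgvs_c}\t"
                f"{p.clnsig}\tcriteria provided\n"
            )
    clf_path.write_text("".join(rows))

    freq_path = out_dir / f"{couple_id}.frequency.tsv"
    rows = ["CHROM\tPOS\tREF\tALT\tAF_GNOMAD\tAF_1KG\n"]
    for p in plants:
        if p.af is not None:
            rows.append(
                f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}\t{p.af:.6g}\t{p.af / 2:.6g}\n"
            )
    freq_path.write_text("".join(rows))

    return GeneratedCouple(
        vcf=vcf_path,
        classification=clf_path,
        frequency=freq_path,
        truth=TruthTable(plants=list(plants)),
    )


# --- gene dropping --------------------------------------------------------------


@dataclass(frozen=True)
class GeneDropConfig:
    """Configuration of a gene-dropping run."""

    relationship: str
    n_replicates: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise CoupleScreenError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GeneDropResult:
    """Monte-Carlo estimate of the partner allele-sharing probability."""

    estimate: float
    se: float
    n_conditioned: int
    n_replicates: int


def gene_drop_sharing(
    config_or_relationship: Union[GeneDropConfig, str, Pedigree],
    n_replicates: int = 200_000,
    seed: int = 0,
) -> GeneDropResult:
    """Estimate P(partner2 carries an allele | partner1 carries it).

    Each replicate assigns every founder two globally unique alleles, drops
    them through the pedigree by Mendelian segregation, and designates one
    founder allele uniformly at random as the tracked (rare) variant.
    Replicates in which partner1 carries the tracked allele form the
    conditioning set; the returned estimate is the fraction of those in
    which partner2 carries it too.  For a correct pedigree this converges
    to the coefficient of genetic relationship.
    """
    if isinstance(config_or_relationship, GeneDropConfig):
        cfg = config_or_relationship
        pedigree = canonical_pedigree(cfg.relationship)
        n_replicates, seed = cfg.n_replicates, cfg.seed
    elif isinstance(config_or_relationship, Pedigree):
        pedigree = config_or_relationship
    else:
        pedigree = canonical_pedigree(config_or_relationship)

    rng = np.random.default_rng(seed)
    n = int(n_replicates)
    founders = pedigree.founders()
    genotypes: dict = {}
    for i, founder in enumerate(founders):
        genotypes[founder] = np.stack(
            [np.full(n, 2 * i, dtype=np.int64), np.full(n, 2 * i + 1, dtype=np.int64)],
            axis=1,
        )
    rows = np.arange(n)
    for pid in pedigree.topological_order():
        father, mother = pedigree.parents_of(pid)
        if father is None and mother is None:
            continue
        if father is None or mother is None:
            raise CoupleScreenError(
                f"individual {pid!r} has exactly one known parent; gene dropping "
                "needs both parents or none"
            )
        paternal = genotypes[father][rows, rng.integers(0, 2, n)]
        maternal = genotypes[mother][rows, rng.integers(0, 2, n)]
        genotypes[pid] = np.stack([paternal, maternal], axis=1)

    designated = rng.integers(0, 2 * len(founders), n)
    p1, p2 = pedigree.partner_pair
    carries1 = np.any(genotypes[p1] == designated[:, None], axis=1)
    carries2 = np.any(genotypes[p2] == designated[:, None], axis=1)
    n_conditioned = int(carries1.sum())
    if n_conditioned == 0:
        raise CoupleScreenError(
            "no replicate had partner1 carrying the designated allele; "
            "increase n_replicates"
        )
    estimate = float((carries1 & carries2).sum() / n_conditioned)
    se = float(np.sqrt(estimate * (1.0 - estimate) / n_conditioned))
    return GeneDropResult(
        estimate=estimate, se=se,
        n_conditioned=n_conditioned, n_replicates=n,
    )


def simulate_arc(cgr: float, plp: int, n_couples: int, seed: int = 0) -> float:
    """Observed at-risk fraction under independent per-variant sharing.

    Each couple undergoes ``plp`` independent Bernoulli(CGR) sharing trials
    and is at risk when at least one succeeds.  Converges to
    ``arc_from_plp(cgr, plp)`` as the number of couples grows.
    """
    if not 0.0 < cgr < 1.0:
        raise CoupleScreenError(f"CGR must lie in (0, 1), got {cgr}")
    if plp < 0 or int(plp) != plp:
        raise CoupleScreenError("plp must be a non-negative integer for simulation")
    if n_couples < 1:
        raise CoupleScreenError("n_couples must be >= 1")
    if plp == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    shared = rng.random((int(n_couples), int(plp))) < cgr
    return float(shared.any(axis=1).mean())


# --- end-to-end cohort simulation ----------------------------------------------


def simulate_screened_cohort(
    n_couples: int,
    relationship: str,
    plp_pool: int,
    panel: dict,
    seed: int = 0,
    n_decoys_per_class: int = 1,
) -> list:
    """Simulate a cohort and screen it with the real pipeline.

    Each couple draws its number of shared pathogenic variants from
    Binomial(``plp_pool``, CGR) — every variant in the couple's joint pool
    is shared independently with probability equal to the coefficient of
    genetic relationship — plants them (plus one decoy of each class) and
    runs the standard screening.  Returns one
    :class:`~couplescreen.triage.CoupleScreenResult` per couple.
    """
    if n_couples < 1:
        raise CoupleScreenError("n_couples must be >= 1")
    cgr = cgr_from_relationship(relationship)
    rng = np.random.default_rng(seed)
    results: list[CoupleScreenResult] = []
    for i in range(n_couples):
        n_shared = int(rng.binomial(plp_pool, cgr))
        plants = plan_couple(n_shared, n_decoys_per_class, panel, rng)
        couple_set = build_couple_set(plants, couple_id=f"sim{i + 1:03d}")
        classification, frequency = build_couple_tables(plants)
        results.append(
            screen_couple(
                couple_set, panel, classification, frequency,
                cgr=cgr, relationship=relationship,
            )
        )
    return results
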