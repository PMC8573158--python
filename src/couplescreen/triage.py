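"""Conservative pathogenicity triage of shared variants.

Every variant carried by both partners is pushed through a fixed decision
tree.  The tree is deliberately conservative: a non-truncating variant
(missense, in-frame indel) is only accepted when an external clinical
classification already asserts it pathogenic or likely pathogenic, while a
truncating variant (frameshift, nonsense, canonical splice) is additionally
accepted when loss of function is a known disease mechanism for its gene.
Everything else is excluded, with the reason recorded for the audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotation_panel import (
    ClassificationRecord,
    ClassificationTable,
    ConsequenceClass,
    FrequencyTable,
    GenePanelEntry,
    PLP_SIGNIFICANCES,
    attach_frequency,
    classify_consequence,
)
from .errors import CoupleScreenError
from .vcf_couple import CoupleVariantSet, GenotypeCall, Variant

logger = logging.getLogger(__name__)

INCLUDE_PLP = "include_plp"
EXCLUDE = "exclude"

CLINVAR_PLP = "clinvar_plp"
LOF_RULE = "lof_rule"
COMMON_VARIANT = "common_variant"
NOT_AR_GENE = "not_ar_gene"
INSUFFICIENT_EVIDENCE = "insufficient_evidence"
INCLUDE_REASONS = frozenset({CLINVAR_PLP, LOF_RULE})
EXCLUDE_REASONS = frozenset({COMMON_VARIANT, NOT_AR_GENE, INSUFFICIENT_EVIDENCE})

DEFAULT_AF_THRESHOLD = 0.01


@dataclass(frozen=True)
class TriageVerdict:
    """Outcome of the decision tree for a single shared variant."""

    decision: str
    reason: str
    classification: ConsequenceClass
    significance: str

    def __post_init__(self) -> None:
        if self.decision not in (INCLUDE_PLP, EXCLUDE):
            raise CoupleScreenError(f"unknown decision {self.decision!r}")
        if (self.decision == INCLUDE_PLP) != (self.reason in INCLUDE_REASONS):
            raise CoupleScreenError(
                f"inconsistent verdict: decision={self.decision} reason={self.reason}"
            )

    @property
    def included(self) -> bool:
        return self.decision == INCLUDE_PLP


@dataclass(frozen=True)
class AuditRecord:
    """One shared variant with its verdict and supporting annotations."""

    variant: Variant
    partner1: GenotypeCall
    partner2: GenotypeCall
    verdict: TriageVerdict
    panel_entry: Optional[GenePanelEntry] = None


@dataclass
class CoupleScreenResult:
    """Screening outcome for one couple.

    ``shared_plp`` lists only the variants retained as pathogenic or likely
    pathogenic, sorted by genomic position; the full ``audit`` trail keeps
    every shared variant with its exclusion reason.
    """

    couple_id: str
    cgr: float
    shared_plp: list[AuditRecord] = field(default_factory=list)
    audit: list[AuditRecord] = field(default_factory=list)
    relationship: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cgr < 1.0:
            raise CoupleScreenError(
                f"CGR must lie in (0, 1), got {self.cgr} for couple {self.couple_id}"
            )

    @property
    def n_plp(self) -> int:
        return len(self.shared_plp)

    @property
    def positive(self) -> bool:
        return self.n_plp >= 1


def triage_variant(
    variant: Variant,
    consequence: ConsequenceClass,
    classification: ClassificationRecord,
    panel_entry: Optional[GenePanelEntry],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> TriageVerdict:
    """Apply the screening decision tree to one shared variant.

    Rule order (first match wins):

    1. allele frequency at or above the rarity threshold -> exclude (common);
       the comparison is strict, a variant is rare only when ``af < threshold``,
       and a variant missing from every population database counts as rare
    2. gene not in the autosomal-recessive panel -> exclude
    3. asserted pathogenic / likely pathogenic -> include, whatever the
       molecular consequence
    4. truncating consequence in a gene with a known loss-of-function
       disease mechanism -> include
    5. otherwise -> exclude for insufficient evidence
    """
    if not 0.0 < af_threshold <= 1.0:
        raise CoupleScreenError(
            f"af_threshold must lie in (0, 1], got {af_threshold}"
        )

    def verdict(decision: str, reason: str) -> TriageVerdict:
        return TriageVerdict(
            decision=decision,
            reason=reason,
            classification=consequence,
            significance=classification.significance,
        )

    if variant.max_af is not None and variant.max_af >= af_threshold:
        return verdict(EXCLUDE, COMMON_VARIANT)
    if panel_entry is None:
        return verdict(EXCLUDE, NOT_AR_GENE)
    if classification.significance in PLP_SIGNIFICANCES:
        return verdict(INCLUDE_PLP, CLINVAR_PLP)
    if consequence.truncating and panel_entry.lof_mechanism == "yes":
        return verdict(INCLUDE_PLP, LOF_RULE)
    return verdict(EXCLUDE, INSUFFICIENT_EVIDENCE)


def screen_couple(
    couple_variant_set: CoupleVariantSet,
    panel: dict[str, GenePanelEntry],
    classification_table: ClassificationTable,
    frequency_source: Optional[FrequencyTable],
    cgr: float,
    relationship: Optional[str] = None,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> CoupleScreenResult:
    """Triage every shared variant of a couple and assemble the result.

    Pipeline per variant: attach allele frequency, classify the HGVS
    consequence, look up the clinical classification, then run the decision
    tree.  Variants without any HGVS description are classified ``other``
    (non-truncating), so they can only be retained through a clinical
    assertion.
    """
    audit: list[AuditRecord] = []
    for entry in couple_variant_set:
        variant = attach_frequency(entry.variant, frequency_source)
        if variant.hgvs_c or variant.hgvs_p:
            consequence = classify_consequence(variant.hgvs_c, variant.hgvs_p)
        else:
            logger.debug("no HGVS description for %s; consequence 'other'", variant)
            consequence = ConsequenceClass("other")
        classification = classification_table.lookup(variant)
        panel_entry = panel.get(variant.gene) if variant.gene else None
        verdict = triage_variant(
            variant, consequence, classification, panel_entry, af_threshold
        )
        audit.append(
            AuditRecord(
                variant=variant,
                partner1=entry.partner1,
                partner2=entry.partner2,
                verdict=verdict,
                panel_entry=panel_entry,
            )
        )
    audit.sort(key=lambda rec: (rec.variant.chrom, rec.variant.pos, rec.variant.alt))
    shared_plp = [rec for rec in audit if rec.verdict.included]
    return CoupleScreenResult(
        couple_id=couple_variant_set.couple_id,
        cgr=cgr,
        shared_plp=shared_plp,
        audit=audit,
        relationship=relationship,
    )
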