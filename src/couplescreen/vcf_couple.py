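"""Partner genotype ingestion and couple-wise variant intersection.

The screening protocol starts from exome-wide genotype calls for the two
members of a consanguineous couple and reduces them to the set of sites at
which *both* partners carry at least one alternate allele — the candidate
loci at which a future child could be homozygous by descent.

Variants are decomposed to one alternate allele per record and trimmed to
their parsimonious representation so that the two partners' calls (and any
external annotation tables) match on a canonical ``(chrom, pos, ref, alt)``
key.  No reference-genome left-alignment is attempted unless local reference
sequence is supplied: calls produced by a single caller on the same cohort
already agree on placement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import CoupleScreenError, VcfParseError

logger = logging.getLogger(__name__)

# zygosity vocabulary
REF = "ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
ZYGOSITIES = (REF, HET, HOM_ALT, MISSING)
CARRIER_ZYGOSITIES = frozenset({HET, HOM_ALT})

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Variant:
    """A normalized, biallelic genomic change with optional annotations.

    Coordinates are VCF-style: 1-based, ``ref`` anchored at ``pos``.
    ``max_af`` is the maximum allele frequency observed across population
    databases, or ``None`` when the variant is absent from all of them
    (treated downstream as rarer than any threshold).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    gene: str = ""
    max_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CoupleScreenError(f"variant position must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref):
            raise CoupleScreenError(f"invalid REF allele {self.ref!r}")
        if not _ALLELE_RE.match(self.alt):
            raise CoupleScreenError(f"invalid ALT allele {self.alt!r}")
        if self.ref == self.alt:
            raise CoupleScreenError(
                f"REF and ALT are identical ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.max_af is not None and not 0.0 <= self.max_af <= 1.0:
            raise CoupleScreenError(
                f"allele frequency {self.max_af} outside [0, 1] at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Canonical matching key after normalization."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's zygosity at one (decomposed) variant site."""

    sample_id: str
    zygosity: str

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise CoupleScreenError(f"unknown zygosity {self.zygosity!r}")

    @property
    def is_carrier(self) -> bool:
        return self.zygosity in CARRIER_ZYGOSITIES


@dataclass(frozen=True)
class SharedVariant:
    """A variant carried by both partners, with each partner's call."""

    variant: Variant
    partner1: GenotypeCall
    partner2: GenotypeCall

    def __post_init__(self) -> None:
        for call in (self.partner1, self.partner2):
            if not call.is_carrier:
                raise CoupleScreenError(
                    f"shared variant {self.variant} has non-carrier call for "
                    f"{call.sample_id} ({call.zygosity})"
                )

    @property
    def has_hom_alt(self) -> bool:
        """True when either partner is homozygous for the alternate allele."""
        return HOM_ALT in (self.partner1.zygosity, self.partner2.zygosity)


@dataclass
class CoupleVariantSet:
    """All variants for which both members of a couple are carriers."""

    couple_id: str
    shared: list[SharedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [entry.variant.key for entry in self.shared]
        if len(keys) != len(set(keys)):
            raise CoupleScreenError(
                f"duplicate variant keys in shared set for couple {self.couple_id}"
            )

    def __len__(self) -> int:
        return len(self.shared)

    def __iter__(self):
        return iter(self.shared)


def _zygosity_for_allele(alleles: Sequence[int], alt_index: int) -> str:
    """Zygosity of one sample w.r.t. one alternate allele.

    ``alleles`` are the integer allele indices from the GT field (-1 for
    missing).  Half-calls such as ``./1`` count as het: the alternate allele
    was observed.  Phase is irrelevant here.
    """
    observed = [a for a in alleles if a >= 0]
    if not observed:
        return MISSING
    n_alt = sum(1 for a in observed if a == alt_index)
    if n_alt >= 2:
        return HOM_ALT
    if n_alt == 1:
        return HET
    return REF


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _per_alt_info(value, alt_index: int, n_alts: int) -> str:
    """Pick the value for one alternate allele from an INFO field."""
    if value is None:
        return ""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            value = value[alt_index - 1]
        else:
            value = value[0]
        return "" if value is None else str(value)
    text = str(value)
    if "," in text:
        parts = text.split(",")
        if len(parts) == n_alts:
            return parts[alt_index - 1].strip()
    return text


def _per_alt_af(value, alt_index: int, n_alts: int) -> Optional[float]:
    text = _per_alt_info(value, alt_index, n_alts)
    if text in ("", ".", "None"):
        return None
    return float(text)


def read_partner_genotypes(
    vcf_source,
    sample_id: Optional[str] = None,
    *,
    strip_chr_prefix: bool = True,
    gene_field: str = "GENE",
    hgvs_c_field: str = "HGVSC",
    hgvs_p_field: str = "HGVSP",
    af_field: str = "AF",
) -> list[tuple[Variant, GenotypeCall]]:
    """Read one partner's genotypes from a VCF 4.x file.

    Multi-allelic records are decomposed to one entry per alternate allele;
    each resulting variant is parsimony-trimmed.  Annotations (gene symbol,
    HGVS descriptions, allele frequency) are taken from the named INFO
    fields when present; a missing field simply leaves the annotation empty.

    Parameters
    ----------
    vcf_source
        Path to a plain or bgzipped VCF file.
    sample_id
        Sample to extract.  May be omitted for single-sample files.
    strip_chr_prefix
        Drop a leading ``chr`` from chromosome names so that ``chr1`` and
        ``1`` compare equal between differently-styled sources.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    try:
        vcf = VCF(str(vcf_source))
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise VcfParseError(f"cannot open VCF {vcf_source}: {exc}") from exc

    samples = list(vcf.samples)
    if sample_id is None:
        if len(samples) != 1:
            raise VcfParseError(
                "sample_id required for multi-sample VCF; available samples: "
                + ", ".join(samples)
            )
        sample_index = 0
        sample_id = samples[0]
    else:
        if sample_id not in samples:
            raise VcfParseError(
                f"sample {sample_id!r} not in VCF header; available samples: "
                + ", ".join(samples)
            )
        sample_index = samples.index(sample_id)

    entries: list[tuple[Variant, GenotypeCall]] = []
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            alleles = list(rec.genotypes[sample_index][:-1])  # last item is phase flag
            chrom = _strip_chr(rec.CHROM) if strip_chr_prefix else rec.CHROM
            alts = rec.ALT or []
            n_alts = len(alts)
            for alt_index, alt in enumerate(alts, start=1):
                ref = (rec.REF or "").upper()
                alt = (alt or "").upper()
                if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
                    logger.debug(
                        "skipping non-sequence allele at %s:%s (%r>%r)",
                        rec.CHROM, rec.POS, rec.REF, alt,
                    )
                    continue
                variant = Variant(
                    chrom=chrom,
                    pos=rec.POS,
                    ref=ref,
                    alt=alt,
                    gene=_per_alt_info(rec.INFO.get(gene_field), alt_index, n_alts),
                    hgvs_c=_per_alt_info(rec.INFO.get(hgvs_c_field), alt_index, n_alts),
                    hgvs_p=_per_alt_info(rec.INFO.get(hgvs_p_field), alt_index, n_alts),
                    max_af=_per_alt_af(rec.INFO.get(af_field), alt_index, n_alts),
                )
                variant = normalize_variant(variant)
                call = GenotypeCall(
                    sample_id=sample_id,
                    zygosity=_zygosity_for_allele(alleles, alt_index),
                )
                entries.append((variant, call))
    except CoupleScreenError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record #{record_no + 1} in {vcf_source}: {exc}"
        ) from exc
    return entries


def normalize_variant(
    variant: Variant,
    reference: Optional[str] = None,
    reference_start: int = 1,
) -> Variant:
    """Reduce a variant to its parsimonious (and, with reference, left-aligned)
    representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (always retaining at least one base in each allele); the position is
    advanced by the number of leading bases removed.  The operation is
    idempotent.

    When ``reference`` is given (a sequence string whose first base sits at
    1-based genomic position ``reference_start``), pure indels are also
    shifted left through repetitive context, matching the standard
    variant-normalization algorithm.  Without it, no left-alignment across
    flanking sequence is attempted.
    """
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    if not ref or not alt:
        raise CoupleScreenError(f"empty allele in record at {variant.chrom}:{variant.pos}")

    def _ref_base(p: int) -> Optional[str]:
        if reference is None:
            return None
        idx = p - reference_start
        if 0 <= idx < len(reference):
            return reference[idx].upper()
        return None

    while True:
        # trim shared suffix; with reference context an emptied allele is
        # re-padded on the left (this is what shifts indels leftward)
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if reference is not None and ref[-1] == alt[-1] and min(len(ref), len(alt)) == 1:
            base = _ref_base(pos - 1)
            if base is None:
                break
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:
        raise CoupleScreenError(
            f"malformed record: allele emptied by trimming at {variant.chrom}:{variant.pos}"
        )
    if (pos, ref, alt) == (variant.pos, variant.ref, variant.alt):
        return variant
    return replace(variant, pos=pos, ref=ref, alt=alt)


def _carrier_index(
    entries: Iterable[tuple[Variant, GenotypeCall]],
    partner_label: str,
) -> dict[tuple[str, int, str, str], tuple[Variant, GenotypeCall]]:
    index: dict[tuple[str, int, str, str], tuple[Variant, GenotypeCall]] = {}
    for variant, call in entries:
        if variant.key in index:
            logger.warning(
                "duplicate variant key %s for %s after normalization; keeping first",
                variant, partner_label,
            )
            continue
        index[variant.key] = (variant, call)
    return index


def intersect_couple(
    partner1: Iterable[tuple[Variant, GenotypeCall]],
    partner2: Iterable[tuple[Variant, GenotypeCall]],
    couple_id: str,
) -> CoupleVariantSet:
    """Variants for which both partners carry at least one alternate allele.

    The operation is symmetric in the two partners and keyed on the
    normalized ``(chrom, pos, ref, alt)`` tuple.  Homozygous-alternate calls
    count as carriers and are flagged on the resulting entries
    (``SharedVariant.has_hom_alt``) so reports can surface them distinctly.
    """
    index1 = _carrier_index(partner1, "partner1")
    index2 = _carrier_index(partner2, "partner2")
    shared: list[SharedVariant] = []
    for key in sorted(set(index1) & set(index2)):
        v1, call1 = index1[key]
        v2, call2 = index2[key]
        if call1.is_carrier and call2.is_carrier:
            # prefer the more annotated of the two copies of the variant
            variant = v1 if (v1.gene or v1.hgvs_c) else v2
            shared.append(SharedVariant(variant=variant, partner1=call1, partner2=call2))
    return CoupleVariantSet(couple_id=couple_id, shared=shared)
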