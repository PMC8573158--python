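"""Gene panel, clinical classification, consequence and frequency annotation.

The screening protocol restricts analysis to genes with an autosomal
recessive inheritance pattern (Clinical Genomic Database dialect), and
classifies each shared variant's molecular consequence from its HGVS
description.  The consequence split that matters downstream is binary:
*truncating* (frameshift, nonsense, canonical +/-1,2 splice) versus
*non-truncating* (missense, in-frame indel, everything else), because the
triage rules treat the two groups differently.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import CoupleScreenError
from .vcf_couple import Variant

logger = logging.getLogger(__name__)

# --- consequence vocabulary -------------------------------------------------

NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
CANONICAL_SPLICE = "canonical_splice"
MISSENSE = "missense"
INFRAME_INDEL = "inframe_indel"
OTHER = "other"
CONSEQUENCE_CATEGORIES = (
    NONSENSE, FRAMESHIFT, CANONICAL_SPLICE, MISSENSE, INFRAME_INDEL, OTHER,
)
TRUNCATING_CATEGORIES = frozenset({NONSENSE, FRAMESHIFT, CANONICAL_SPLICE})

# --- clinical significance vocabulary ---------------------------------------

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
PLP_COMBINED = "plp_combined"
VUS = "vus"
CONFLICTING = "conflicting"
BENIGN = "benign"
LIKELY_BENIGN = "likely_benign"
ABSENT = "absent"
SIGNIFICANCES = (
    PATHOGENIC, LIKELY_PATHOGENIC, PLP_COMBINED, VUS, CONFLICTING,
    BENIGN, LIKELY_BENIGN, ABSENT,
)
#: significances that count as pathogenic/likely pathogenic for triage
PLP_SIGNIFICANCES = frozenset({PATHOGENIC, LIKELY_PATHOGENIC, PLP_COMBINED})
#: ordering used to resolve duplicate classification rows (most pathogenic first)
SEVERITY_ORDER = (
    PATHOGENIC, PLP_COMBINED, LIKELY_PATHOGENIC, CONFLICTING, VUS,
    LIKELY_BENIGN, BENIGN, ABSENT,
)

LOF_MECHANISM_VALUES = ("yes", "no", "unknown")


@dataclass(frozen=True)
class GenePanelEntry:
    """One disease gene from the autosomal-recessive panel."""

    gene: str
    condition: str
    omim: str
    inheritance: frozenset
    lof_mechanism: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene:
            raise CoupleScreenError("panel entry with empty gene symbol")
        if not self.inheritance:
            raise CoupleScreenError(f"panel gene {self.gene}: empty inheritance set")
        if self.lof_mechanism not in LOF_MECHANISM_VALUES:
            raise CoupleScreenError(
                f"panel gene {self.gene}: lof_mechanism must be one of "
                f"{LOF_MECHANISM_VALUES}, got {self.lof_mechanism!r}"
            )


@dataclass(frozen=True)
class ClassificationRecord:
    """Clinical significance assertion for one variant (ClinVar-like)."""

    significance: str = ABSENT
    review_status: str = ""

    def __post_init__(self) -> None:
        if self.significance not in SIGNIFICANCES:
            raise CoupleScreenError(f"unknown significance {self.significance!r}")

    @property
    def is_plp(self) -> bool:
        return self.significance in PLP_SIGNIFICANCES


@dataclass(frozen=True)
class ConsequenceClass:
    """Molecular consequence with the truncating/non-truncating split."""

    category: str

    def __post_init__(self) -> None:
        if self.category not in CONSEQUENCE_CATEGORIES:
            raise CoupleScreenError(f"unknown consequence category {self.category!r}")

    @property
    def truncating(self) -> bool:
        return self.category in TRUNCATING_CATEGORIES


# --- panel loading -----------------------------------------------------------

_PANEL_COLUMNS = ("GENE", "CONDITION", "OMIM", "INHERITANCE", "LOF_MECHANISM")
_INHERITANCE_SPLIT = re.compile(r"[,/;|\s]+")


def _read_tsv(source, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise CoupleScreenError(
            f"table is missing required column(s): {', '.join(missing)}"
        )
    return frame


def load_panel(tsv_source: Union[str, io.IOBase]) -> dict[str, GenePanelEntry]:
    """Load a gene panel TSV and keep only autosomal-recessive genes.

    A gene is retained when its inheritance token set contains ``AR`` —
    genes annotated as both dominant and recessive (``AD,AR``) therefore
    stay in the panel.  Duplicate gene rows keep the first occurrence.
    """
    frame = _read_tsv(tsv_source, _PANEL_COLUMNS)
    panel: dict[str, GenePanelEntry] = {}
    for row in frame.itertuples(index=False):
        gene = row.GENE.strip()
        if not gene:
            continue
        if gene in panel:
            logger.warning("duplicate panel gene %s; keeping first row", gene)
            continue
        tokens = frozenset(
            t.upper() for t in _INHERITANCE_SPLIT.split(row.INHERITANCE.strip()) if t
        )
        if "AR" not in tokens:
            continue
        lof = row.LOF_MECHANISM.strip().lower() or "unknown"
        panel[gene] = GenePanelEntry(
            gene=gene,
            condition=row.CONDITION.strip(),
            omim=row.OMIM.strip(),
            inheritance=tokens,
            lof_mechanism=lof,
        )
    if not panel:
        logger.warning("gene panel is empty after AR filtering")
    logger.info("loaded %d AR panel genes", len(panel))
    return panel


# --- HGVS consequence classification -----------------------------------------

_INTRON_OFFSET = re.compile(r"(?<=\d)([+-])(\d+)")
_MISSENSE = re.compile(r"^[A-Z][a-z]{2}\d+[A-Z][a-z]{2}$")
_STOP_GAIN = re.compile(r"^[A-Z][a-z]{2}\d+(\*|Ter)$")
_RANGE = re.compile(r"(\d+)(?:_(\d+))?(delins|del|dup|ins)([ACGT]*)", re.IGNORECASE)


def _strip_p(hgvs_p: str) -> str:
    text = hgvs_p.strip()
    if text.startswith("p."):
        text = text[2:]
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1]
    return text


def _indel_span(hgvs_c: str) -> Optional[tuple[str, int]]:
    """(kind, net length change) for a c.-level indel description, if any."""
    match = _RANGE.search(hgvs_c)
    if not match:
        return None
    start, end, kind, seq = match.groups()
    kind = kind.lower()
    span = int(end) - int(start) + 1 if end else 1
    if kind == "ins":
        length = len(seq) if seq else 0
        if length == 0:
            return None  # length unknown, e.g. "ins(20)"
    elif kind == "delins":
        length = abs(span - len(seq))
    else:  # del or dup
        length = span
    return kind, length


def classify_consequence(hgvs_c: str, hgvs_p: str = "") -> ConsequenceClass:
    """Classify a variant's consequence from its HGVS c. and p. descriptions.

    Rules are applied in a fixed order; the protein-level description wins
    when it is informative (a frameshift or stop annotation) because it
    reflects the observed reading-frame effect:

    1. ``fs`` in the protein change        -> frameshift
    2. substitution to a stop (``*``/Ter)  -> nonsense
    3. intronic offset of +/-1 or +/-2     -> canonical splice
    4. c.-level del/dup/ins, length % 3 == 0 -> in-frame indel
       (a non-multiple-of-3 length with no protein description is called
       frameshift from the nucleotide arithmetic alone)
    5. single amino-acid substitution      -> missense
    6. anything else                       -> other

    Unparseable descriptions never raise; they fall through to ``other``
    with a logged warning.
    """
    if not hgvs_c and not hgvs_p:
        raise CoupleScreenError("classify_consequence needs at least one HGVS string")
    p = _strip_p(hgvs_p or "")
    c = (hgvs_c or "").strip()

    if "fs" in p:
        return ConsequenceClass(FRAMESHIFT)
    if _STOP_GAIN.match(p):
        return ConsequenceClass(NONSENSE)
    offset = _INTRON_OFFSET.search(c)
    if offset and int(offset.group(2)) in (1, 2):
        return ConsequenceClass(CANONICAL_SPLICE)
    span = _indel_span(c)
    if span is not None:
        _, length = span
        if length % 3 == 0:
            return ConsequenceClass(INFRAME_INDEL)
        if not p:
            return ConsequenceClass(FRAMESHIFT)
    if _MISSENSE.match(p):
        return ConsequenceClass(MISSENSE)
    if p or c:
        logger.debug("consequence fell through to 'other' for (%r, %r)", hgvs_c, hgvs_p)
    return ConsequenceClass(OTHER)


# --- classification (ClinVar-like) table -------------------------------------

_SIGNIFICANCE_ALIASES = {
    "pathogenic": PATHOGENIC,
    "likely pathogenic": LIKELY_PATHOGENIC,
    "pathogenic likely pathogenic": PLP_COMBINED,
    "uncertain significance": VUS,
    "vus": VUS,
    "conflicting": CONFLICTING,
    "conflicting interpretations of pathogenicity": CONFLICTING,
    "conflicting classifications of pathogenicity": CONFLICTING,
    "benign": BENIGN,
    "likely benign": LIKELY_BENIGN,
    "benign likely benign": LIKELY_BENIGN,
    "absent": ABSENT,
    "not provided": ABSENT,
}


def parse_significance(text: str) -> str:
    """Map a free-form clinical significance string onto the closed vocabulary.

    Case, underscores and slashes are ignored; unrecognized strings map to
    ``vus`` (never counted as pathogenic) with a warning.
    """
    if text is None or not str(text).strip():
        return ABSENT
    canon = re.sub(r"[_/,]+", " ", str(text).strip().lower())
    canon = re.sub(r"\s+", " ", canon)
    if canon in _SIGNIFICANCE_ALIASES:
        return _SIGNIFICANCE_ALIASES[canon]
    logger.warning("unrecognized clinical significance %r; treating as VUS", text)
    return VUS


_CLASSIFICATION_COLUMNS = (
    "CHROM", "POS", "REF", "ALT", "GENE", "HGVS_C", "CLNSIG", "REVIEW_STATUS",
)


class ClassificationTable:
    """Lookup of clinical significance by genomic key or (gene, hgvs_c).

    Exact genomic keys take precedence; the HGVS key is the fallback for
    variants whose table rows lack coordinates.  Duplicate keys keep the
    most pathogenic assertion.
    """

    def __init__(self) -> None:
        self._by_genomic: dict[tuple[str, int, str, str], ClassificationRecord] = {}
        self._by_hgvs: dict[tuple[str, str], ClassificationRecord] = {}

    def __len__(self) -> int:
        return max(len(self._by_genomic), len(self._by_hgvs))

    @staticmethod
    def _more_severe(a: ClassificationRecord, b: ClassificationRecord) -> ClassificationRecord:
        return min(a, b, key=lambda r: SEVERITY_ORDER.index(r.significance))

    def _add(self, index, key, record) -> None:
        if key in index:
            logger.warning(
                "duplicate classification rows for %s; keeping most pathogenic", key
            )
            record = self._more_severe(index[key], record)
        index[key] = record

    def add_record(
        self,
        *,
        chrom: str = "",
        pos: Optional[int] = None,
        ref: str = "",
        alt: str = "",
        gene: str = "",
        hgvs_c: str = "",
        clnsig: str = "",
        review_status: str = "",
    ) -> None:
        record = ClassificationRecord(
            significance=parse_significance(clnsig),
            review_status=review_status,
        )
        if chrom and pos is not None and ref and alt:
            self._add(self._by_genomic, (str(chrom), int(pos), ref, alt), record)
        if gene and hgvs_c:
            self._add(self._by_hgvs, (gene, hgvs_c), record)
        if not ((chrom and pos is not None and ref and alt) or (gene and hgvs_c)):
            raise CoupleScreenError(
                "classification row needs a genomic key or a (gene, hgvs_c) key"
            )

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "ClassificationTable":
        table = cls()
        for rec in records:
            table.add_record(**rec)
        return table

    @classmethod
    def from_tsv(cls, tsv_source) -> "ClassificationTable":
        frame = _read_tsv(tsv_source, _CLASSIFICATION_COLUMNS)
        table = cls()
        for row in frame.itertuples(index=False):
            table.add_record(
                chrom=row.CHROM,
                pos=int(row.POS) if str(row.POS).strip() else None,
                ref=row.REF,
                alt=row.ALT,
                gene=row.GENE,
                hgvs_c=row.HGVS_C,
                clnsig=row.CLNSIG,
                review_status=row.REVIEW_STATUS,
            )
        return table

    def lookup(self, variant: Variant) -> ClassificationRecord:
        """Significance for a variant; ``absent`` when unlisted."""
        record = self._by_genomic.get(variant.key)
        if record is not None:
            return record
        if variant.gene and variant.hgvs_c:
            record = self._by_hgvs.get((variant.gene, variant.hgvs_c))
            if record is not None:
                return record
        return ClassificationRecord(significance=ABSENT)


def lookup_classification(
    variant: Variant, classification_table: ClassificationTable
) -> ClassificationRecord:
    """Functional alias for :meth:`ClassificationTable.lookup`."""
    return classification_table.lookup(variant)


# --- allele frequencies -------------------------------------------------------

_FREQUENCY_KEY_COLUMNS = ("CHROM", "POS", "REF", "ALT")


class FrequencyTable:
    """Per-variant maximum allele frequency across population columns."""

    def __init__(self) -> None:
        self._max_af: dict[tuple[str, int, str, str], float] = {}

    def __len__(self) -> int:
        return len(self._max_af)

    def add_record(self, chrom: str, pos: int, ref: str, alt: str, *afs: float) -> None:
        values = [float(a) for a in afs if a is not None and str(a).strip() != ""]
        for af in values:
            if not 0.0 <= af <= 1.0:
                raise CoupleScreenError(
                    f"allele frequency {af} outside [0, 1] for {chrom}:{pos}"
                )
        if values:
            self._max_af[(str(chrom), int(pos), ref, alt)] = max(values)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "FrequencyTable":
        table = cls()
        for chrom, pos, ref, alt, *afs in records:
            table.add_record(chrom, pos, ref, alt, *afs)
        return table

    @classmethod
    def from_tsv(cls, tsv_source) -> "FrequencyTable":
        frame = _read_tsv(tsv_source, _FREQUENCY_KEY_COLUMNS)
        af_columns = [c for c in frame.columns if c.upper().startswith("AF")]
        if not af_columns:
            raise CoupleScreenError("frequency table has no AF_* columns")
        table = cls()
        for row in frame.itertuples(index=False):
            afs = [
                float(getattr(row, col))
                for col in af_columns
                if str(getattr(row, col)).strip() not in ("", ".")
            ]
            table.add_record(row.CHROM, int(row.POS), row.REF, row.ALT, *afs)
        return table

    def max_af(self, variant: Variant) -> Optional[float]:
        return self._max_af.get(variant.key)


def attach_frequency(
    variant: Variant, frequency_source: Optional[FrequencyTable]
) -> Variant:
    """Set ``max_af`` to the maximum over all available frequency sources.

    Any frequency already carried by the variant (e.g. from the VCF INFO
    field) is combined with the lookup table; a variant absent everywhere
    keeps ``max_af = None`` and is treated as rare downstream.
    """
    from dataclasses import replace

    candidates = [variant.max_af]
    if frequency_source is not None:
        candidates.append(frequency_source.max_af(variant))
    values = [v for v in candidates if v is not None]
    if not values:
        return variant
    return replace(variant, max_af=max(values))
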