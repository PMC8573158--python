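"""Reference cohort of 39 consanguineous couples.

This module encodes the published screening outcome of a cohort of 39
consanguineous couples — relationship label, shared pathogenic / likely
pathogenic (PLP) variants per couple, and the associated disease genes —
as structured data.  HGVS strings are stored without internal whitespace
(``c.1456C>T``, not ``c.1456C > T``).

The cohort serves both as a regression fixture (the pipeline must
reproduce its counts exactly: 21/39 positive couples overall, 13/25
positive first-cousin couples, 8 couples with two or more shared PLPs)
and as a realistic panel/classification source for the synthetic-couple
generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .annotation_panel import ClassificationTable, GenePanelEntry, classify_consequence
from .errors import CoupleScreenError
from .risk import cgr_from_relationship
from .triage import CoupleScreenResult, screen_couple
from .vcf_couple import CoupleVariantSet, GenotypeCall, SharedVariant, Variant


@dataclass(frozen=True)
class FixtureVariant:
    gene: str
    disease: str
    omim: str
    hgvs_c: str
    hgvs_p: str = ""


@dataclass(frozen=True)
class FixtureCouple:
    couple_id: str
    relationship: str
    variants: tuple = ()

    @property
    def positive(self) -> bool:
        return len(self.variants) > 0

    @property
    def cgr(self) -> float:
        return cgr_from_relationship(self.relationship)


# (relationship, ((gene, disease, omim, hgvs_c, hgvs_p), ...)) in table order
_RAW = (
    ("uncle_niece", (
        ("PKLR", "Pyruvate kinase deficiency in red blood cells", "266200",
         "c.1456C>T", "p.(Arg486Trp)"),
    )),
    ("double_first_cousins", (
        ("CHEK2", "Breast and colorectal cancer, susceptibility to", "604373",
         "c.975+1G>C", ""),
        ("CC2D1A", "Intellectual deficiency, autosomal recessive 3", "608443",
         "c.1357-2A>C", ""),
        ("GJB2", "Deafness, autosomal recessive 1A", "220290",
         "c.109G>A", "p.(Val37Ile)"),
    )),
    ("first_cousins", (
        ("NEB", "Nemaline myopathy 2, autosomal recessive", "256030",
         "c.1258-2A>G", ""),
        ("DYNC2H1", "Asphyxiating thoracic dystrophy 3", "613091",
         "c.6047A>G", "p.(Tyr2016Cys)"),
    )),
    ("first_cousins", (
        ("WRAP53", "Dyskeratosis congenita, autosomal recessive 3", "613988",
         "c.1564dup", "p.(Ala522Glyfs*8)"),
    )),
    ("first_cousins", (
        ("SLC37A4", "Glycogen storage disease Ib", "232220",
         "c.935_936del", "p.(Thr312Serfs*13)"),
        ("IFT122", "Cranioectodermal dysplasia 1", "218330",
         "c.1301-1G>C", ""),
    )),
    ("first_cousins", (
        ("CBS", "Homocystinuria", "236200", "c.833T>C", "p.(Ile278Thr)"),
        ("CYP21A2", "Adrenal hyperplasia, congenital", "201910",
         "c.955C>T", "p.(Gln319*)"),
    )),
    ("first_cousins", (
        ("TMEM70", "Mitochondrial complex V deficiency, nuclear type 2", "614052",
         "c.317-2A>G", ""),
        ("ASS1", "Citrullinemia", "215700", "c.323G>T", "p.(Arg108Leu)"),
    )),
    ("first_cousins", (
        ("ABCA4", "Stargardt disease 1", "248200", "c.2588G>C", "p.(Gly863Ala)"),
    )),
    ("first_cousins", (
        ("CTSC", "Papillon-Lefevre syndrome", "245000",
         "c.194_197dup", "p.(Tyr67Profs*11)"),
    )),
    ("first_cousins", (
        ("GALT", "Galactosemia", "230400", "c.563A>G", "p.(Gln188Arg)"),
    )),
    ("first_cousins", (
        ("RIPPLY2", "Spondylocostal dysostosis 6", "616566",
         "c.238A>T", "p.(Arg80*)"),
    )),
    ("first_cousins", (
        ("DUOX2", "Thyroid dyshormonogenesis 6", "607200",
         "c.2428G>T", "p.(Glu810*)"),
    )),
    ("first_cousins", (
        ("HBB", "Sickle cell anemia", "603903", "c.20A>T", "p.(Glu7Val)"),
        ("LPL", "Hyperlipoproteinemia, type I", "238600",
         "c.953A>G", "p.(Asn318Ser)"),
    )),
    ("first_cousins", (
        ("MCPH1", "Microcephaly 1", "251200", "c.2145G>A", "p.(Trp715*)"),
        ("GJB2", "Deafness, autosomal recessive 1A", "220290",
         "c.35del", "p.(Gly12Valfs*2)"),
    )),
    ("first_cousins", (
        ("CBS", "Cystathionine beta-synthase deficiency", "236200",
         "c.833T>C", "p.(Ile278Thr)"),
        ("MUTYH", "Familial adenomatous polyposis 2", "608456",
         "c.721C>T", "p.(Arg241Trp)"),
    )),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("half_uncle_niece", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins", ()),
    ("first_cousins_once_removed", (
        ("ACADVL", "Acyl-CoA dehydrogenase, very long-chain, deficiency", "201475",
         "c.685C>T", "p.(Arg229*)"),
    )),
    ("first_cousins_once_removed", (
        ("ACPT", "Amelogenesis imperfecta, type IJ", "617297",
         "c.945dup", "p.(Glu316*)"),
    )),
    ("first_cousins_once_removed", ()),
    ("second_cousins", (
        ("LOXHD1", "Deafness, autosomal recessive 77", "613079",
         "c.2047+1G>A", ""),
    )),
    ("second_cousins", (
        ("SCN4A", "Fetal akinesia deformation sequence 1", "208150",
         "c.1173del", "p.(Phe392Serfs*12)"),
    )),
    ("second_cousins", (
        ("TCTN1", "Joubert syndrome, type 13", "614173",
         "c.1775_1778del", "p.(Val592_593delins30)"),
    )),
    ("second_cousins", (
        ("IL10RA", "Inflammatory bowel disease 28, early onset", "613148",
         "c.349C>T", "p.(Arg117Cys)"),
    )),
    ("second_cousins", ()),
    ("second_cousins", ()),
    ("second_cousins", ()),
    ("second_cousins", ()),
)

# genes with a recognized dominant mode in addition to the recessive one
_AD_AR_GENES = frozenset({"CHEK2", "MUTYH"})


@dataclass
class Table1Fixture:
    """The reference cohort as structured records."""

    couples: list = field(default_factory=list)

    @property
    def n_couples(self) -> int:
        return len(self.couples)

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.couples if c.positive)

    @property
    def variants(self) -> list:
        return [v for c in self.couples for v in c.variants]

    def by_relationship(self, label: str) -> list:
        return [c for c in self.couples if c.relationship == label]


def load_table1_fixture() -> Table1Fixture:
    """The reference cohort: 39 couples, 30 shared PLP variant rows."""
    couples = [
        FixtureCouple(
            couple_id=f"C{i:02d}",
            relationship=relationship,
            variants=tuple(FixtureVariant(*v) for v in variants),
        )
        for i, (relationship, variants) in enumerate(_RAW, start=1)
    ]
    return Table1Fixture(couples=couples)


def fixture_panel() -> dict:
    """Autosomal-recessive gene panel covering every cohort gene.

    Loss of function is recorded as a known disease mechanism for each of
    these genes, so unlisted truncating variants are retained by the
    loss-of-function rule; genes that also cause dominant disease carry
    both inheritance tokens.
    """
    panel: dict[str, GenePanelEntry] = {}
    for couple in load_table1_fixture().couples:
        for v in couple.variants:
            if v.gene in panel:
                continue
            modes = frozenset({"AD", "AR"}) if v.gene in _AD_AR_GENES else frozenset({"AR"})
            panel[v.gene] = GenePanelEntry(
                gene=v.gene,
                condition=v.disease,
                omim=v.omim,
                inheritance=modes,
                lof_mechanism="yes",
            )
    return panel


def fixture_classification() -> ClassificationTable:
    """Clinical assertions for the cohort's non-truncating variants.

    The protocol only retains a non-truncating shared variant when an
    external classification already asserts it pathogenic or likely
    pathogenic, so every retained missense/in-frame variant of the cohort
    is, by construction, asserted; truncating variants are left unlisted
    and flow through the loss-of-function rule instead.
    """
    table = ClassificationTable()
    seen: set[tuple[str, str]] = set()
    for v in load_table1_fixture().variants:
        key = (v.gene, v.hgvs_c)
        if key in seen:
            continue
        seen.add(key)
        consequence = classify_consequence(v.hgvs_c, v.hgvs_p)
        if not consequence.truncating:
            table.add_record(
                gene=v.gene, hgvs_c=v.hgvs_c, clnsig="Pathogenic",
                review_status="criteria provided, multiple submitters",
            )
    return table


_SUBSTITUTION = re.compile(r"c\.\d+([ACGT])>([ACGT])$")


def _fixture_variant_objects(couple: FixtureCouple, base_pos: int) -> list[Variant]:
    """Variant objects with synthetic, collision-free genomic coordinates.

    The published table identifies variants by gene and HGVS description
    only; coordinates here are placeholders so that object invariants hold
    and classification lookups resolve through the (gene, hgvs_c) key.
    """
    out = []
    for j, v in enumerate(couple.variants):
        match = _SUBSTITUTION.match(v.hgvs_c)
        ref, alt = match.groups() if match else ("AT", "A")
        out.append(
            Variant(
                chrom="1", pos=base_pos + 100 * j, ref=ref, alt=alt,
                gene=v.gene, hgvs_c=v.hgvs_c, hgvs_p=v.hgvs_p,
            )
        )
    return out


def screen_table1(af_threshold: float = 0.01) -> list:
    """Run the real triage pipeline over the reference cohort.

    Every cohort variant is rare (absent from population tables here) and
    shared in heterozygosity by both partners; the returned per-couple
    results must reproduce the published counts.
    """
    fixture = load_table1_fixture()
    panel = fixture_panel()
    classification = fixture_classification()
    results: list[CoupleScreenResult] = []
    for i, couple in enumerate(fixture.couples):
        variants = _fixture_variant_objects(couple, base_pos=10_000 + 10_000 * i)
        shared = [
            SharedVariant(
                variant=variant,
                partner1=GenotypeCall(f"{couple.couple_id}-P1", "het"),
                partner2=GenotypeCall(f"{couple.couple_id}-P2", "het"),
            )
            for variant in variants
        ]
        couple_set = CoupleVariantSet(couple_id=couple.couple_id, shared=shared)
        results.append(
            screen_couple(
                couple_set,
                panel,
                classification,
                frequency_source=None,
                cgr=couple.cgr,
                relationship=couple.relationship,
                af_threshold=af_threshold,
            )
        )
    n_plp = sum(r.n_plp for r in results)
    if n_plp != len(fixture.variants):  # pragma: no cover - internal consistency
        raise CoupleScreenError(
            f"fixture triage retained {n_plp} variants, expected "
            f"{len(fixture.variants)}"
        )
    return results
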