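"""Genotype ingestion, variant normalization, and couple intersection."""

import numpy as np
import pytest

from couplescreen import (
    CoupleScreenError,
    GenotypeCall,
    Variant,
    VcfParseError,
    intersect_couple,
    normalize_variant,
    read_partner_genotypes,
)
from couplescreen.vcf_couple import CARRIER_ZYGOSITIES, HET, HOM_ALT, MISSING, REF

from conftest import write_vcf


def _gt_zygosity_oracle(gt: str, alt_index: int) -> str:
    """Independent zygosity rule applied directly to a GT string."""
    alleles = gt.replace("|", "/").split("/")
    observed = [a for a in alleles if a != "."]
    if not observed:
        return MISSING
    hits = sum(1 for a in observed if int(a) == alt_index)
    return {0: REF, 1: HET}.get(hits, HOM_ALT)


class TestReadPartnerGenotypes:
    def test_single_sample_het(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "A", "G", "GENE=GJB2", "0/1")],
                         samples=("S1",))
        entries = read_partner_genotypes(path)  # sample_id optional
        assert len(entries) == 1
        variant, call = entries[0]
        assert (variant.key, call.zygosity) == (("1", 100, "A", "G"), HET)
        assert variant.gene == "GJB2"

    @pytest.mark.parametrize("gt", ["0/0", "0/1", "1/0", "0|1", "1|0", "1/1",
                                    "./1", "1/.", "./.", "0/."])
    def test_biallelic_zygosity_matches_gt_oracle(self, tmp_path, gt):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "A", "G", None, gt)], samples=("S1",))
        (_, call), = read_partner_genotypes(path)
        assert call.zygosity == _gt_zygosity_oracle(gt, 1)

    @pytest.mark.parametrize("gt", ["0/0", "0/1", "0/2", "1/1", "1/2", "2/2",
                                    "./1", "./2", "./."])
    def test_multiallelic_decomposition_matches_oracle(self, tmp_path, gt):
        """GT over two alternates decomposes to one het/hom call per allele."""
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "G", "A,T", None, gt)], samples=("S1",))
        entries = read_partner_genotypes(path)
        assert [v.alt for v, _ in entries] == ["A", "T"]
        for alt_index, (_, call) in enumerate(entries, start=1):
            assert call.zygosity == _gt_zygosity_oracle(gt, alt_index)

    def test_missing_genotype_yields_missing(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "A", "G", None, "./.")], samples=("S1",))
        (_, call), = read_partner_genotypes(path)
        assert call.zygosity == MISSING

    def test_unknown_sample_error_names_available(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "A", "G", None, "0/1", "0/0")])
        with pytest.raises(VcfParseError, match="P1, P2"):
            read_partner_genotypes(path, "NOPE")

    def test_multisample_requires_sample_id(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "A", "G", None, "0/1", "0/0")])
        with pytest.raises(VcfParseError, match="sample_id required"):
            read_partner_genotypes(path)

    def test_chr_prefix_stripped_by_default(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("chr2", 100, "A", "G", None, "0/1")], samples=("S1",))
        (variant, _), = read_partner_genotypes(path)
        assert variant.chrom == "2"
        (variant, _), = read_partner_genotypes(path, strip_chr_prefix=False)
        assert variant.chrom == "chr2"

    def test_info_af_attached_per_alt(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         [("1", 100, "G", "A,T", "AF=0.004,0.2", "1/2")],
                         samples=("S1",))
        entries = read_partner_genotypes(path)
        assert [v.max_af for v, _ in entries] == pytest.approx([0.004, 0.2], rel=1e-5)


def _trim_oracle(pos, ref, alt):
    """Enumerate every legal (prefix, suffix) trim; return the maximal one.

    Suffix bases are removed first, then prefix bases, each while the two
    alleles still agree there and at least one base remains on each side.
    """
    best = (pos, ref, alt)
    max_s = min(len(ref), len(alt)) - 1
    for s in range(max_s, -1, -1):
        r, a = (ref[:-s], alt[:-s]) if s else (ref, alt)
        if ref[len(ref) - s:] != alt[len(alt) - s:]:
            continue
        for p in range(min(len(r), len(a)) - 1, -1, -1):
            if r[:p] == a[:p]:
                return (pos + p, r[p:], a[p:])
    return best


class TestNormalizeVariant:
    @pytest.mark.parametrize("raw,expected", [
        ((100, "A", "G"), (100, "A", "G")),          # already minimal
        ((50, "TTC", "TGC"), (51, "T", "G")),        # shared prefix+suffix
        ((200, "GCC", "GCCACC"), (200, "G", "GCCA")),  # suffix trimmed first
    ])
    def test_parsimony_examples(self, raw, expected):
        pos, ref, alt = raw
        v = normalize_variant(Variant(chrom="1", pos=pos, ref=ref, alt=alt))
        assert (v.pos, v.ref, v.alt) == expected

    def test_matches_exhaustive_trim_oracle(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            core = lambda n: "".join(rng.choice(bases, size=n))
            pre, suf = core(rng.integers(0, 4)), core(rng.integers(0, 4))
            ref = pre + core(rng.integers(1, 4)) + suf
            alt = pre + core(rng.integers(1, 4)) + suf
            if ref == alt:
                continue
            v = normalize_variant(Variant(chrom="1", pos=100, ref=ref, alt=alt))
            assert (v.pos, v.ref, v.alt) == _trim_oracle(100, ref, alt)

    def test_idempotent_on_randomized_indels(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            ref = "".join(rng.choice(bases, size=rng.integers(1, 8)))
            alt = "".join(rng.choice(bases, size=rng.integers(1, 8)))
            if ref == alt:
                continue
            once = normalize_variant(Variant(chrom="1", pos=500, ref=ref, alt=alt))
            assert normalize_variant(once) == once

    def test_left_alignment_with_reference_context(self):
        # deletion of one AC unit inside an AC run shifts to the run start
        reference = "TTCACACACAG"  # positions 100..110
        v = Variant(chrom="1", pos=106, ref="CAC", alt="C")
        shifted = normalize_variant(v, reference=reference, reference_start=100)
        assert (shifted.pos, shifted.ref, shifted.alt) == (101, "TCA", "T")

        # equivalence: both representations delete the same haplotype bases
        def apply(pos, ref, alt):
            i = pos - 100
            assert reference[i:i + len(ref)] == ref
            return reference[:i] + alt + reference[i + len(ref):]

        assert apply(106, "CAC", "C") == apply(*([shifted.pos, shifted.ref, shifted.alt]))
        assert normalize_variant(shifted, reference=reference,
                                 reference_start=100) == shifted

    def test_invalid_alleles_rejected(self):
        with pytest.raises(CoupleScreenError):
            Variant(chrom="1", pos=100, ref="A", alt="A")
        with pytest.raises(CoupleScreenError):
            Variant(chrom="1", pos=0, ref="A", alt="G")
        with pytest.raises(CoupleScreenError):
            Variant(chrom="1", pos=100, ref="", alt="G")


def _entry(pos, zygosity, sample="S"):
    return (Variant(chrom="1", pos=pos, ref="A", alt="G"),
            GenotypeCall(sample, zygosity))


class TestIntersectCouple:
    def test_basic_intersection(self):
        p1 = [_entry(1, HET), _entry(2, HET)]
        p2 = [_entry(2, HET), _entry(3, HET)]
        result = intersect_couple(p1, p2, "c1")
        assert [e.variant.pos for e in result] == [2]

    def test_disjoint_lists_give_empty_set(self):
        result = intersect_couple([_entry(1, HET)], [_entry(2, HET)], "c1")
        assert len(result) == 0

    @pytest.mark.parametrize("z1", [REF, HET, HOM_ALT, MISSING])
    @pytest.mark.parametrize("z2", [REF, HET, HOM_ALT, MISSING])
    def test_all_zygosity_pairs_against_carrier_rule(self, z1, z2):
        """A site is shared exactly when both calls carry an alt allele."""
        result = intersect_couple([_entry(5, z1)], [_entry(5, z2)], "c1")
        expected = z1 in CARRIER_ZYGOSITIES and z2 in CARRIER_ZYGOSITIES
        assert (len(result) == 1) == expected

    def test_hom_alt_retained_and_flagged(self):
        result = intersect_couple([_entry(5, HET)], [_entry(5, HOM_ALT)], "c1")
        assert len(result) == 1 and result.shared[0].has_hom_alt
        result = intersect_couple([_entry(5, HET)], [_entry(5, HET)], "c1")
        assert not result.shared[0].has_hom_alt

    def test_symmetric_in_partner_order(self):
        rng = np.random.default_rng(19)
        zygosities = [REF, HET, HOM_ALT, MISSING]
        p1 = [_entry(int(p) + 1, zygosities[rng.integers(4)]) for p in range(30)]
        p2 = [_entry(int(p) + 1, zygosities[rng.integers(4)])
              for p in rng.choice(40, size=25, replace=False)]
        forward = intersect_couple(p1, p2, "c1")
        backward = intersect_couple(p2, p1, "c1")
        assert ([e.variant.key for e in forward]
                == [e.variant.key for e in backward])

    def test_duplicate_keys_keep_first_with_warning(self, caplog):
        p1 = [_entry(5, HET, "a"), _entry(5, HOM_ALT, "b")]
        with caplog.at_level("WARNING"):
            result = intersect_couple(p1, [_entry(5, HET)], "c1")
        assert "duplicate" in caplog.text
        assert result.shared[0].partner1.sample_id == "a"

    def test_decomposition_then_intersection_commutes(self, tmp_path):
        """Intersecting decomposed records equals decomposing the shared site."""
        records = [("1", 100, "G", "A,T", None, "1/2", "0/1"),
                   ("1", 200, "C", "T", None, "0/1", "1/1")]
        path = write_vcf(tmp_path / "m.vcf", records)
        p1 = read_partner_genotypes(path, "P1")
        p2 = read_partner_genotypes(path, "P2")
        shared = intersect_couple(p1, p2, "c1")
        # P1 carries A and T at 100, P2 only A; both carry T at 200
        assert {e.variant.key for e in shared} == {
            ("1", 100, "G", "A"), ("1", 200, "C", "T"),
        }
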