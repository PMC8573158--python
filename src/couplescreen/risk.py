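"""Pedigree kinship, coefficient of genetic relationship, and couple risk.

The coefficient of genetic relationship (CGR) between the two partners is
twice their kinship coefficient — the expected fraction of alleles shared
identical by descent.  For a couple sharing ``PLP`` pathogenic or likely
pathogenic carrier variants, the probability that at least one of them is
shared through common ancestry gives the at-risk-couple (ARC) rate:

    ARC = 1 - (1 - CGR) ** PLP

which inverts to ``PLP = ln(1 - ARC) / ln(1 - CGR)``.  Both directions are
exposed, together with cohort summarization (positive fractions with exact
binomial confidence intervals, stratified by CGR and by relationship label,
plus the formula-inverted PLP estimate per stratum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .errors import CoupleScreenError
from .triage import CoupleScreenResult

#: closed vocabulary of pedigree-backed relationship labels
RELATIONSHIP_LABELS = (
    "uncle_niece",
    "double_first_cousins",
    "first_cousins",
    "half_uncle_niece",
    "first_cousins_once_removed",
    "second_cousins",
)


@dataclass
class Pedigree:
    """Individuals with parent links and the couple of interest.

    ``parents`` maps an individual to its (father, mother); founders are
    absent from the map or have ``(None, None)``.  Parent links must be
    acyclic.
    """

    individuals: set
    parents: dict
    partner_pair: tuple

    def __post_init__(self) -> None:
        for pid in self.partner_pair:
            if pid not in self.individuals:
                raise CoupleScreenError(f"partner {pid!r} not in pedigree")
        for child, (fa, mo) in self.parents.items():
            for parent in (fa, mo):
                if parent is not None and parent not in self.individuals:
                    raise CoupleScreenError(
                        f"parent {parent!r} of {child!r} not in pedigree"
                    )
        self.generation()  # raises on cycles

    def parents_of(self, pid) -> tuple:
        return self.parents.get(pid, (None, None))

    def founders(self) -> list:
        return sorted(
            pid for pid in self.individuals
            if self.parents_of(pid) == (None, None)
        )

    def generation(self) -> dict:
        """Generation depth per individual (founders 0); detects cycles."""
        depth: dict = {}
        in_progress: set = set()

        def visit(pid) -> int:
            if pid in depth:
                return depth[pid]
            if pid in in_progress:
                raise CoupleScreenError(f"pedigree contains a cycle through {pid!r}")
            in_progress.add(pid)
            fa, mo = self.parents_of(pid)
            d = 0 if fa is None and mo is None else 1 + max(
                visit(p) for p in (fa, mo) if p is not None
            )
            in_progress.discard(pid)
            depth[pid] = d
            return d

        for pid in self.individuals:
            visit(pid)
        return depth

    def topological_order(self) -> list:
        depth = self.generation()
        return sorted(self.individuals, key=lambda pid: (depth[pid], str(pid)))


def kinship(pedigree: Pedigree, id_a, id_b) -> float:
    """Kinship coefficient between two pedigree members.

    Standard recursion: founders are mutually unrelated and non-inbred;
    phi(a, a) = (1 + phi(father_a, mother_a)) / 2; for distinct individuals
    the recursion descends through the parents of whichever member sits in
    the later generation (which therefore cannot be an ancestor of the
    other).
    """
    for pid in (id_a, id_b):
        if pid not in pedigree.individuals:
            raise CoupleScreenError(f"individual {pid!r} not in pedigree")
    depth = pedigree.generation()
    cache: dict = {}

    def phi(a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if (depth[a], str(a)) <= (depth[b], str(b)) else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            fa, mo = pedigree.parents_of(a)
            value = 0.5 * (1.0 + phi(fa, mo))
        else:
            # recurse through the later-generation member
            if (depth[a], str(a)) < (depth[b], str(b)):
                a, b = b, a
            fa, mo = pedigree.parents_of(a)
            if fa is None and mo is None:
                value = 0.0  # founder, unrelated to everyone else
            else:
                value = 0.5 * (phi(fa, b) + phi(mo, b))
        cache[key] = value
        return value

    return phi(id_a, id_b)


def pedigree_cgr(pedigree: Pedigree) -> float:
    """Coefficient of genetic relationship of the pedigree's partner pair."""
    a, b = pedigree.partner_pair
    return 2.0 * kinship(pedigree, a, b)


def canonical_pedigree(label: str) -> Pedigree:
    """Construct the canonical pedigree for a relationship label."""
    if label == "uncle_niece":
        parents = {
            "uncle": ("gf", "gm"),
            "parent": ("gf", "gm"),
            "niece": ("parent", "spouse"),
        }
        pair = ("uncle", "niece")
    elif label == "double_first_cousins":
        parents = {
            "a1": ("fa", "ma"), "a2": ("fa", "ma"),
            "b1": ("fb", "mb"), "b2": ("fb", "mb"),
            "c1": ("a1", "b1"), "c2": ("a2", "b2"),
        }
        pair = ("c1", "c2")
    elif label == "first_cousins":
        parents = {
            "s1": ("gf", "gm"), "s2": ("gf", "gm"),
            "c1": ("s1", "x1"), "c2": ("s2", "x2"),
        }
        pair = ("c1", "c2")
    elif label == "half_uncle_niece":
        parents = {
            "uncle": ("f", "m1"),
            "halfsib": ("f", "m2"),
            "niece": ("halfsib", "spouse"),
        }
        pair = ("uncle", "niece")
    elif label == "first_cousins_once_removed":
        parents = {
            "s1": ("gf", "gm"), "s2": ("gf", "gm"),
            "c1": ("s1", "x1"), "c2": ("s2", "x2"),
            "d": ("c2", "y"),
        }
        pair = ("c1", "d")
    elif label == "second_cousins":
        parents = {
            "s1": ("gf", "gm"), "s2": ("gf", "gm"),
            "c1": ("s1", "x1"), "c2": ("s2", "x2"),
            "d1": ("c1", "y1"), "d2": ("c2", "y2"),
        }
        pair = ("d1", "d2")
    elif label == "parent_offspring":
        # not part of the screening vocabulary; used to validate simulations
        parents = {"child": ("parent", "spouse")}
        pair = ("parent", "child")
    else:
        raise CoupleScreenError(
            f"unknown relationship label {label!r}; expected one of "
            + ", ".join(RELATIONSHIP_LABELS)
        )
    individuals = set(parents)
    for fa, mo in parents.values():
        individuals.update(p for p in (fa, mo) if p is not None)
    return Pedigree(individuals=individuals, parents=parents, partner_pair=pair)


def cgr_from_relationship(label: str) -> float:
    """CGR for a relationship label, computed from its canonical pedigree."""
    if label not in RELATIONSHIP_LABELS:
        raise CoupleScreenError(
            f"unknown relationship label {label!r}; expected one of "
            + ", ".join(RELATIONSHIP_LABELS)
        )
    return pedigree_cgr(canonical_pedigree(label))


# --- ARC / PLP mathematics ----------------------------------------------------


def _check_cgr(cgr: float) -> None:
    if not 0.0 < cgr < 1.0:
        raise CoupleScreenError(f"CGR must lie in (0, 1), got {cgr}")


def arc_from_plp(cgr: float, plp: float) -> float:
    """At-risk-couple probability for a given CGR and mean PLP count.

    Each of the ``plp`` carrier variants is assumed to be shared through
    common ancestry independently with probability CGR; the couple is at
    risk when at least one is shared.  ``plp`` may be fractional (a cohort
    mean).
    """
    _check_cgr(cgr)
    if plp < 0:
        raise CoupleScreenError(f"PLP count must be >= 0, got {plp}")
    return 1.0 - (1.0 - cgr) ** plp


def plp_from_arc(cgr: float, arc: float) -> float:
    """Mean PLP count implied by an observed at-risk-couple rate.

    Exact inverse of :func:`arc_from_plp`:
    ``PLP = ln(1 - ARC) / ln(1 - CGR)``.
    """
    _check_cgr(cgr)
    if not 0.0 <= arc < 1.0:
        raise CoupleScreenError(
            f"ARC rate must lie in [0, 1), got {arc} (1 would imply infinite PLPs)"
        )
    return math.log(1.0 - arc) / math.log(1.0 - cgr) + 0.0  # normalize -0.0


@dataclass(frozen=True)
class RiskEstimate:
    """A (CGR, PLP, ARC) triple satisfying ARC = 1 - (1 - CGR)^PLP."""

    cgr: float
    plp: float
    arc: float

    def __post_init__(self) -> None:
        _check_cgr(self.cgr)
        if not math.isclose(self.arc, arc_from_plp(self.cgr, self.plp), abs_tol=1e-9):
            raise CoupleScreenError(
                "inconsistent risk estimate: ARC != 1-(1-CGR)^PLP"
            )


# --- cohort summarization ------------------------------------------------------


@dataclass
class StratumSummary:
    """Positive-couple statistics for one stratum of the cohort."""

    name: str
    cgr: float
    n_couples: int
    n_positive: int
    ci_low: float
    ci_high: float
    plp_estimate: float

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_couples


@dataclass
class CohortSummary:
    """Cohort-level screening statistics.

    ``plp_estimate`` per stratum is the ARC formula inverted at the
    stratum's observed positive fraction — the mean number of shared PLP
    carrier variants implied by the data.  Confidence intervals are exact
    (Clopper-Pearson) binomial intervals at the stated level.
    """

    n_couples: int
    n_positive: int
    n_with_two_or_more: int
    ci_low: float
    ci_high: float
    n_included_variants: int
    n_truncating_variants: int
    by_cgr: list = field(default_factory=list)
    by_relationship: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_couples

    @property
    def truncating_fraction(self) -> Optional[float]:
        if self.n_included_variants == 0:
            return None
        return self.n_truncating_variants / self.n_included_variants

    def to_dict(self) -> dict:
        def stratum(s: StratumSummary) -> dict:
            return {
                "name": s.name,
                "cgr": s.cgr,
                "n_couples": s.n_couples,
                "n_positive": s.n_positive,
                "positive_fraction": s.positive_fraction,
                "ci95_low": s.ci_low,
                "ci95_high": s.ci_high,
                "plp_estimate": s.plp_estimate if math.isfinite(s.plp_estimate) else None,
            }

        return {
            "n_couples": self.n_couples,
            "n_positive": self.n_positive,
            "positive_fraction": self.positive_fraction,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "n_with_two_or_more_plp": self.n_with_two_or_more,
            "n_included_variants": self.n_included_variants,
            "n_truncating_variants": self.n_truncating_variants,
            "truncating_fraction": self.truncating_fraction,
            "by_cgr": [stratum(s) for s in self.by_cgr],
            "by_relationship": [stratum(s) for s in self.by_relationship],
        }


def _binom_ci(count: int, nobs: int, alpha: float) -> tuple[float, float]:
    low, high = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return float(low), float(high)


def summarize_cohort(
    results: Sequence[CoupleScreenResult], alpha: float = 0.05
) -> CohortSummary:
    """Summarize screening results across a cohort of couples.

    Reports overall and per-stratum positive fractions (strata by CGR and,
    when available, by relationship label), the count of couples sharing
    two or more PLP variants, the truncating fraction among retained
    variants, and the formula-inverted PLP estimate per stratum.
    """
    results = list(results)
    if not results:
        raise CoupleScreenError("summarize_cohort needs at least one couple result")

    n = len(results)
    n_pos = sum(1 for r in results if r.positive)
    n_ge2 = sum(1 for r in results if r.n_plp >= 2)
    n_included = sum(r.n_plp for r in results)
    # placeholder entries (counts-only input) carry no verdict to inspect
    n_trunc = sum(
        1
        for r in results
        for rec in r.shared_plp
        if rec is not None and rec.verdict.classification.truncating
    )
    ci_low, ci_high = _binom_ci(n_pos, n, alpha)

    def make_stratum(name: str, cgr: float, members: list) -> StratumSummary:
        k = sum(1 for r in members if r.positive)
        low, high = _binom_ci(k, len(members), alpha)
        # every couple positive -> the point estimate of the PLP mean diverges
        plp_est = math.inf if k == len(members) else plp_from_arc(cgr, k / len(members))
        return StratumSummary(
            name=name,
            cgr=cgr,
            n_couples=len(members),
            n_positive=k,
            ci_low=low,
            ci_high=high,
            plp_estimate=plp_est,
        )

    by_cgr = []
    for cgr in sorted({r.cgr for r in results}, reverse=True):
        members = [r for r in results if r.cgr == cgr]
        by_cgr.append(make_stratum(f"cgr_{cgr:g}", cgr, members))

    by_relationship = []
    labels = sorted({r.relationship for r in results if r.relationship})
    for label in labels:
        members = [r for r in results if r.relationship == label]
        by_relationship.append(make_stratum(label, members[0].cgr, members))

    return CohortSummary(
        n_couples=n,
        n_positive=n_pos,
        n_with_two_or_more=n_ge2,
        ci_low=ci_low,
        ci_high=ci_high,
        n_included_variants=n_included,
        n_truncating_variants=n_trunc,
        by_cgr=by_cgr,
        by_relationship=by_relationship,
        alpha=alpha,
    )
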