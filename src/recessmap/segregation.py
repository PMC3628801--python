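"""Cohort-level validation of candidate variants.

For a fully penetrant recessive variant, every affected individual must be
homozygous for the alternate allele and no unaffected control may be —
"perfect association" is this concordance pattern, not a statistical test.
The module also reports carrier (heterozygote) frequencies per cohort group
and the squared genotype-dosage correlation r² between two loci, the
statistic behind a "perfect linkage disequilibrium" observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, UndefinedLDError

__all__ = ["GenotypeTable", "recessive_concordance", "carrier_frequency",
           "format_percent", "genotype_r2"]

GROUPS = ("cases", "breed_controls", "other_breeds")


@dataclass
class GenotypeTable:
    """Genotype counts for one variant across cohort groups.

    ``counts`` maps group name -> (n_hom_ref, n_het, n_hom_alt); groups not
    present are treated as empty.  ``n_failed`` records genotyping assays
    that produced no call; failed assays never enter any denominator.
    """

    variant_id: str
    counts: dict
    n_failed: int = 0

    def __post_init__(self):
        for group, triple in self.counts.items():
            if len(triple) != 3 or any(c < 0 for c in triple):
                raise DomainError(f"bad genotype counts for group {group!r}: {triple}")

    def group_total(self, group) -> int:
        return sum(self.counts.get(group, (0, 0, 0)))


def recessive_concordance(gt: GenotypeTable):
    """(concordant, n_violations) under a fully penetrant recessive model.

    Concordant iff every case is hom_alt and no control of any group is;
    violations count the offending individuals.
    """
    if not any(gt.group_total(g) for g in gt.counts):
        raise DomainError("empty genotype table")
    case_ref, case_het, _case_alt = gt.counts.get("cases", (0, 0, 0))
    if gt.group_total("cases") == 0:
        raise DomainError("concordance needs at least one case")
    violations = case_ref + case_het
    for group in gt.counts:
        if group != "cases":
            violations += gt.counts[group][2]
    return violations == 0, violations


def carrier_frequency(gt: GenotypeTable, group: str) -> float:
    """Heterozygote fraction among successfully genotyped members of ``group``."""
    total = gt.group_total(group)
    if total == 0:
        raise DomainError(f"group {group!r} is empty")
    return gt.counts[group][1] / total


def format_percent(fraction: float) -> str:
    """One-decimal percent string, e.g. 0.06217 -> '6.2%'."""
    return f"{100.0 * fraction:.1f}%"


def genotype_r2(geno_a, geno_b) -> float:
    """Squared Pearson correlation of 0/1/2 dosages over complete pairs.

    Samples missing (-1) at either locus are dropped.  A locus that is
    monomorphic among the complete pairs leaves LD undefined and raises
    :class:`UndefinedLDError` (r² is not zero in that case — it does not
    exist).
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("dosage vectors must have equal length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise DomainError("need at least two samples with both calls")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLDError("LD undefined: a locus is monomorphic among complete pairs")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
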