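"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle deliberately takes a different computational route from the
library implementation it checks: exact integer arithmetic instead of
floating recurrences, exhaustive enumeration instead of vectorized scans.
"""

import math
from fractions import Fraction


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value by explicit enumeration with exact integers.

    Conditional on allele counts, the probability of h heterozygotes is
    proportional to n! * 2^h / (hom_rare! * h! * hom_common!); the constant
    margin factor cancels in the normalization, so exact integer weights
    suffice.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        weights[h] = (math.factorial(n) * 2**h
                      // (math.factorial(hom_rare) * math.factorial(h)
                          * math.factorial(hom_common)))
    obs = weights[n_het]
    total = sum(weights.values())
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


def shared_runs_bruteforce(ds, min_markers: int = 1):
    """All maximal shared-homozygosity runs by checking every marker window.

    A window [i, j] qualifies iff every marker in it is 'compatible'
    (no case heterozygous, all non-missing case genotypes the same
    homozygote, not all cases missing) and it cannot be extended either way.
    Returns a set of (chromosome, first_index, last_index) triples.
    """
    cases = ds.genotypes[ds.case_mask]
    chroms = ds.chromosomes

    def compatible(m):
        col = [int(g) for g in cases[:, m]]
        seen = {g for g in col if g != -1}
        return bool(seen) and 1 not in seen and len(seen) == 1

    n = ds.n_markers
    runs = set()
    for i in range(n):
        for j in range(i, n):
            if chroms[i] != chroms[j]:
                continue
            window = range(i, j + 1)
            if not all(compatible(m) for m in window):
                continue
            left_open = i > 0 and chroms[i - 1] == chroms[i] and compatible(i - 1)
            right_open = j < n - 1 and chroms[j + 1] == chroms[j] and compatible(j + 1)
            if not left_open and not right_open and j - i + 1 >= min_markers:
                runs.add((chroms[i], i, j))
    return runs
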