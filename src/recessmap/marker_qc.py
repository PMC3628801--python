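"""Marker exclusion rules applied before association testing.

Three rules, mirroring standard array QC for a small case/control cohort:
markers with call rate below 90%, minor allele frequency below 0.05, or a
strong deviation from Hardy-Weinberg equilibrium in the *controls*
(exact-test p < 1e-5) are removed.  Samples with call rate below 90% are
removed first, and all marker statistics are computed on the remaining
samples, so the audit trail is deterministic.

MAF is computed over the non-missing genotypes of all samples (cases and
controls); the HWE term uses controls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .iomodel import GenotypeDataset

__all__ = ["MarkerQCResult", "hwe_exact_test", "qc_filter"]


@dataclass
class MarkerQCResult:
    """Per-marker audit record: the statistics and the verdict."""

    marker_id: str
    call_rate: float
    maf: float
    hwe_p_controls: float
    excluded: bool
    exclusion_reasons: set = field(default_factory=set)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on one genotype-count triple.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (the exact-test convention of PLINK's
    ``--hwe``, no mid-p correction).  Monomorphic input returns 1.0.

    The distribution over heterozygote counts is built by the usual
    two-directional recurrence from the modal count, then normalized.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise DomainError(f"negative genotype counts {counts}")
    n = sum(counts)
    if n == 0:
        raise DomainError("at least one genotyped individual required")
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0

    # modal heterozygote count, matched to the parity of the rare-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1

    probs = {mid: 1.0}
    # downward: het -> het - 2 trades one heterozygote pair for hom_rare + hom_common
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (homr + 1) * (homc + 1))
        het -= 2
        homr += 1
        homc += 1
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het + 2 <= rare:
        probs[het + 2] = probs[het] * 4.0 * homr * homc / ((het + 2) * (het + 1))
        het += 2
        homr -= 1
        homc -= 1

    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:
        raise DomainError(
            f"heterozygote count {n_het} impossible for allele counts of table {counts}")
    # relative slack absorbs recurrence round-off when ranking equal-probability tails
    threshold = obs * (1.0 + 1e-9)
    return min(1.0, sum(p for p in probs.values() if p <= threshold) / total)


def qc_filter(ds: GenotypeDataset,
              call_rate_min: float = 0.90,
              maf_min: float = 0.05,
              hwe_alpha: float = 1e-5,
              sample_call_rate_min: float = 0.90):
    """Apply the three marker-exclusion rules; returns (retained dataset, audit).

    The audit list covers every input marker, so retained + excluded always
    equals the input marker count.  Filtering an already-filtered dataset
    removes nothing (idempotence).
    """
    if not ds.control_mask.any():
        raise ConfigurationError("QC needs at least one control (for the HWE term)")

    called = ds.genotypes != -1
    sample_cr = called.mean(axis=1) if ds.n_markers else np.ones(ds.n_samples)
    keep_samples = sample_cr >= sample_call_rate_min
    ds = ds.subset_samples(keep_samples)
    if not ds.control_mask.any():
        raise ConfigurationError("all controls removed by the sample call-rate filter")

    g = ds.genotypes
    called = g != -1
    n_called = called.sum(axis=0)
    call_rate = n_called / ds.n_samples

    alt_dose = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, alt_dose / (2.0 * n_called), 0.0)
    maf = np.minimum(af, 1.0 - af)

    ctrl = g[ds.control_mask]
    results, keep = [], []
    for m, marker in enumerate(ds.markers):
        col = ctrl[:, m]
        col = col[col != -1]
        if col.size:
            hwe_p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                   int((col == 2).sum()))
        else:
            hwe_p = 1.0
        reasons = set()
        if call_rate[m] < call_rate_min:
            reasons.add("low_call_rate")
        if maf[m] < maf_min:
            reasons.add("low_maf")
        if hwe_p < hwe_alpha:
            reasons.add("hwe_deviation")
        results.append(MarkerQCResult(marker.marker_id, float(call_rate[m]),
                                      float(maf[m]), float(hwe_p),
                                      excluded=bool(reasons),
                                      exclusion_reasons=reasons))
        if not reasons:
            keep.append(m)
    return ds.subset_markers(keep), results
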