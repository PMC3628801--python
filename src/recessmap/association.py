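"""Per-marker allelic association, genomic inflation, max-T permutation.

The raw test is the Pearson chi-square on the 2x2 table of allele counts in
cases vs controls (1 df, no continuity correction — the classic PLINK
``--assoc`` statistic).  Family-wise correction uses the max-T permutation
scheme: phenotype labels are permuted with genotypes fixed, and each
marker's corrected p-value is the fraction of permutations whose
*genome-wide maximum* chi-square reaches that marker's observed value,
with the (1+k)/(1+N) estimator so no p-value is exactly zero.

Stratification is reported through the genomic inflation factor lambda
(median observed chi-square over the chi-square(1) null median) and is
deliberately not corrected beyond that report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .errors import DomainError
from .iomodel import GenotypeDataset

__all__ = [
    "CHI2_NULL_MEDIAN", "Chi2Result", "AssociationResult",
    "allelic_chi2", "run_gwas", "genomic_inflation", "max_t_permutation",
    "manhattan_table", "plot_manhattan",
]

#: Median of the chi-square distribution with 1 df (the null median for lambda).
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


class Chi2Result(NamedTuple):
    chi2: float
    p: float
    degenerate: bool = False


@dataclass
class AssociationResult:
    marker_id: str
    case_alt_count: int
    case_ref_count: int
    control_alt_count: int
    control_ref_count: int
    chi2: float
    p_raw: float
    p_corrected: Optional[float] = None


def allelic_chi2(case_alt: int, case_ref: int, control_alt: int, control_ref: int) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 allele table.

    A zero row or column margin makes the statistic undefined; such tables
    return ``Chi2Result(0.0, 1.0, degenerate=True)`` rather than raising,
    since monomorphic markers can survive QC only in edge cases.
    """
    a, b, c, d = (int(x) for x in (case_alt, case_ref, control_alt, control_ref))
    if min(a, b, c, d) < 0:
        raise DomainError("allele counts must be non-negative")
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return Chi2Result(0.0, 1.0, True)
    chi2 = n * (a * d - b * c) ** 2 / den
    return Chi2Result(float(chi2), float(stats.chi2.sf(chi2, 1)), False)


def _allele_count_arrays(ds: GenotypeDataset):
    """Vectorized per-marker allele counts; missing genotypes drop both alleles."""
    g = ds.genotypes
    dose = np.where(g >= 0, g, 0).astype(np.float64)
    called = (g >= 0).astype(np.float64)
    case, ctrl = ds.case_mask, ds.control_mask
    case_alt = dose[case].sum(axis=0)
    case_tot = 2.0 * called[case].sum(axis=0)
    ctrl_alt = dose[ctrl].sum(axis=0)
    ctrl_tot = 2.0 * called[ctrl].sum(axis=0)
    return case_alt, case_tot - case_alt, ctrl_alt, ctrl_tot - ctrl_alt


def _chi2_2x2(a, b, c, d):
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def run_gwas(ds: GenotypeDataset) -> list:
    """Allelic chi-square scan over every marker, in marker-map order."""
    if ds.n_markers == 0:
        raise DomainError("empty dataset")
    if not ds.case_mask.any() or not ds.control_mask.any():
        raise DomainError("association needs at least one case and one control")
    ca, cr, ta, tr = _allele_count_arrays(ds)
    chi2 = _chi2_2x2(ca, cr, ta, tr)
    degenerate = ((ca + cr == 0) | (ta + tr == 0) | (ca + ta == 0) | (cr + tr == 0))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, 1))
    return [AssociationResult(m.marker_id, int(ca[i]), int(cr[i]), int(ta[i]), int(tr[i]),
                              float(chi2[i]), float(p[i]))
            for i, m in enumerate(ds.markers)]


def genomic_inflation(chi2_values) -> float:
    """Genomic inflation factor: median observed chi2 / chi2_1 null median."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise DomainError("genomic inflation needs at least one statistic")
    return float(np.median(chi2_values) / CHI2_NULL_MEDIAN)


def max_t_permutation(ds: GenotypeDataset, n_perm: int = 100_000, seed: int = 0,
                      chunk: int = 2048) -> np.ndarray:
    """Max-T family-wise corrected p-values from phenotype permutations.

    For marker m: ``p_corrected = (1 + #{perm: max_chi2_perm >= chi2_m}) / (1 + n_perm)``.
    Unknown-phenotype samples are excluded; the permutation stream is a
    deterministic function of (seed, n_perm, n_samples) only, so a fixed
    seed reproduces the output bit for bit regardless of marker content.
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    labelled = ds.case_mask | ds.control_mask
    ds = ds.subset_samples(labelled)
    if not ds.case_mask.any() or not ds.control_mask.any():
        raise DomainError("permutation needs at least one case and one control")

    g = ds.genotypes
    dose = np.where(g >= 0, g, 0).astype(np.float64)
    called2 = 2.0 * (g >= 0).astype(np.float64)
    n_cases = int(ds.case_mask.sum())
    tot_alt = dose.sum(axis=0)
    tot_all = called2.sum(axis=0)

    obs = _observed_chi2(ds.case_mask.astype(np.float64), dose, called2, tot_alt, tot_all)

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, ds.n_samples))
    order = np.argsort(keys, axis=1, kind="stable")
    indicators = np.zeros((n_perm, ds.n_samples), dtype=np.float64)
    np.put_along_axis(indicators, order[:, :n_cases], 1.0, axis=1)

    perm_max = np.empty(n_perm)
    for lo in range(0, n_perm, chunk):
        block = indicators[lo:lo + chunk]
        chi2 = _observed_chi2(block, dose, called2, tot_alt, tot_all)
        perm_max[lo:lo + chunk] = chi2.max(axis=-1)

    perm_sorted = np.sort(perm_max)
    exceed = n_perm - np.searchsorted(perm_sorted, obs - 1e-12, side="left")
    return (1.0 + exceed) / (1.0 + n_perm)


def _observed_chi2(case_indicator, dose, called2, tot_alt, tot_all):
    """chi2 per marker for one or many case-label assignments (rows)."""
    ca = case_indicator @ dose
    ct = case_indicator @ called2
    oa = tot_alt - ca
    ot = tot_all - ct
    return _chi2_2x2(ca, ct - ca, oa, ot - oa)


def attach_corrected(results, p_corrected) -> list:
    for r, p in zip(results, p_corrected):
        r.p_corrected = float(p)
    return results


def manhattan_table(ds: GenotypeDataset, results):
    """Plot-ready table: marker, chromosome, position, counts, chi2, p-values."""
    import pandas as pd
    return pd.DataFrame({
        "marker": [m.marker_id for m in ds.markers],
        "chromosome": ds.chromosomes,
        "position_bp": ds.positions,
        "case_alt": [r.case_alt_count for r in results],
        "case_ref": [r.case_ref_count for r in results],
        "control_alt": [r.control_alt_count for r in results],
        "control_ref": [r.control_ref_count for r in results],
        "chi2": [r.chi2 for r in results],
        "p_raw": [r.p_raw for r in results],
        "p_corrected": [r.p_corrected for r in results],
    })


def plot_manhattan(table, path, title="Allelic association") -> None:
    """Write a simple -log10(p) Manhattan plot to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(9, 3))
    logp = -np.log10(np.clip(table["p_raw"].to_numpy(), 1e-300, 1.0))
    ax.scatter(table["position_bp"] / 1e6, logp, s=4, c="steelblue")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
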