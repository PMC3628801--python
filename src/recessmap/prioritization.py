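"""Variant hard-filter engine and the prioritization cascade.

The hard filters reproduce the three printed rule families used to label
raw variant calls:

(i)   ``HardToValidate``: MQ0 >= 4 and MQ0/DP > 0.1 (the fraction of
      mapping-quality-zero reads is too high to trust the site);
(ii)  ``LowQual``: QUAL < 30.0, or QD < 5.0, or HRun > 5, or SB > 0.00
      (SB exactly 0.00 passes — strict inequality);
(iii) ``SnpCluster``: the variant belongs to a set of >= 3 SNVs spanning
      <= 10 bp (coordinate difference); indels neither count nor get
      flagged.

A record with an empty label set is PASS.  As the original call set did,
labeled records are dropped *before* the cascade, so cascade counts are
over retained calls only.

The cascade itself is a chain of pure intersections over the PASS records:
homozygous-alternate proband genotype, position inside the critical
interval, alternate allele absent from every panel genome (a missing panel
genotype is treated as non-carrying, with the missing count kept for
audit), and a non-synonymous predicted consequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, RecessmapError
from .iomodel import CriticalInterval

__all__ = ["PanelGenotypes", "CascadeReport", "hard_filter_label",
           "flag_snp_clusters", "apply_hard_filters", "run_cascade"]

CASCADE_STEPS = ("filter_pass", "total_homozygous", "in_interval",
                 "absent_from_panel", "nonsynonymous")

_NONSYN = {"missense", "nonsense", "frameshift"}


@dataclass
class PanelGenotypes:
    """Per-variant genotypes of a panel of unrelated genomes.

    ``genotypes`` maps variant id -> int8 array of per-sample codes
    (0/1/2, -1 missing).  A variant with no entry carries no evidence of
    the alternate allele in the panel.
    """

    genotypes: dict
    panel_size: int


@dataclass
class CascadeReport:
    """Ordered step counts plus the surviving variant ids (audit included)."""

    steps: list                       # [(step_name, count), ...]
    surviving_variants: list
    panel_missing: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.steps)


def hard_filter_label(v) -> set:
    """Filter labels for one record from rule families (i) and (ii).

    DP = 0 with MQ0 > 0 yields ``HardToValidate`` (the MQ0/DP ratio is
    treated as +inf; the division is guarded).
    """
    labels = set()
    if v.dp == 0:
        if v.mq0 > 0:
            labels.add("HardToValidate")
    elif v.mq0 >= 4 and v.mq0 / (1.0 * v.dp) > 0.1:
        labels.add("HardToValidate")
    if v.qual < 30.0 or v.qd < 5.0 or v.hrun > 5 or v.sb > 0.00:
        labels.add("LowQual")
    return labels


def flag_snp_clusters(variants, window_bp: int = 10, cluster_size: int = 3) -> list:
    """Per-variant booleans for rule (iii); input must be coordinate-sorted.

    A variant is flagged iff it belongs to any set of >= ``cluster_size``
    SNVs whose first-to-last coordinate difference is <= ``window_bp``.
    """
    keys = [(v.chromosome, v.position_bp) for v in variants]
    if keys != sorted(keys):
        raise DomainError("variants must be sorted by (chromosome, position)")
    flagged = [False] * len(variants)
    # consecutive-window check per chromosome over SNVs only
    snv_idx = [i for i, v in enumerate(variants) if v.is_snv]
    by_chrom = {}
    for i in snv_idx:
        by_chrom.setdefault(variants[i].chromosome, []).append(i)
    for idxs in by_chrom.values():
        pos = [variants[i].position_bp for i in idxs]
        for k in range(len(idxs) - cluster_size + 1):
            if pos[k + cluster_size - 1] - pos[k] <= window_bp:
                for i in idxs[k:k + cluster_size]:
                    flagged[i] = True
    return flagged


def apply_hard_filters(variants, window_bp: int = 10, cluster_size: int = 3) -> list:
    """Populate ``filter_labels`` on every record (rules i-iii); returns the list."""
    order = sorted(range(len(variants)),
                   key=lambda i: (variants[i].chromosome, variants[i].position_bp))
    ordered = [variants[i] for i in order]
    clustered = flag_snp_clusters(ordered, window_bp, cluster_size)
    for v, in_cluster in zip(ordered, clustered):
        v.filter_labels = hard_filter_label(v)
        if in_cluster:
            v.filter_labels.add("SnpCluster")
    return variants


def _panel_state(panel: PanelGenotypes, vid: str):
    """(carries_alt, n_missing) for one variant across the panel."""
    codes = panel.genotypes.get(vid)
    if codes is None:
        return False, 0
    codes = np.asarray(codes)
    return bool((codes > 0).any()), int((codes == -1).sum())


def run_cascade(variants, interval: CriticalInterval, panel: PanelGenotypes,
                consequences: dict) -> CascadeReport:
    """Run the full prioritization cascade and return its audit report.

    ``consequences`` maps variant id -> :class:`ConsequenceCall` for the
    coding variants; variants without an entry are treated as non-coding at
    the final step.  Steps 1-4 are pure intersections, so their order does
    not change the surviving set, only the intermediate counts.
    """
    ordered = sorted(variants, key=lambda v: (v.chromosome, v.position_bp,
                                              v.ref_allele, v.alt_allele))
    if ordered and all(v.chromosome != interval.chromosome for v in ordered):
        raise ConfigurationError(
            f"no variant lies on interval chromosome {interval.chromosome!r} "
            "(naming-convention clash?)")
    apply_hard_filters(ordered)
    passing = [v for v in ordered if not v.filter_labels]
    hom = [v for v in passing if v.proband_genotype == "hom_alt"]
    in_interval = [v for v in hom
                   if v.chromosome == interval.chromosome
                   and interval.start_bp <= v.position_bp <= interval.end_bp]
    absent, panel_missing = [], {}
    for v in in_interval:
        carries, n_missing = _panel_state(panel, v.variant_id)
        if n_missing:
            panel_missing[v.variant_id] = n_missing
        if not carries:
            absent.append(v)
    nonsyn = [v for v in absent
              if v.variant_id in consequences
              and consequences[v.variant_id].effect in _NONSYN]

    counts = [len(passing), len(hom), len(in_interval), len(absent), len(nonsyn)]
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise RecessmapError("cascade counts must be non-increasing")  # unreachable
    return CascadeReport(steps=list(zip(CASCADE_STEPS, counts)),
                         surviving_variants=[v.variant_id for v in nonsyn],
                         panel_missing=panel_missing)
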