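"""Shared-homozygosity mapping across affected individuals.

An autosomal recessive mutation inherited from a recent common founder sits
on a chromosomal segment that all affected individuals carry identical by
descent, so every case is homozygous for the *same* allele across the
segment's markers.  This module scans for maximal runs of such markers
(cases only — controls play no role in the criterion) and delineates the
critical interval as the closed span between the nearest flanking markers
that violate shared homozygosity.

A marker belongs to a run iff no case is heterozygous and all non-missing
case genotypes are the same homozygote.  Missing case genotypes are
compatible with a run (array missingness would otherwise shatter true IBD
segments) but cannot carry one alone: a marker where every case is missing
breaks the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .iomodel import CriticalInterval, GenotypeDataset

__all__ = ["SharedRun", "find_shared_runs", "delineate_interval", "interval_report"]

# per-marker case status codes
_BREAK, _SHARED_REF, _SHARED_ALT = 0, 1, 2


@dataclass
class SharedRun:
    """A maximal run of markers where all cases share one homozygous allele.

    Marker indices are positions in the dataset's (sorted) marker list;
    ``shared_allele_per_marker`` records which allele ('ref' or 'alt') the
    cases share at each marker of the run.
    """

    chromosome: str
    first_marker_index: int
    last_marker_index: int
    n_markers: int
    shared_allele_per_marker: list


def _case_status(ds: GenotypeDataset) -> np.ndarray:
    """Status per marker over cases: shared-ref, shared-alt, or break."""
    cases = ds.genotypes[ds.case_mask]
    any_het = (cases == 1).any(axis=0)
    any_ref = (cases == 0).any(axis=0)
    any_alt = (cases == 2).any(axis=0)
    all_missing = (cases == -1).all(axis=0)
    status = np.full(ds.n_markers, _BREAK, dtype=np.int8)
    ok = ~any_het & ~all_missing & ~(any_ref & any_alt)
    status[ok & any_ref] = _SHARED_REF
    status[ok & any_alt] = _SHARED_ALT
    return status


def _chromosome_blocks(ds: GenotypeDataset):
    """(chromosome, first_index, last_index) for each contiguous chromosome block."""
    blocks, start = [], 0
    chroms = ds.chromosomes
    for i in range(1, ds.n_markers + 1):
        if i == ds.n_markers or chroms[i] != chroms[start]:
            blocks.append((chroms[start], start, i - 1))
            start = i
    return blocks


def find_shared_runs(ds: GenotypeDataset, min_markers: int = 1) -> list:
    """All maximal shared-homozygosity runs per chromosome, cases only."""
    if ds.case_mask.sum() < 1:
        raise DomainError("run finding needs at least one case")
    status = _case_status(ds)
    allele_name = {_SHARED_REF: "ref", _SHARED_ALT: "alt"}
    runs = []
    for chrom, lo, hi in _chromosome_blocks(ds):
        i = lo
        while i <= hi:
            if status[i] == _BREAK:
                i += 1
                continue
            j = i
            while j + 1 <= hi and status[j + 1] != _BREAK:
                j += 1
            if j - i + 1 >= min_markers:
                runs.append(SharedRun(
                    chromosome=chrom, first_marker_index=i, last_marker_index=j,
                    n_markers=j - i + 1,
                    shared_allele_per_marker=[allele_name[s] for s in status[i:j + 1]]))
            i = j + 1
    return runs


def delineate_interval(run: SharedRun, ds: GenotypeDataset) -> CriticalInterval:
    """Critical interval: positions of the nearest discordant flanking markers.

    When the run touches a chromosome end, the terminal marker's own
    position is used and the corresponding truncation flag is set.
    """
    if not (0 <= run.first_marker_index <= run.last_marker_index < ds.n_markers):
        raise DomainError("run indices out of range for this dataset")
    lo = hi = None
    for chrom, blo, bhi in _chromosome_blocks(ds):
        if chrom == run.chromosome and blo <= run.first_marker_index <= bhi:
            lo, hi = blo, bhi
            break
    if lo is None:
        raise DomainError(f"run chromosome {run.chromosome!r} not in dataset")
    positions = ds.positions
    left_trunc = run.first_marker_index == lo
    right_trunc = run.last_marker_index == hi
    start = positions[run.first_marker_index if left_trunc else run.first_marker_index - 1]
    end = positions[run.last_marker_index if right_trunc else run.last_marker_index + 1]
    return CriticalInterval(run.chromosome, int(start), int(end),
                            n_core_markers=run.n_markers,
                            left_truncated=left_trunc, right_truncated=right_trunc)


_REPORT_HEADER = "chromosome\tstart_bp\tend_bp\tlength_mb\tn_core_markers\tflags"


def interval_report(intervals) -> str:
    """Deterministic text table of intervals; lengths in Mb at two decimals."""
    lines = [_REPORT_HEADER]
    for iv in intervals:
        flags = []
        if iv.left_truncated:
            flags.append("left_truncated")
        if iv.right_truncated:
            flags.append("right_truncated")
        lines.append(f"{iv.chromosome}\t{iv.start_bp}\t{iv.end_bp}\t{iv.length_mb} Mb"
                     f"\t{iv.n_core_markers}\t{','.join(flags) or '-'}")
    return "\n".join(lines) + "\n"
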