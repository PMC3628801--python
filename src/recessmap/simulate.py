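"""Synthetic-data generator with planted ground truth.

Emulates the study design of a small autozygosity-mapping experiment:
a handful of affected individuals (default 7) inbred to a common founder,
the same number of controls, dense biallelic markers on one chromosome, an
identical-by-descent homozygous segment of ~3.5 Mb shared by all cases, a
variant table over that segment carrying one causal single-base coding
deletion plus one linked nonsense passenger in perfect LD with it, QC
statistics for the hard-filter engine, a panel of unrelated genomes, and
Table-style validation cohorts for segregation analysis.

Everything is a deterministic function of :class:`SimConfig` (including its
seed): the same configuration yields byte-identical output files.  The
generator always consumes the same random stream regardless of the noise
rates, so a run with ``missing_rate=0, genotype_error_rate=0`` is the exact
noise-free twin of a run with the same seed and noise switched on.

Genotyping errors are modeled as cluster-assignment miscalls: an errored
call is redrawn from the marker's Hardy-Weinberg genotype distribution.
Marker scale (5,000 markers over 80 Mb) keeps the full pipeline with a
10,000-permutation scan in the minutes range on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .consequence import CodingVariant, annotate
from .errors import ConfigurationError, DomainError
from .iomodel import (GenotypeDataset, Marker, TranscriptModel, VariantRecord,
                      write_genotypes, write_panel_vcf, write_transcripts_fasta,
                      write_variants_vcf)
from .prioritization import PanelGenotypes, apply_hard_filters

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_variants",
           "simulate_validation_cohort", "SegregationCohort", "write_bundle",
           "build_synthetic_transcript", "synthetic_cubn_like_transcript",
           "synthetic_mrc1_like_transcript"]


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults are the emulated design."""

    seed: int = 0
    n_cases: int = 7
    n_controls: int = 7
    n_markers: int = 5000
    chrom_length_bp: int = 80_000_000
    chromosome: str = "chr2"
    #: planted IBD segment (start_bp, end_bp); None disables planting
    ibd_segment: Optional[tuple] = (38_000_000, 41_534_378)
    maf_range: tuple = (0.05, 0.5)
    maf_beta: tuple = (1.2, 2.0)
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001
    n_panel: int = 12
    n_interval_variants: int = 60
    n_background_variants: int = 600
    #: fraction of non-planted variants built to fail each hard-filter family
    fail_fraction: float = 0.10
    n_breed_controls: int = 200
    n_other_breeds: int = 357
    assay_failure_rate: float = 0.02
    #: planted heterozygote (carrier) fraction among breed controls
    carrier_frequency: float = 0.062

    def validate(self) -> None:
        for name in ("missing_rate", "genotype_error_rate", "fail_fraction",
                     "assay_failure_rate", "carrier_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.ibd_segment is not None:
            lo, hi = self.ibd_segment
            if not (1 <= lo < hi <= self.chrom_length_bp):
                raise ConfigurationError("ibd_segment must lie within the chromosome")
        if self.n_markers < 2 or self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("need >= 2 markers and >= 1 case and control")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    planted_interval: Optional[tuple]
    segment_marker_indices: np.ndarray
    carrier_status: dict                  # sample id -> copies of the causal allele
    causal_variant_id: Optional[str] = None
    passenger_variant_id: Optional[str] = None


# ---------------------------------------------------------------------------
# synthetic transcripts
# ---------------------------------------------------------------------------

# sense codons used as filler; none is a stop codon
_SAFE_CODONS = ("GCT", "GCC", "GAA", "GAT", "CTG", "CTT", "AAA", "AAG",
                "GGC", "GGA", "TTC", "TTT", "CCA", "CCG", "ACC", "ACT")
_STOP = "TAA"


def build_synthetic_transcript(n_codons: int, fixed: Optional[dict] = None,
                               transcript_id: str = "SYNTH-TX", gene_symbol: str = "",
                               seed: int = 0) -> TranscriptModel:
    """Random CDS of ``n_codons`` sense codons plus a terminal stop.

    ``fixed`` pins specific 1-based codon indices to given codons (codon 1
    is always ATG).  Fillers are drawn from a stop-free codon set, so the
    resulting CDS always satisfies the transcript invariants.
    """
    fixed = dict(fixed or {})
    fixed.setdefault(1, "ATG")
    if n_codons < 2:
        raise DomainError("a transcript needs at least two codons")
    for idx, codon in fixed.items():
        if not 1 <= idx <= n_codons:
            raise DomainError(f"fixed codon index {idx} outside 1..{n_codons}")
        if codon in ("TAA", "TAG", "TGA"):
            raise DomainError("fixed codons may not be stop codons")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(_SAFE_CODONS, size=n_codons))
    for idx, codon in fixed.items():
        codons[idx - 1] = codon
    tm = TranscriptModel(transcript_id, "".join(codons) + _STOP, gene_symbol=gene_symbol)
    tm.validate()
    return tm


def synthetic_cubn_like_transcript():
    """Synthetic 3,620-codon CUBN-like stand-in plus its c.8392delC variant.

    This is a constructed stand-in, not the real cubilin mRNA: only the
    features the frameshift computation touches are pinned — codon 2798 is
    CAG (Q), the local context c.8392..8401 reads CAGAGCTTGA so deleting
    the C at c.8392 shifts the frame to AGA-GCT-TGA (p.Q2798Rfs*3), and the
    wildtype ORF is 3,620 amino acids, placing the mutant stop 821 codons
    early.
    """
    fixed = {2798: "CAG", 2799: "AGC", 2800: "TTG", 2801: "AAA"}
    tm = build_synthetic_transcript(3620, fixed, "CUBN-SYNTH-1", "CUBN", seed=8392)
    assert tm.cds[8391:8401] == "CAGAGCTTGA"
    return tm, CodingVariant("CUBN-SYNTH-1", 8392, "C", "")


def synthetic_mrc1_like_transcript():
    """Synthetic 1,456-codon MRC1-like stand-in plus its c.2143C>T nonsense SNV.

    Codon 715 is pinned to CGA (R) so the C>T at c.2143 creates TGA
    (p.R715*), truncating slightly more than half of the protein.
    """
    tm = build_synthetic_transcript(1456, {715: "CGA"}, "MRC1-SYNTH-1", "MRC1", seed=2143)
    return tm, CodingVariant("MRC1-SYNTH-1", 2143, "C", "T")


# ---------------------------------------------------------------------------
# cohort genotypes
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def _unique_sorted_positions(rng, n, lo, hi):
    seen = np.array([], dtype=np.int64)
    while seen.size < n:
        draw = rng.integers(lo, hi + 1, size=n + 200)
        seen = np.unique(np.concatenate([seen, draw]))
    subset = rng.permutation(seen.size)[:n]
    return np.sort(seen[subset])


def simulate_cohort(cfg: SimConfig):
    """Generate the SNP-array dataset; returns (GenotypeDataset, GroundTruth).

    Markers are placed uniformly at random and sorted.  Controls (and cases
    outside the planted segment) are drawn under Hardy-Weinberg equilibrium
    at each marker's alternate-allele frequency; inside the segment every
    case is homozygous for one fixed founder haplotype.  Genotype error and
    missingness are applied last, in that order.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    n, S = cfg.n_markers, cfg.n_cases + cfg.n_controls

    pos = _unique_sorted_positions(rng, n, 1, cfg.chrom_length_bp)
    lo_f, hi_f = cfg.maf_range
    q = lo_f + (hi_f - lo_f) * rng.beta(*cfg.maf_beta, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)

    geno = rng.binomial(2, q, size=(S, n)).astype(np.int8)
    founder_is_alt = rng.random(n) < q

    if cfg.ibd_segment is not None:
        seg_lo, seg_hi = cfg.ibd_segment
        seg_mask = (pos >= seg_lo) & (pos <= seg_hi)
        if seg_mask.sum() < 10:
            raise ConfigurationError(
                f"planted segment contains only {int(seg_mask.sum())} markers (< 10) "
                "at this marker density")
        geno[:cfg.n_cases, seg_mask] = np.where(founder_is_alt[seg_mask], 2, 0).astype(np.int8)
    else:
        seg_mask = np.zeros(n, dtype=bool)

    # noise draws are made unconditionally so a zero-rate run is the exact twin
    u_err = rng.random((S, n))
    redraw = rng.binomial(2, q, size=(S, n)).astype(np.int8)
    geno = np.where(u_err < cfg.genotype_error_rate, redraw, geno)
    u_miss = rng.random((S, n))
    geno = np.where(u_miss < cfg.missing_rate, np.int8(-1), geno)

    markers = [Marker(f"m{i + 1:05d}", cfg.chromosome, int(pos[i]),
                      *_ALLELE_PAIRS[pair_idx[i]]) for i in range(n)]
    samples = ([f"case_{i + 1:02d}" for i in range(cfg.n_cases)]
               + [f"control_{i + 1:02d}" for i in range(cfg.n_controls)])
    phenotypes = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    ds = GenotypeDataset(markers, samples, phenotypes, geno)

    carrier = {s: (2 if p == "case" else 0) for s, p in zip(samples, phenotypes)}
    truth = GroundTruth(planted_interval=cfg.ibd_segment,
                        segment_marker_indices=np.flatnonzero(seg_mask),
                        carrier_status=carrier)
    return ds, truth


# ---------------------------------------------------------------------------
# variant table, panel and transcripts
# ---------------------------------------------------------------------------

def simulate_variants(cfg: SimConfig, truth: GroundTruth):
    """Variant substrate for the cascade.

    Returns ``(variants, panel, transcripts, coding_variants, consequences)``:
    the proband's variant records with QC annotations, panel genotypes over
    the same variants, the synthetic transcripts, the per-variant coding
    variants, and the consequence calls keyed by variant id.

    Construction mirrors the mapped scenario: the causal single-base
    deletion and the nonsense passenger are homozygous, clean, inside the
    planted interval and absent from the panel; a couple of synonymous
    variants are also panel-absent; every other variant is carried by at
    least one panel genome.  ``fail_fraction`` of the non-planted variants
    are built to fail each hard-filter family.
    """
    if truth.planted_interval is None:
        raise ConfigurationError("variant simulation needs a planted interval")
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    seg_lo, seg_hi = truth.planted_interval

    # positions on coarse grids: no accidental SNP clusters, no duplicates
    iv_grid = np.arange(seg_lo + 50, seg_hi - 50, 50)
    iv_pos = np.sort(rng.choice(iv_grid, size=cfg.n_interval_variants, replace=False))
    bg_grid = np.concatenate([np.arange(1000, seg_lo - 1000, 200),
                              np.arange(seg_hi + 1000, cfg.chrom_length_bp - 1000, 200)])
    bg_pos = np.sort(rng.choice(bg_grid, size=cfg.n_background_variants, replace=False))

    special = rng.choice(cfg.n_interval_variants, size=2, replace=False)
    causal_pos, passenger_pos = int(iv_pos[special[0]]), int(iv_pos[special[1]])

    variants, is_planted = [], []
    for p in iv_pos:
        p = int(p)
        if p == causal_pos:
            v = VariantRecord(cfg.chromosome, p, "TC", "T", "hom_alt")
        elif p == passenger_pos:
            v = VariantRecord(cfg.chromosome, p, "G", "A", "hom_alt")
        else:
            v = _random_variant(rng, cfg.chromosome, p, indel_rate=0.1)
        variants.append(v)
        is_planted.append(p in (causal_pos, passenger_pos))
    for p in bg_pos:
        variants.append(_random_variant(rng, cfg.chromosome, int(p), indel_rate=0.1))
        is_planted.append(False)

    _draw_qc_stats(rng, variants)
    extra = _plant_filter_failures(rng, cfg, variants, is_planted)
    variants += extra
    is_planted += [False] * len(extra)

    order = np.argsort([v.position_bp for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    is_planted = [is_planted[i] for i in order]

    causal_id = next(v.variant_id for v in variants if v.position_bp == causal_pos)
    passenger_id = next(v.variant_id for v in variants if v.position_bp == passenger_pos)
    truth.causal_variant_id = causal_id
    truth.passenger_variant_id = passenger_id

    transcripts, coding_variants, consequences = _assign_consequences(
        rng, cfg, variants, seg_lo, seg_hi, causal_id, passenger_id)

    panel = _draw_panel(rng, cfg, variants, consequences, seg_lo, seg_hi,
                        causal_id, passenger_id)
    return variants, panel, transcripts, coding_variants, consequences


def _random_variant(rng, chrom, pos, indel_rate):
    gt = str(rng.choice(["hom_ref", "het", "hom_alt", "missing"],
                        p=[0.15, 0.30, 0.50, 0.05]))
    if rng.random() < indel_rate:
        anchor = str(rng.choice(list("ACGT")))
        deleted = str(rng.choice(list("ACGT")))
        return VariantRecord(chrom, pos, anchor + deleted, anchor, gt)
    ref, alt = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
    return VariantRecord(chrom, pos, ref, alt, gt)


def _draw_qc_stats(rng, variants):
    """Comfortably passing QC statistics for every record."""
    for v in variants:
        v.qual = float(rng.uniform(60, 2000))
        v.qd = float(rng.uniform(6.0, 25.0))
        v.dp = int(rng.poisson(12) + 4)
        v.mq0 = int(rng.integers(0, 2))       # 0 or 1: passes (i) at any depth >= 4
        v.hrun = int(rng.integers(0, 4))
        v.sb = float(rng.uniform(-30.0, -0.5))


def _plant_filter_failures(rng, cfg, variants, is_planted):
    """Push a configured fraction of non-planted records across each threshold.

    Returns extra SNV records fabricated to complete SNP-cluster triples.
    """
    candidates = [i for i, planted in enumerate(is_planted) if not planted]
    k = int(round(cfg.fail_fraction * len(candidates)))
    if k == 0:
        return []
    htv = rng.choice(candidates, size=k, replace=False)
    for i in htv:
        v = variants[i]
        v.mq0 = int(rng.integers(4, 15))
        v.dp = int(rng.integers(1, 9 * v.mq0))      # MQ0/DP > 0.1 guaranteed < 10x
    lowq = rng.choice(candidates, size=k, replace=False)
    for i in lowq:
        v = variants[i]
        clause = rng.integers(0, 4)
        if clause == 0:
            v.qual = float(rng.uniform(5.0, 29.9))
        elif clause == 1:
            v.qd = float(rng.uniform(0.5, 4.9))
        elif clause == 2:
            v.hrun = int(rng.integers(6, 12))
        else:
            v.sb = float(rng.uniform(0.01, 3.0))

    # clusters: pick non-planted SNVs and fabricate two neighbours within 10 bp
    snv_bg = [i for i in candidates if variants[i].is_snv]
    n_clusters = max(0, int(round(cfg.fail_fraction * len(snv_bg) / 6)))
    extra = []
    if n_clusters:
        seeds = rng.choice(snv_bg, size=n_clusters, replace=False)
        for i in seeds:
            base = variants[i]
            for offset in (3, 7):
                ref, alt = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
                nb = VariantRecord(base.chromosome, base.position_bp + offset, ref, alt,
                                   str(rng.choice(["het", "hom_alt"])))
                extra.append(nb)
        _draw_qc_stats(rng, extra)
    return extra


def _assign_consequences(rng, cfg, variants, seg_lo, seg_hi, causal_id, passenger_id):
    transcripts, coding_variants, consequences = {}, {}, {}
    cubn, cubn_cv = synthetic_cubn_like_transcript()
    mrc1, mrc1_cv = synthetic_mrc1_like_transcript()
    transcripts[cubn.transcript_id] = cubn
    transcripts[mrc1.transcript_id] = mrc1
    coding_variants[causal_id] = cubn_cv
    coding_variants[passenger_id] = mrc1_cv
    consequences[causal_id] = annotate(cubn, cubn_cv)
    consequences[passenger_id] = annotate(mrc1, mrc1_cv)

    for v in variants:
        vid = v.variant_id
        if vid in consequences or not (seg_lo <= v.position_bp <= seg_hi) or not v.is_snv:
            continue
        tx_seed = int(rng.integers(0, 2**31))
        if rng.random() < 0.65:   # synonymous: CTG -> CTA at codon 50, third base
            tm = build_synthetic_transcript(120, {50: "CTG"}, f"TX-{v.position_bp}",
                                            "BG", seed=tx_seed)
            cv = CodingVariant(tm.transcript_id, 150, "G", "A")
        else:                     # missense: GAA -> CAA (E50Q), first base
            tm = build_synthetic_transcript(120, {50: "GAA"}, f"TX-{v.position_bp}",
                                            "BG", seed=tx_seed)
            cv = CodingVariant(tm.transcript_id, 148, "G", "C")
        transcripts[tm.transcript_id] = tm
        coding_variants[vid] = cv
        consequences[vid] = annotate(tm, cv)
    return transcripts, coding_variants, consequences


def _draw_panel(rng, cfg, variants, consequences, seg_lo, seg_hi,
                causal_id, passenger_id):
    """Panel genotypes: everything is carried somewhere except the planted
    pair and two synonymous in-interval survivors."""
    apply_hard_filters(variants)
    absent = {causal_id, passenger_id}
    synonymous_clean = [v.variant_id for v in variants
                        if seg_lo <= v.position_bp <= seg_hi
                        and v.proband_genotype == "hom_alt" and not v.filter_labels
                        and consequences.get(v.variant_id) is not None
                        and consequences[v.variant_id].effect == "synonymous"]
    absent.update(synonymous_clean[:2])
    for v in variants:           # labels are recomputed downstream anyway
        v.filter_labels = set()

    genotypes = {}
    for v in variants:
        vid = v.variant_id
        if vid in absent:
            genotypes[vid] = np.zeros(cfg.n_panel, dtype=np.int8)
            continue
        q = rng.uniform(0.05, 0.5)
        codes = rng.binomial(2, q, size=cfg.n_panel).astype(np.int8)
        miss = rng.random(cfg.n_panel) < 0.01
        codes[miss] = -1
        if not (codes > 0).any():
            j = int(rng.integers(0, cfg.n_panel))
            codes[j] = 1
        genotypes[vid] = codes
    return PanelGenotypes(genotypes=genotypes, panel_size=cfg.n_panel)


# ---------------------------------------------------------------------------
# validation cohorts (segregation substrate)
# ---------------------------------------------------------------------------

@dataclass
class SegregationCohort:
    """Genotyping-cohort results for the candidate variants.

    ``tables`` maps variant id -> :class:`~recessmap.segregation.GenotypeTable`;
    ``dosages`` maps variant id -> per-dog 0/1/2 dosage vector (-1 for a
    failed assay) across cases + breed controls + other breeds, in that
    order.  The causal and passenger variants share one carrier vector:
    perfect linkage disequilibrium by construction.
    """

    tables: dict
    dosages: dict
    group_slices: dict = field(default_factory=dict)


def simulate_validation_cohort(cfg: SimConfig, truth: GroundTruth) -> SegregationCohort:
    from .segregation import GenotypeTable
    if truth.causal_variant_id is None or truth.passenger_variant_id is None:
        raise ConfigurationError("run simulate_variants first (variant ids unset)")
    rng = np.random.default_rng([cfg.seed, 2])

    cases = np.full(cfg.n_cases, 2, dtype=np.int8)
    bc = np.zeros(cfg.n_breed_controls, dtype=np.int8)
    bc[rng.random(cfg.n_breed_controls) < cfg.carrier_frequency] = 1
    bc[rng.random(cfg.n_breed_controls) < cfg.assay_failure_rate] = -1
    ob = np.zeros(cfg.n_other_breeds, dtype=np.int8)
    ob[rng.random(cfg.n_other_breeds) < cfg.assay_failure_rate] = -1

    dosage = np.concatenate([cases, bc, ob])
    n_failed = int((dosage == -1).sum())

    def triple(arr):
        return (int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum()))

    tables, dosages = {}, {}
    for vid in (truth.causal_variant_id, truth.passenger_variant_id):
        tables[vid] = GenotypeTable(vid, {"cases": triple(cases),
                                          "breed_controls": triple(bc),
                                          "other_breeds": triple(ob)},
                                    n_failed=n_failed)
        dosages[vid] = dosage.copy()
    slices = {"cases": slice(0, cfg.n_cases),
              "breed_controls": slice(cfg.n_cases, cfg.n_cases + cfg.n_breed_controls),
              "other_breeds": slice(cfg.n_cases + cfg.n_breed_controls, dosage.size)}
    return SegregationCohort(tables=tables, dosages=dosages, group_slices=slices)


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

def write_bundle(cfg: SimConfig, out_dir) -> dict:
    """Generate everything and write the pipeline's input files.

    Writes PED/MAP, proband VCF, panel VCF, transcript FASTA and a
    ground-truth JSON; returns the path map.  Deterministic given ``cfg``.
    """
    from .consequence import write_coding_variants_tsv
    os.makedirs(out_dir, exist_ok=True)
    ds, truth = simulate_cohort(cfg)
    variants, panel, transcripts, coding_variants, _cons = simulate_variants(cfg, truth)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("ped", "cohort.ped"), ("map", "cohort.map"),
        ("proband_vcf", "proband.vcf"), ("panel_vcf", "panel.vcf"),
        ("transcripts", "transcripts.fasta"), ("coding_variants", "coding_variants.tsv"),
        ("truth", "truth.json")]}
    write_genotypes(ds, paths["ped"], paths["map"])
    write_variants_vcf(variants, paths["proband_vcf"])
    write_panel_vcf(variants, panel, paths["panel_vcf"])
    write_transcripts_fasta(transcripts, paths["transcripts"])
    write_coding_variants_tsv(coding_variants, paths["coding_variants"])
    with open(paths["truth"], "w") as fh:
        json.dump({"planted_interval": list(truth.planted_interval),
                   "causal_variant_id": truth.causal_variant_id,
                   "passenger_variant_id": truth.passenger_variant_id,
                   "carrier_status": truth.carrier_status,
                   "n_segment_markers": int(truth.segment_marker_indices.size),
                   "config": dataclasses.asdict(cfg)},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
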