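"""Core domain types and readers/writers for the standard file formats.

Genotypes are coded as integers throughout the package:

====  =========  ==============================================
code  name       meaning
====  =========  ==============================================
0     hom_ref    homozygous for the reference allele
1     het        heterozygous
2     hom_alt    homozygous for the alternate (risk) allele
-1    missing    no call
====  =========  ==============================================

By convention the alternate allele of an array marker is the minor allele
among the *controls* (falling back to the global minor allele when the
controls are monomorphic), so that ``hom_alt`` is the natural risk genotype
for a recessive trait without peeking at case genotypes.

All internal coordinates are 1-based closed (VCF/HGVS convention); the
0-based half-open BED convention is applied only at the file boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DomainError, FormatError

__all__ = [
    "HOM_REF", "HET", "HOM_ALT", "MISSING",
    "Marker", "GenotypeDataset", "VariantRecord", "TranscriptModel",
    "CriticalInterval", "ConsequenceCall",
    "read_genotypes", "write_genotypes", "read_variants", "read_panel_vcf",
    "write_variants_vcf", "write_panel_vcf",
    "write_interval_bed", "read_interval_bed",
    "read_transcripts_fasta", "write_transcripts_fasta",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_DNA = set("ACGT")
_PHENO_FROM_PED = {"1": "control", "2": "case"}
_PHENO_TO_PED = {"control": "1", "case": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """One array marker: identifier, genomic location and its two alleles."""

    marker_id: str
    chromosome: str
    position_bp: int
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self):
        if self.position_bp < 1:
            raise DomainError(f"marker {self.marker_id}: position must be >= 1")


def _marker_order(markers):
    return sorted(range(len(markers)),
                  key=lambda i: (markers[i].chromosome, markers[i].position_bp,
                                 markers[i].marker_id))


@dataclass
class GenotypeDataset:
    """SNP-array genotypes for a case/control cohort.

    ``genotypes`` is an ``(n_samples, n_markers)`` int8 matrix in the coding
    above.  Markers are kept sorted by (chromosome, position), stable by
    marker id on position ties; marker ids must be unique.
    """

    markers: list
    samples: list
    phenotypes: list
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise DomainError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers")
        if len(self.phenotypes) != len(self.samples):
            raise DomainError("one phenotype label per sample required")
        bad = set(self.phenotypes) - {"case", "control", "unknown"}
        if bad:
            raise DomainError(f"unknown phenotype labels: {sorted(bad)}")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise DomainError("duplicate marker ids")
        order = _marker_order(self.markers)
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[i] for i in order]
            self.genotypes = self.genotypes[:, order]

    # -- convenience views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p == "case" for p in self.phenotypes])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([p == "control" for p in self.phenotypes])

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)

    @property
    def chromosomes(self) -> list:
        return [m.chromosome for m in self.markers]

    def subset_markers(self, indices) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeDataset([self.markers[i] for i in indices],
                               list(self.samples), list(self.phenotypes),
                               self.genotypes[:, indices])

    def subset_samples(self, mask) -> "GenotypeDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeDataset(list(self.markers),
                               [self.samples[i] for i in idx],
                               [self.phenotypes[i] for i in idx],
                               self.genotypes[idx, :])


@dataclass
class VariantRecord:
    """One called variant with the QC annotations the hard-filter engine reads.

    Missing QC annotations are represented by neutral sentinels that cannot
    trigger any filter (``qd`` large, ``mq0=0``, ``dp=1``, ``hrun=0``,
    ``sb=-1``): absence of evidence must not fail a record.
    """

    chromosome: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    proband_genotype: str = "missing"       # hom_ref | het | hom_alt | missing
    qual: float = 1.0e6
    qd: float = 1.0e6
    mq0: int = 0
    dp: int = 1
    hrun: int = 0
    sb: float = -1.0
    filter_labels: set = field(default_factory=set)

    def __post_init__(self):
        for allele, name in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if not allele or set(allele) - _DNA:
                raise DomainError(
                    f"{name} allele {allele!r} at {self.chromosome}:{self.position_bp} "
                    "must be a non-empty ACGT string")
        if self.mq0 < 0 or self.dp < 0 or self.hrun < 0:
            raise DomainError("MQ0, DP and HRun must be non-negative")
        if self.proband_genotype not in {"hom_ref", "het", "hom_alt", "missing"}:
            raise DomainError(f"bad genotype {self.proband_genotype!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position_bp}:{self.ref_allele}>{self.alt_allele}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref_allele) > len(self.alt_allele)


@dataclass
class TranscriptModel:
    """A coding sequence (CDS) with an identifier; substrate of consequence calls.

    The CDS must start with ATG, have length divisible by three, and
    translate to exactly one terminal stop with no internal stop.
    ``cds_to_genome`` optionally maps c. positions to genomic coordinates
    (chromosome, strand, ordered exon segments); the cascade may instead
    supply variants directly in c. coordinates.
    """

    transcript_id: str
    cds: str
    gene_symbol: str = ""
    cds_to_genome: object = None

    def validate(self) -> None:
        from .consequence import translate  # local import: avoid module cycle
        if len(self.cds) % 3:
            raise DomainError(f"{self.transcript_id}: CDS length not divisible by 3")
        if not self.cds.startswith("ATG"):
            raise DomainError(f"{self.transcript_id}: CDS does not start with ATG")
        protein = translate(self.cds)
        if 3 * (len(protein) + 1) != len(self.cds):
            raise DomainError(
                f"{self.transcript_id}: CDS must contain exactly one terminal stop")


@dataclass
class CriticalInterval:
    """Closed genomic interval bounded by the flanking discordant markers."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_core_markers: int = 0
    left_truncated: bool = False
    right_truncated: bool = False

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise DomainError("interval start must be < end")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> str:
        """Length in Mb, rounded half-up to two decimals (e.g. '3.53')."""
        mb = Decimal(self.length_bp).scaleb(-6)
        return str(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConsequenceCall:
    """Predicted coding consequence of one variant on one transcript.

    ORF lengths count amino acids excluding the stop codon on both the
    wildtype and mutant side, so truncation differences do not depend on the
    stop-counting convention.
    """

    hgvs_c: str
    hgvs_p: str
    effect: str          # synonymous | missense | nonsense | frameshift | other
    wt_orf_codons: int
    mut_orf_codons: int
    no_downstream_stop: bool = False


# ---------------------------------------------------------------------------
# PED/MAP (PLINK text dialect)
# ---------------------------------------------------------------------------

def _read_map(map_path):
    markers = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, marker_id, _cm, pos = fields
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(f"{map_path}:{lineno}: bad position {pos!r}") from None
            markers.append((marker_id, chrom, pos))
    return markers


def read_genotypes(ped_path, map_path) -> GenotypeDataset:
    """Load a PLINK-text PED/MAP pair into a :class:`GenotypeDataset`.

    PED rows carry six leading columns (family, individual, father, mother,
    sex, phenotype) followed by two allele columns per marker; allele ``0``
    means no call.  Phenotype column 1 maps to ``control``, 2 to ``case``,
    anything else to ``unknown``.  The alternate allele is recoded as the
    minor allele among controls (global minor on control-monomorphic
    markers; lexicographically greater allele on exact ties).
    """
    map_entries = _read_map(map_path)
    n_markers = len(map_entries)
    samples, phenotypes, allele_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} MAP markers, got {len(fields)}")
            samples.append(fields[1])
            phenotypes.append(_PHENO_FROM_PED.get(fields[5], "unknown"))
            alleles = fields[6:]
            for a in alleles:
                if a not in _DNA and a != "0":
                    raise FormatError(
                        f"{ped_path}:{lineno}: allele symbol {a!r} outside A,C,G,T,0")
            allele_rows.append(alleles)

    n_samples = len(samples)
    geno = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    controls = [i for i, p in enumerate(phenotypes) if p == "control"]
    markers = []
    for m, (marker_id, chrom, pos) in enumerate(map_entries):
        pairs = [(allele_rows[s][2 * m], allele_rows[s][2 * m + 1]) for s in range(n_samples)]
        observed = sorted({a for pair in pairs for a in pair if a != "0"})
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: marker {marker_id} has {len(observed)} alleles {observed}")
        if not observed:
            observed = ["A"]
        ref, alt = _choose_ref_alt(pairs, observed, controls)
        for s, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            geno[s, m] = (a1 == alt) + (a2 == alt)
        markers.append(Marker(marker_id, chrom, pos, ref, alt))
    return GenotypeDataset(markers, samples, phenotypes, geno)


def _choose_ref_alt(pairs, observed, controls):
    """Pick (ref, alt): alt is the minor allele in controls, falling back to
    the global minor when controls are monomorphic/uninformative; exact ties
    make the lexicographically greater allele the alt."""
    if len(observed) == 1:
        ref = observed[0]
        alt = next(a for a in "ACGT" if a != ref)
        return ref, alt
    a, b = observed

    def counts(sample_idx):
        c = {a: 0, b: 0}
        for s in sample_idx:
            for al in pairs[s]:
                if al != "0":
                    c[al] += 1
        return c

    def pick(c):
        if c[a] == 0 or c[b] == 0:   # monomorphic here: no information
            return None
        if c[a] < c[b]:
            return b, a
        if c[b] < c[a]:
            return a, b
        return "tie"

    choice = pick(counts(controls)) if controls else None
    if choice in (None, "tie"):
        fallback = pick(counts(range(len(pairs))))
        choice = fallback if fallback not in (None, "tie") else "tie"
    if choice == "tie":
        choice = (min(a, b), max(a, b))
    return choice


def write_genotypes(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset back to the PLINK-text PED/MAP dialect."""
    with open(map_path, "w") as fh:
        for m in ds.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    with open(ped_path, "w") as fh:
        for s in range(ds.n_samples):
            row = [ds.samples[s], ds.samples[s], "0", "0", "0",
                   _PHENO_TO_PED[ds.phenotypes[s]]]
            for m, marker in enumerate(ds.markers):
                g = ds.genotypes[s, m]
                if g == MISSING:
                    row += ["0", "0"]
                elif g == HOM_REF:
                    row += [marker.ref_allele, marker.ref_allele]
                elif g == HET:
                    row += [marker.ref_allele, marker.alt_allele]
                else:
                    row += [marker.alt_allele, marker.alt_allele]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_SENTINELS = {"QD": 1.0e6, "MQ0": 0, "DP": 1, "HRun": 0, "SB": -1.0}


def _dosage_to_code(allele_pair, alt_index):
    a1, a2 = allele_pair[0], allele_pair[1]
    if a1 < 0 or a2 < 0:
        return MISSING
    return int(a1 == alt_index) + int(a2 == alt_index)


_GT_NAME = {MISSING: "missing", 0: "hom_ref", 1: "het", 2: "hom_alt"}


def read_variants(vcf_path) -> list:
    """Read a (single-proband) VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per ALT allele; input
    order is preserved.  INFO keys QD/MQ0/DP/HRun/SB are read when present
    and replaced by filter-neutral sentinels when absent.
    """
    import cyvcf2
    if not os.path.exists(vcf_path):
        raise FormatError(f"{vcf_path}: no such file")
    records = []
    try:
        vcf = cyvcf2.VCF(str(vcf_path))
        for v in vcf:
            info = {k: v.INFO.get(k, _INFO_SENTINELS[k]) for k in _INFO_SENTINELS}
            if v.genotypes:
                pair = v.genotypes[0]
            else:
                pair = [-1, -1, False]
            for alt_i, alt in enumerate(v.ALT, start=1):
                dose = _dosage_to_code(pair, alt_i)
                records.append(VariantRecord(
                    chromosome=v.CHROM,
                    position_bp=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    proband_genotype=_GT_NAME[dose],
                    qual=float(v.QUAL) if v.QUAL is not None else 1.0e6,
                    qd=float(info["QD"]),
                    mq0=int(info["MQ0"]),
                    dp=int(info["DP"]),
                    hrun=int(info["HRun"]),
                    sb=float(info["SB"]),
                ))
        vcf.close()
    except (OSError, ValueError, RuntimeError) as exc:
        raise FormatError(f"{vcf_path}: malformed VCF ({exc})") from exc
    return records


def read_panel_vcf(vcf_path):
    """Read a multi-sample panel VCF into a :class:`~recessmap.prioritization.PanelGenotypes`."""
    import cyvcf2

    from .prioritization import PanelGenotypes
    genotypes = {}
    try:
        vcf = cyvcf2.VCF(str(vcf_path))
        n = len(vcf.samples)
        for v in vcf:
            for alt_i, alt in enumerate(v.ALT, start=1):
                vid = f"{v.CHROM}:{v.POS}:{v.REF}>{alt}"
                codes = np.array([_dosage_to_code(pair, alt_i) for pair in v.genotypes],
                                 dtype=np.int8)
                genotypes[vid] = codes
        vcf.close()
    except (OSError, ValueError, RuntimeError) as exc:
        raise FormatError(f"{vcf_path}: malformed VCF ({exc})") from exc
    return PanelGenotypes(genotypes=genotypes, panel_size=n)


_GT_FIELD = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
_CODE_FIELD = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality zero">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=HRun,Number=1,Type=Integer,Description="Homopolymer run length">
##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _vcf_line(v: VariantRecord, gt_fields):
    info = (f"QD={v.qd:.2f};MQ0={v.mq0};DP={v.dp};HRun={v.hrun};SB={v.sb:.2f}")
    cols = [v.chromosome, str(v.position_bp), ".", v.ref_allele, v.alt_allele,
            f"{v.qual:.2f}", ".", info, "GT"] + gt_fields
    return "\t".join(cols) + "\n"


def write_variants_vcf(records, path, sample_name="proband") -> None:
    """Write proband variant records as a minimal single-sample VCF 4.2."""
    records = sorted(records, key=lambda v: (v.chromosome, v.position_bp, v.ref_allele, v.alt_allele))
    chrom = records[0].chromosome if records else "chr1"
    length = max((v.position_bp for v in records), default=1) + 1000
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=length, samples=sample_name))
        for v in records:
            fh.write(_vcf_line(v, [_GT_FIELD[v.proband_genotype]]))


def write_panel_vcf(records, panel, path, sample_prefix="panel") -> None:
    """Write panel genotypes for the given variants as a multi-sample VCF.

    Variants with no entry in ``panel`` are written as all hom_ref (the
    panel carries no copy of the alternate allele).
    """
    records = sorted(records, key=lambda v: (v.chromosome, v.position_bp, v.ref_allele, v.alt_allele))
    chrom = records[0].chromosome if records else "chr1"
    length = max((v.position_bp for v in records), default=1) + 1000
    names = "\t".join(f"{sample_prefix}{i + 1:02d}" for i in range(panel.panel_size))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=length, samples=names))
        for v in records:
            codes = panel.genotypes.get(v.variant_id)
            if codes is None:
                codes = [0] * panel.panel_size
            fh.write(_vcf_line(v, [_CODE_FIELD[int(c)] for c in codes]))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_interval_bed(interval: CriticalInterval, path) -> None:
    """Write one interval as a BED line (0-based half-open at the boundary)."""
    with open(path, "w") as fh:
        fh.write(f"{interval.chromosome}\t{interval.start_bp - 1}\t{interval.end_bp}"
                 f"\tcritical_interval\t{interval.n_core_markers}\n")


def read_interval_bed(path) -> CriticalInterval:
    """Read the first BED line back into 1-based closed bounds."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad BED coordinates") from None
            n_core = int(fields[4]) if len(fields) > 4 else 0
            return CriticalInterval(fields[0], start0 + 1, end, n_core_markers=n_core)
    raise FormatError(f"{path}: no interval line found")


# ---------------------------------------------------------------------------
# FASTA (transcript CDS)
# ---------------------------------------------------------------------------

def read_transcripts_fasta(path, validate=True) -> dict:
    """Read CDS records; returns ``{transcript_id: TranscriptModel}``.

    The gene symbol is taken from a ``gene=SYMBOL`` token in the description
    when present.
    """
    from Bio import SeqIO
    transcripts = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        tm = TranscriptModel(rec.id, str(rec.seq).upper(), gene_symbol=gene)
        if validate:
            tm.validate()
        transcripts[rec.id] = tm
    return transcripts


def write_transcripts_fasta(transcripts, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(tm.cds), id=tm.transcript_id, description=f"gene={tm.gene_symbol}")
            for tm in (transcripts.values() if isinstance(transcripts, dict) else transcripts)]
    seqio_write(recs, str(path), "fasta")
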