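"""Coding-consequence annotation from a CDS and a variant in c. coordinates.

Produces HGVS c./p. strings (single-letter amino-acid style, e.g.
``p.Q2798Rfs*3``), an effect class, and the wildtype/mutant open reading
frame lengths in amino acids (stop codon excluded on both sides, so
truncation deltas do not depend on the stop convention).

Frameshift naming follows the standard HGVS reading: the first codon whose
amino acid changes is position 1 of the frameshifted peptide and the new
stop sits at position ``n`` of ``fs*n`` — so ``p.Q2798Rfs*3`` puts the stop
in codon 2800 and leaves a 2,799-residue mutant protein.  Deletions and
insertions are 3'-normalized within repeated sequence before naming.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Data import CodonTable

from .errors import DomainError
from .iomodel import ConsequenceCall, TranscriptModel

__all__ = ["CodingVariant", "translate", "annotate", "truncation_summary",
           "apply_coding_variant", "normalize_3prime",
           "read_coding_variants_tsv", "write_coding_variants_tsv"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_DNA = set("ACGT")


@dataclass(frozen=True)
class CodingVariant:
    """A variant in CDS (c.) coordinates: 1-based position, ref and alt strings.

    ``ref`` is empty for a pure insertion (inserted before ``c_position``),
    ``alt`` is empty for a pure deletion; they may not both be empty.
    """

    transcript_id: str
    c_position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.c_position < 1:
            raise DomainError("c. position must be >= 1")
        if not self.ref and not self.alt:
            raise DomainError("ref and alt may not both be empty")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if set(allele) - _DNA:
                raise DomainError(f"{name} allele {allele!r} outside ACGT")


def translate(cds: str) -> str:
    """Standard-code translation, stopping at the first stop codon.

    The stop is not included in the returned protein; a trailing partial
    codon is ignored.  Characters outside ACGT raise :class:`DomainError`.
    """
    protein, _ = _translate_orf(cds)
    return protein


def _translate_orf(seq: str):
    if set(seq) - _DNA:
        raise DomainError("sequence contains characters outside ACGT")
    if len(seq) < 3:
        raise DomainError("need at least one full codon")
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in _STOPS:
            return "".join(aas), True
        aas.append(_CODON_TO_AA[codon])
    return "".join(aas), False


def normalize_3prime(cds: str, cv: CodingVariant) -> CodingVariant:
    """Shift a pure deletion/insertion to its 3'-most equivalent position.

    HGVS names the 3'-most copy of a deleted/duplicated unit inside
    repeated sequence; SNVs and delins are returned unchanged.
    """
    if cv.ref and cv.alt:
        return cv
    pos0 = cv.c_position - 1
    if cv.alt == "":            # deletion of cds[pos0 : pos0+len(ref)]
        seg_len = len(cv.ref)
        while pos0 + seg_len < len(cds) and cds[pos0] == cds[pos0 + seg_len]:
            pos0 += 1
        return replace(cv, c_position=pos0 + 1, ref=cds[pos0:pos0 + seg_len])
    alt = cv.alt                # insertion before pos0+1
    while pos0 < len(cds) and alt[0] == cds[pos0]:
        alt = alt[1:] + alt[0]
        pos0 += 1
    return replace(cv, c_position=pos0 + 1, alt=alt)


def apply_coding_variant(cds: str, cv: CodingVariant) -> str:
    """Return the mutant CDS sequence (no normalization applied here)."""
    pos0 = cv.c_position - 1
    return cds[:pos0] + cv.alt + cds[pos0 + len(cv.ref):]


def _hgvs_c(cv: CodingVariant) -> str:
    p = cv.c_position
    if cv.ref and cv.alt:
        if len(cv.ref) == 1 and len(cv.alt) == 1:
            return f"c.{p}{cv.ref}>{cv.alt}"
        end = p + len(cv.ref) - 1
        return f"c.{p}_{end}delins{cv.alt}"
    if cv.alt == "":
        if len(cv.ref) == 1:
            return f"c.{p}del{cv.ref}"
        return f"c.{p}_{p + len(cv.ref) - 1}del{cv.ref}"
    return f"c.{p - 1}_{p}ins{cv.alt}"


def annotate(tm: TranscriptModel, cv: CodingVariant) -> ConsequenceCall:
    """Predict the coding consequence of ``cv`` on transcript ``tm``.

    In-frame SNV comparison yields synonymous/missense/nonsense; a
    length change that is not a multiple of three yields a frameshift
    ``p.<wt><pos><new>fs*<n>`` call.  In-frame indels are classified as
    ``other`` (their precise HGVS naming is out of scope here).
    """
    cds = tm.cds
    if cv.c_position > len(cds):
        raise DomainError(
            f"c.{cv.c_position} lies 3' of the CDS of {tm.transcript_id} ({len(cds)} nt)")
    pos0 = cv.c_position - 1
    if cv.ref and cds[pos0:pos0 + len(cv.ref)] != cv.ref:
        raise DomainError(
            f"ref allele {cv.ref!r} does not match CDS "
            f"{cds[pos0:pos0 + len(cv.ref)]!r} at c.{cv.c_position}")

    wt_prot, _ = _translate_orf(cds)
    wt_stop_start = 3 * len(wt_prot)          # 0-based CDS offset of the stop codon
    if pos0 >= wt_stop_start + 3:
        raise DomainError(f"c.{cv.c_position} lies 3' of the stop codon")

    if cv.ref == cv.alt:                      # identity "variant"
        return ConsequenceCall(_hgvs_c(cv), "p.(=)", "synonymous",
                               len(wt_prot), len(wt_prot))

    cv = normalize_3prime(cds, cv)
    pos0 = cv.c_position - 1
    mut = apply_coding_variant(cds, cv)
    mut_prot, mut_has_stop = _translate_orf(mut)
    delta = len(cv.alt) - len(cv.ref)

    if delta == 0 and len(cv.ref) == 1:
        return _annotate_snv(cv, wt_prot, wt_stop_start, pos0, mut)
    if delta % 3 == 0:
        effect = "synonymous" if mut_prot == wt_prot and mut_has_stop else "other"
        return ConsequenceCall(_hgvs_c(cv), "p.?", effect, len(wt_prot), len(mut_prot),
                               no_downstream_stop=not mut_has_stop)
    return _annotate_frameshift(cv, wt_prot, mut_prot, mut_has_stop)


def _annotate_snv(cv, wt_prot, wt_stop_start, pos0, mut):
    codon_idx = pos0 // 3
    codon_start = 3 * codon_idx
    mut_codon = mut[codon_start:codon_start + 3]
    if codon_idx == len(wt_prot):             # variant inside the stop codon
        if mut_codon in _STOPS:
            return ConsequenceCall(_hgvs_c(cv), f"p.*{codon_idx + 1}=", "synonymous",
                                   len(wt_prot), len(wt_prot))
        mut_prot, has_stop = _translate_orf(mut)   # stop lost: read-through
        return ConsequenceCall(_hgvs_c(cv), f"p.*{codon_idx + 1}{_CODON_TO_AA[mut_codon]}ext*?",
                               "other", len(wt_prot), len(mut_prot),
                               no_downstream_stop=not has_stop)
    wt_aa = wt_prot[codon_idx]
    pos1 = codon_idx + 1
    if mut_codon in _STOPS:
        return ConsequenceCall(_hgvs_c(cv), f"p.{wt_aa}{pos1}*", "nonsense",
                               len(wt_prot), codon_idx)
    mut_aa = _CODON_TO_AA[mut_codon]
    if mut_aa == wt_aa:
        return ConsequenceCall(_hgvs_c(cv), f"p.{wt_aa}{pos1}=", "synonymous",
                               len(wt_prot), len(wt_prot))
    return ConsequenceCall(_hgvs_c(cv), f"p.{wt_aa}{pos1}{mut_aa}", "missense",
                           len(wt_prot), len(wt_prot))


def _annotate_frameshift(cv, wt_prot, mut_prot, mut_has_stop):
    hgvs_c = _hgvs_c(cv)
    # first codon whose amino acid changes
    i = 0
    limit = min(len(wt_prot), len(mut_prot))
    while i < limit and wt_prot[i] == mut_prot[i]:
        i += 1
    pos1 = i + 1
    if i >= len(mut_prot):
        # mutant terminates where the wildtype still has a residue
        wt_aa = wt_prot[i] if i < len(wt_prot) else "*"
        return ConsequenceCall(hgvs_c, f"p.{wt_aa}{pos1}*", "frameshift",
                               len(wt_prot), len(mut_prot))
    wt_aa = wt_prot[i] if i < len(wt_prot) else "*"
    new_aa = mut_prot[i]
    if not mut_has_stop:
        return ConsequenceCall(hgvs_c, f"p.{wt_aa}{pos1}{new_aa}fs*?", "frameshift",
                               len(wt_prot), len(mut_prot), no_downstream_stop=True)
    n_stop = len(mut_prot) + 2 - pos1         # stop codon counted from pos1 as 1
    return ConsequenceCall(hgvs_c, f"p.{wt_aa}{pos1}{new_aa}fs*{n_stop}", "frameshift",
                           len(wt_prot), len(mut_prot))


def write_coding_variants_tsv(coding_variants: dict, path) -> None:
    """Write a variant-id -> c.-coordinate mapping as a 5-column TSV.

    Columns: variant_id, transcript, c_position, ref, alt; '-' stands for
    an empty allele (pure insertion/deletion).
    """
    with open(path, "w") as fh:
        fh.write("variant_id\ttranscript\tc_position\tref\talt\n")
        for vid in sorted(coding_variants):
            cv = coding_variants[vid]
            fh.write(f"{vid}\t{cv.transcript_id}\t{cv.c_position}"
                     f"\t{cv.ref or '-'}\t{cv.alt or '-'}\n")


def read_coding_variants_tsv(path) -> dict:
    """Inverse of :func:`write_coding_variants_tsv`."""
    from .errors import FormatError
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("variant_id\t"):
            raise FormatError(f"{path}:1: missing coding-variant header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            vid, tx, c_pos, ref, alt = fields
            out[vid] = CodingVariant(tx, int(c_pos),
                                     "" if ref == "-" else ref,
                                     "" if alt == "-" else alt)
    return out


def truncation_summary(call: ConsequenceCall):
    """(codons lost, fraction of the wildtype ORF lost) for a truncating call."""
    if call.mut_orf_codons >= call.wt_orf_codons:
        raise DomainError("truncation summary requires a truncating consequence")
    delta = call.wt_orf_codons - call.mut_orf_codons
    return delta, delta / call.wt_orf_codons
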