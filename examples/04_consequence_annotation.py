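"""HGVS coding-consequence annotation: frameshift, nonsense, missense.

Annotates the package's synthetic CUBN-like and MRC1-like transcripts and
shows the open-reading-frame arithmetic behind a frameshift call.
"""

from recessmap.consequence import annotate, truncation_summary
from recessmap.simulate import (synthetic_cubn_like_transcript,
                                synthetic_mrc1_like_transcript)

for builder in (synthetic_cubn_like_transcript, synthetic_mrc1_like_transcript):
    tm, cv = builder()
    call = annotate(tm, cv)
    delta, fraction = truncation_summary(call)
    print(f"{tm.gene_symbol}: {call.hgvs_c} -> {call.hgvs_p} ({call.effect})")
    print(f"  wildtype ORF {call.wt_orf_codons} aa, mutant ORF {call.mut_orf_codons} aa"
          f" -> {delta} codons shorter ({100 * fraction:.0f}% of the protein lost)")
# p.Q2798Rfs*3 reads: glutamine 2798 becomes arginine, the frame shifts,
# and the new stop sits at the 3rd frameshifted codon — so the mutant
# protein ends at residue 2,799.
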