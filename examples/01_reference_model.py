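"""Build mature and precursor tRNAs from an annotated gene record.

The mature sequence is the spliced body plus the post-transcriptionally
added 3' CCA; the precursor keeps the intron and the 5' leader / 3'
trailer flanks.  Fragment coordinates downstream are 1-based on these
sequences.
"""

from tsrnakit import TRNAGeneRecord, build_mature, build_precursor

body = ("GGCTCGTTGGTCTAGGGGTATGATTCTCGCTTA"   # acceptor stem + D-arm (33 nt)
        "AGG"                                  # anticodon, positions 34-36
        "GTGCGAGAGGTCCCGGGTTCAAATCCCGGACGAGCC")  # 72-nt body in total
gene = TRNAGeneRecord.from_parts(
    gene_id="Pro-AGG-1", body_seq=body, anticodon_start=34,
    leader_seq="ACGTTTGAGCCTGGGAGTTT", trailer_seq="CTTTTTTTGCCGGGAATGCTG")

mature = build_mature(gene)
precursor = build_precursor(gene)

print(f"gene            {gene.gene_id} (family {gene.family})")
print(f"mature length   {mature.length} nt, ends ...{mature.seq[-6:]}")
print(f"anticodon span  {mature.anticodon_span}")
print(f"precursor       {precursor.length} nt, body at {precursor.body_span}")

# The mature length (spliced body + CCA) fixes which fragment coordinates
# reach the 3' terminus: here a fragment 59..76 would be a 3'-terminal
# 18-mer, the hallmark of a tRF-3a.
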