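"""Structural isoform distinguishability.

An isoform is indistinguishable when every fragment it can generate maps,
by genomic exon-footprint, onto some other isoform of its gene.  Such
isoforms carry no unique read evidence, which is exactly where a
ChIP-derived prior earns its keep.
"""

from peakprior import Transcript, distinguishability

gene = [
    Transcript("A1", "geneA", "chr1", "+", ((0, 300), (500, 800))),
    Transcript("A2", "geneA", "chr1", "+", ((0, 300),)),  # contained in A1
]

for rep in distinguishability(gene, fragment_length=100):
    status = "indistinguishable" if rep.indistinguishable else "distinguishable"
    print(
        f"{rep.transcript_id}: {status} "
        f"({rep.witness_fragments} fragments unique to it)"
    )
# A2 lies entirely inside A1's first exon, so all of its fragments also
# align to A1.  A1's junction-spanning and second-exon fragments are its
# witnesses: unique evidence no other isoform can absorb.
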