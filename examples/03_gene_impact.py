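"""Breakpoint-based gene-impact annotation.

The same gene receives different impact categories depending on how an
SV intersects its canonical transcript: an exon-removing deletion is a
potential loss of function (pLoF), a gene-spanning duplication a copy
gain (CG), an intragenic exon duplication an IED, and so on.
"""

import ppsv
from ppsv.model import GeneModel, SVRecord, SVType

gene = GeneModel(
    gene_id="TSG1", gene_name="TSG1", canonical_transcript="TSG1.t1",
    chrom="chr2", strand="+", tx_start=100_000, tx_end=130_000,
    exons=[(100_000 + k * 4_000, 100_000 + k * 4_000 + 199) for k in range(8)],
    cds_start=100_100, cds_end=128_100, canonical=True,
)

cases = [
    ("exon-removing DEL", SVRecord("d", "chr2", 103_800, "chr2", 108_500, SVType.DEL)),
    ("intronic DEL", SVRecord("i", "chr2", 104_300, "chr2", 107_800, SVType.DEL)),
    ("gene-spanning DUP", SVRecord("g", "chr2", 95_000, "chr2", 135_000, SVType.DUP)),
    ("intragenic exon DUP", SVRecord("e", "chr2", 110_500, "chr2", 114_500, SVType.DUP)),
    ("gene-disrupting INV", SVRecord("v", "chr2", 105_000, "chr2", 150_000,
                                     SVType.INV, strands=("+", "+"))),
    ("translocation in CDS", SVRecord("t", "chr2", 110_100, "chr9", 5_000, SVType.TRA)),
]

annotator = ppsv.GenomeAnnotator([gene])
for label, sv in cases:
    anns = annotator.annotate(sv)
    cats = ", ".join(f"{a.gene_id}:{a.category}" for a in anns if a.gene_id)
    print(f"{label:24s} -> {cats or 'intergenic'}")

# pLoF, CG and IED are the gene-disruptive categories: they inactivate a
# gene or raise its dosage, and only they continue into pathogenicity
# classification.
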