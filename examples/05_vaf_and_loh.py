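"""Variant allele fractions and tumour loss of heterozygosity.

A heterozygous germline deletion halves read depth inside the SV, so the
depth-based VAF is ~0.5; a heterozygous tandem duplication raises region
depth 1.5-fold, giving (1.5-1)/1.5 = 0.33.  Tumour LOH is read from
allele-specific copy number: minor allele zero means LOH, subtyped by
the major copy number.
"""

import numpy as np

import ppsv
from ppsv.allelics import BreakpointEvidence, CNSegment, DepthTrack
from ppsv.model import SVRecord, SVType

rng = np.random.default_rng(0)

sv_del = SVRecord("del1", "chr2", 214_768_022, "chr2", 214_772_899, SVType.DEL)
depths = np.concatenate([
    rng.poisson(46, 10_000),            # left flank
    rng.poisson(23, 4_878),             # one allele lost inside the DEL
    rng.poisson(46, 10_000),            # right flank
]).astype(float)
track = DepthTrack("chr2", sv_del.pos1 - 10_000, depths)
est = ppsv.vaf_depth(sv_del, track)
print(f"DEL depth VAF: {est.vaf:.2f} (heterozygous expectation 0.50)")

sv_inv = SVRecord("inv1", "chr6", 108_167_886, "chr6", 110_172_775, SVType.INV,
                  strands=("+", "+"))
tracks = [DepthTrack("chr6", pos - 200, rng.poisson(34, 401).astype(float))
          for _, pos in sv_inv.breakpoints()]
est = ppsv.vaf_breakpoint(sv_inv, BreakpointEvidence("inv1", 10, 4), tracks)
print(f"INV breakpoint VAF: {est.vaf:.2f} (14 altered reads over ~34x depth)")

segments = [CNSegment("chr18", 62_000_000, 62_400_000, major_cn=1, minor_cn=0)]
call = ppsv.classify_loh("PIGN", ("chr18", 62_152_637, 62_157_701), segments)
print(f"tumour LOH for PIGN: {call.status} "
      f"(major={call.major_cn}, minor={call.minor_cn})")
hits = ppsv.second_hit(["PIGN", "SLC3A1"], [("SLC3A1", "CNL")])
print(f"somatic second hits: {hits}")
# LOH_CNL = hemizygous loss of the wild-type allele: together with the
# germline deletion this is biallelic inactivation.
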