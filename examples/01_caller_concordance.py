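"""Dual-caller concordance: build the high-confidence SV set for one sample.

Two callers report slightly different breakpoints for the same events;
calls agree when SV type matches, both breakpoints are within 200 bases,
and at least one call is PASS.
"""

import ppsv
from ppsv.model import SVRecord, SVType

caller_a = [
    SVRecord("a1", "chr1", 10_000, "chr1", 15_000, SVType.DEL),
    SVRecord("a2", "chr2", 40_000, "chr2", 48_000, SVType.DUP),
    SVRecord("a3", "chr3", 5_000, "chr3", 9_000, SVType.DEL),   # private to A
]
caller_b = [
    SVRecord("b1", "chr1", 10_150, "chr1", 14_930, SVType.DEL),  # jittered a1
    SVRecord("b2", "chr2", 40_010, "chr2", 48_005, SVType.DUP, filter="MinQUAL"),
    SVRecord("b3", "chr1", 10_300, "chr1", 15_400, SVType.DEL),  # too far from a1
]

result = ppsv.match_calls(caller_a, caller_b, tolerance=200)
print(f"concordant: {len(result.concordant)}  "
      f"only A: {len(result.only_a)}  only B: {len(result.only_b)}")
for id_a, id_b, d1, d2 in result.match_log:
    print(f"  {id_a} ~ {id_b}  breakpoint distances {d1} and {d2} bases")

# The two concordant calls (a1~b1 and a2~b2) form the sample's
# high-confidence set; merged records keep caller A's coordinates, which
# the downstream genotyper consumes.  a2 matches even though b2 is
# non-PASS because a single PASS call suffices.
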