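"""Cohort genotype QC and ancestry-stratified allele frequencies.

A deletion carried heterozygously by two of 113 African patients (and no
Europeans) has an African MAF of 2/226 = 0.009 — a rare variant.
"""

import ppsv
from ppsv.genotypes import CohortSite, Genotype
from ppsv.model import SVRecord, SVType

samples = [f"AFR{i:03d}" for i in range(113)] + [f"EUR{i:03d}" for i in range(57)]
ancestry = {s: s[:3] for s in samples}
gts = ["0/1"] * 2 + ["0/0"] * 111 + ["0/0"] * 57

site = CohortSite(
    sv=SVRecord("del1", "chr8", 17_418_976, "chr8", 17_544_122, SVType.DEL),
    samples=samples,
    genotypes=[Genotype(gt, ft="PASS", gq=60) for gt in gts],
    ancestry=ancestry,
)

kept = ppsv.site_filter([site], min_pass_ratio=0.5)
for s in kept:
    ppsv.mask_genotypes(s)
kept = ppsv.missingness_filter(kept, max_missing=0.2)
rec = ppsv.compute_frequencies(kept[0])

print(f"African MAF : {rec.maf_afr:.6f} (rounds to {round(rec.maf_afr, 3)})")
print(f"European MAF: {rec.maf_eur:.6f}")
print(f"carriers    : {rec.carriers_afr} AFR / {rec.carriers_eur} EUR")
print(f"rarity      : AFR={rec.rarity_afr}, EUR={rec.rarity_eur}")
# MAF <= 1% in both ancestries, so this SV passes the rarity gate of the
# pathogenic-candidate cascade.
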