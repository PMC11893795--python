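"""Carrier statistics of the packaged reference prostate cancer cohort.

The package ships the curated final candidate table of a 170-patient
cohort (113 African, 57 European men).  This script recomputes the
headline carrier percentages, the aggressive-disease fractions and the
mean heterozygous VAF from those tables.
"""

from ppsv.datasets import PP_CLASSES, REFERENCE_COHORT_SIZES, load_carriers
from ppsv.report import aggressive_fraction, carrier_fraction, mean_vaf

carriers = load_carriers()

for ancestry in ("AFR", "EUR"):
    frac = carrier_fraction(carriers, REFERENCE_COHORT_SIZES, ancestry, PP_CLASSES)
    print(f"{ancestry} patients with a PP-SV: "
          f"{frac.count}/{frac.denominator} = {frac.percent}%")

clinvar = carrier_fraction(carriers, REFERENCE_COHORT_SIZES, "AFR", {"PP_SV_clinvar"})
predicted = carrier_fraction(carriers, REFERENCE_COHORT_SIZES, "AFR", {"PP_SV"})
print(f"AFR archive-validated carriers : {clinvar.count}/113 = {clinvar.percent}%")
print(f"AFR predicted-PP-SV carriers   : {predicted.count}/113 = {predicted.percent}%")

caution = aggressive_fraction(carriers, {"cautionary"})
print(f"cautionary carriers with aggressive disease (ISUP GG>=3): "
      f"{caution.count}/{caution.denominator} = {caution.percent}%")
print(f"mean carrier VAF: {mean_vaf(carriers)}% "
      f"(heterozygous germline expectation ~50%)")
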