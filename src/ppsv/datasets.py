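"""Packaged reference tables from a published 170-patient prostate
cancer cohort (113 men of African, 57 of European ancestry).

Two small curated tables ship with the package:

* ``candidate_svs.tsv`` — the 19 final candidate potentially pathogenic
  SVs (15 PP-SVs, of which 3 carry pathogenic / likely-pathogenic
  clinical-archive labels, and 4 cautionary calls) with breakpoint
  coordinates, SV type, gene impact and ancestry-stratified MAFs.
* ``carriers.tsv`` — one row per carrier patient and SV, with ancestry,
  age, PSA, ISUP group grade, VAF, tumour LOH status and somatic
  second-hit events.

They serve as worked examples and as desk-scale ground truth for the
cohort-summary statistics (carrier percentages, aggressive-disease
fractions, mean heterozygous VAF).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Ancestry cohort sizes of the reference cohort.
REFERENCE_COHORT_SIZES = {"AFR": 113, "EUR": 57}

#: Classes treated as "potentially pathogenic" in carrier summaries.
PP_CLASSES = frozenset({"PP_SV", "PP_SV_clinvar"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("ppsv.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_candidate_svs() -> pd.DataFrame:
    """The final candidate SV table (one row per SV)."""
    return _read("candidate_svs.tsv")


def load_carriers() -> pd.DataFrame:
    """The carrier table (one row per patient and SV)."""
    return _read("carriers.tsv")
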