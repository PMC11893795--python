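# Methods

## Scope and data model

`ppsv` prioritizes rare germline structural variants (SVs) in a case
cohort for potential pathogenicity. It consumes caller outputs and
annotation resources — it does not align reads, discover SVs, re-genotype
graphs, or run the four impact predictors; their outputs are inputs.

An SV is a single record with two breakpoint anchors. VCF coordinates
(1-based inclusive) are kept at the I/O boundary; all interval
arithmetic uses 0-based half-open intervals produced by the model's
helper methods, so the conversion exists in exactly one place.
Breakends are resolved to simple types before anything else: reciprocal
mate pairs on different chromosomes become TRA; on one chromosome the
junction orientation decides — `++`/`--` (inverted) → INV, `+-` → a
deletion-type junction, `-+` → a duplication-type junction. This is
standard breakend orientation semantics; only the inverted and
inter-chromosomal cases are canonical in the literature, the other two
rows of the table are this package's completion of it. Orphan (
asymmetric) breakends are retained and flagged, never classified.

## Caller concordance

Two calls agree when SV type matches, chromosome anchors match (TRA
anchors compared orderlessly), both breakpoint distances are ≤ 200
bases, and at least one call is PASS. "At least one PASS" is the
default reading; `require_both_pass=True` gives the stricter variant.
Matching is one-to-one and greedy by minimal summed breakpoint
distance (ties: smaller first-breakpoint position, then identifiers — a
total order, so results are independent of input order). One-to-one
matching is deliberate: the concordant set doubles as a deduplicated
site list for cohort genotyping, and the merged record keeps the
caller-A coordinates because that dialect feeds the genotyper.
Equivalence with an all-pairs brute-force oracle is asserted in the test
suite on random call sets up to 200 records, including tie cases.

## Genotype QC and allele frequencies

The cascade is: site filter (site FILTER PASS and passing-genotype
fraction ≥ 0.5, recomputed from FT — or GQ ≥ 20 where FT is absent —
when the site annotation is missing; the recomputed denominator is all
samples), genotype masking (FT ≠ PASS → missing; at breakend-derived
INV/TRA sites, which carry no FT, GQ < 20 → missing), missingness
filter (> 20 % missing in *either* ancestry removes the site), and
removal of AF = 100 % sites (fixed differences of the reference, not
cohort variation). The cascade is idempotent; applying it twice equals
once.

Frequencies use non-missing alleles only, per ancestry and overall.
MAF = min(AF, 1 − AF). Rarity classes: rare MAF ≤ 1 %, low-frequency
(1 %, 5 %], common > 5 %; a `rare_boundary_exclusive` flag reproduces
reports that label exactly 1 % as low-frequency. The rarity gate of the
final cascade demands MAF ≤ 1 % in **both** ancestries (equivalently,
the maximum of the two ancestry MAFs ≤ 1 %). All-male cohorts motivate
haploid counting on chrX/chrY (one allele per sample); the chromosome
set is a parameter. Reported MAFs round to three decimals. Per-genome
SV count comparisons between ancestries use the two-sided Wilcoxon
rank-sum (Mann–Whitney U) test from scipy.

## Gene impact

Annotation is per (SV, gene) against the canonical transcript —
selected by flag, else longest CDS, then longest transcript, then
smallest transcript id — with a first-match-wins decision table:

* **DEL**: removes coding-exon sequence → pLoF; exonic but non-coding
  sequence only → UTR; otherwise intronic.
* **DUP**: contains the whole gene → CG (copy gain); both breakpoints
  inside the gene and fully contains ≥ 1 exon → IED; both breakpoints
  inside exons → pLoF; both inside the gene otherwise →
  partial-exon DUP; one breakpoint inside → partial-gene DUP.
* **INV**: contains the gene with both breakpoints outside →
  whole-gene INV; a breakpoint inside the gene with the inverted
  segment touching an exon → pLoF; intronic only → intronic.
* **TRA**: a breakpoint inside the coding span severs the transcript →
  pLoF (including intronic breakpoints between coding exons — a
  translocation separates them regardless; `tra_intronic_is_plof=False`
  restricts pLoF to exonic breakpoints); inside the transcript but
  outside the CDS → UTR.
* Promoter-only overlap → promoter; nothing at all → intergenic.

Promoters are 1-kb windows upstream of the TSS on the transcribed
strand. Enhancer disruption requires a *breakpoint inside* an enhancer
linked to the gene (spanning an enhancer is not disruption of it). SVs
spanning > 1 Mb annotate only genes (and promoters) containing a
breakpoint — short-read callers resolve large spans poorly, so interior
containment is unreliable. A TRA whose breakpoints fall in two
different genes additionally carries a fusion label ordered by
breakpoint position.

Only pLoF, CG and IED count as gene-disruptive downstream: they act by
gene inactivation or dosage increase; the remaining categories have no
clear direct coding effect and are reported but not classified.
Insertions are carried through genotyping and frequency stages but only
receive containment-level annotation. The decision table is validated
against a per-base membership oracle on toy genomes in the test suite.

## Known-SV matching

An archive entry matches when type and chromosome anchors agree and
both breakpoint distances are ≤ 200 bases; the minimal summed distance
wins, ties preferring clinically interpreted entries, then the smallest
entry id (total order ⇒ shuffle-stable). The entry's reported allele
frequencies are summarized as their maximum across studies and
populations — a conservative rarity requirement — and known SVs with a
maximum reported AF ≥ 1 % are excluded from the candidate cascade
(inclusive threshold: a variant already archived at exactly 1 % is not
rare). Conflicting clinical interpretations within one entry are a
known open point; the shipped reduction takes the most pathogenic label
only if no benign label exists, else "uncertain", and is marked as a
placeholder.

## Pathogenicity cascade

Tool thresholds: StrVCTVRE ≥ 0.37, CADD-SV ≥ 10, POSTRE ≥ 0.8,
PhenoSV ≥ 0.5. Each tool covers only some SV types (StrVCTVRE: exonic
DEL/DUP; CADD-SV: DEL/DUP/INS; POSTRE: DEL/DUP/INV/TRA; PhenoSV: all),
so absent scores are structural. Candidacy requires ≥ 2 *absolute*
passes — a TRA scoreable by only two tools must pass both. The
alternative 2-of-scored reading is available (`min_pass_relative`).
Requiring all four tools is far stricter and is shown on synthetic
panels to collapse the candidate set.

Cancer relevance: the union of the SV's disrupted genes (functionally
impacted plus breakpoint-disrupted) must cover ≥ 2 of the three
collections; the union reading lets a fusion of two single-collection
genes qualify, and a single-gene reading is available by flag.

The rule engine runs on candidates passing the cancer and rarity gates
(and the known-frequency exclusion), first match wins, and every call
records the rule that fired:

* **R1** — pathogenic / likely-pathogenic archive match → PP_SV with an
  override flag; whether a non-cancer clinical phenotype makes the call
  plausible for the cohort's cancer is a judgement left to review.
* **R2** (loss-type: pLoF by DEL/INV/TRA) — oncogene loss with no
  tumour suppressor involved → unlikely; all tumour suppressors →
  PP_SV; mixed TSG/oncogene, any conflicting role, or a TSG with
  unclear partners → cautionary; no usable role evidence → unlikely.
* **R3** (dosage-type: CG/IED) — duplicated oncogene → PP_SV;
  unremarkable dosage gene but a TSG/oncogene disrupted at a
  breakpoint → cautionary; otherwise unlikely.
* **R4** — anything else → unlikely.

Genes missing from the role table default to "none" (with a warning
path); the role vocabulary is {TSG, oncogene, conflicting, unclear,
none}, with DNA-damage-repair genes encoded as TSG.

## Allelic evidence

Depth-based VAF: DEL `(flank − region)/flank`, DUP
`(region − flank)/region`, means over per-base depth (zero-depth bases
included) with both ± 10 kb flanks pooled; results clamp to [0, 1].
A heterozygous DEL therefore reads ~ 0.5 and a heterozygous tandem DUP
~ 0.33 — the formulas measure evidence fractions, not allele dosage, so
the two types have different heterozygous expectations. Breakpoint VAF
for INV/TRA divides deduplicated discordant-pair plus split-read counts
by the mean depth over the union of ± 150-base windows around both
breakpoints; it is flagged possibly conservative (a read showing both
signals counts once, and some variant pairs still align properly).

LOH: over the copy-number segment covering the largest fraction of the
gene (ties prefer the more altered status, ordered
CNL > CNN > CNG > negative), minor copy 0 means LOH, subtyped by major
copy 1 / 2 / ≥ 3 into LOH-CNL / LOH-CNN / LOH-CNG; uncovered genes are
undetermined. A somatic copy-number event on a germline-hit gene is
reported as a candidate second hit, all events in input order.

## Cohort summaries

Carrier fractions use distinct-patient semantics over the ancestry's
cohort size; percentages round half-up to one decimal with counts
reported alongside. Aggressive disease is ISUP group grade ≥ 3.
Unknown grades follow a policy: the default `count_aggressive` treats
an ungraded carrier as aggressive (with `exclude` and
`count_nonaggressive` available); on the packaged reference tables the
three policies give 13/14, 12/13 and 12/14 for predicted-PP-SV
carriers, and the default is required to reproduce the published 13/14
— this dependence is deliberate and surfaced in the API.

The packaged reference tables (`ppsv/data/`) are the curated final
candidate and carrier tables of a published 170-patient prostate cancer
cohort (113 African, 57 European men); they back the desk-scale
statistics (12.4 % / 7.0 % / 3.5 % / 8.8 % carriers, 83.3 % cautionary
aggressive fraction, 41.8 % mean VAF) without any controlled-access
data.

## Synthetic cohort design

The generator's defaults mirror the study conditions where those are
stated and desk-feasible: cohort sizes 113 African / 57 European, mean
coverage 46×, planted carrier counts chosen so rare planted SVs realise
the published MAF arithmetic (2 carriers → 0.009, 1 carrier → 0.004),
and an archive with 3 pathogenic/likely-pathogenic plus 10 benign
control entries matching the published validation counts. The genome
itself is deliberately tiny — three 5-Mb chromosomes, 48 genes of 8
exons each — so that the full end-to-end run takes under a second;
genome-scale SV counts (tens of thousands of sites) are intentionally
out of scope, represented by ~ 400 background SVs whose
ancestry-stratified frequencies are drawn from a Beta(0.5, 10) with
ancestry-private mass on both sides (heavier on the African side,
echoing the published private-variant asymmetry).

Noise defaults: breakpoint jitter sd 20 bases per caller (well inside
the 200-base tolerance; the noiseless limit recovers 100 % concordance,
and jitter sd 300 demonstrably breaks it), 3 % per-caller drop rate, 5 %
non-PASS labels, Poisson(2) caller-private false positives per sample,
1 % raw genotype missingness, 3 % FT-failure and 3 % low-GQ rates.
Planted *carrier* genotypes are emitted clean — masking a planted
carrier would silently detach the emitted files from the recorded
truth; all noise rates apply to everything else. Each planted decoy
fails exactly one gate (common frequency, benign scores, non-cancer
gene, oncogene loss, archived at 3 % AF), so a regression in any single
gate flips a specific decoy. Depth tracks for carriers are Poisson
per-base draws at 0.5× (DEL) / 1.5× (DUP) region coverage; breakpoint
evidence is Binomial(coverage, 0.45), reflecting the slight
undercounting of breakpoint reads relative to the ideal 0.5.

What the simulation does **not** emulate: sequence content and
alignment artefacts, segmental duplications and difficult-to-call
regions, linkage between sites, relatedness, multi-allelic sites, and
realistic score distributions for the four predictors (planted panels
are constructed to pass or fail, not sampled from tool behaviour).
Passing the end-to-end tests therefore demonstrates the *logic* of the
cascade — gate correctness, bookkeeping, determinism — not calling
performance on real genomes.

## Numerical and degenerate-input choices

Ties everywhere break by a total order (documented per operation), so
every result is independent of input ordering. Zero-denominator VAFs
and zero-callable-genotype sites are errors/flags rather than NaNs.
Percentages round half-up (not banker's rounding) to match how such
tables are conventionally printed. Sites with undefined frequencies or
AF = 1 are excluded before rarity classing. `pair_breakends` treats
duplicate or self-referencing mate ids as orphans.

## Known limitations

Reciprocal-overlap matching for large DELs/DUPs is not implemented —
concordance and archive matching use the breakpoint-distance rule only.
Multi-allelic SV sites are treated biallelically. UTR calling requires
CDS bounds; without them UTR collapses into pLoF/intronic by exon
overlap. The enhancer flag is only attached to genes that already have
a gene-body or promoter annotation. Transcript-level consequences
(frameshift, NMD) and regulatory position effects are out of scope —
the external score panel is the pipeline's window onto those.
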