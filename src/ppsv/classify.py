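"""Consensus pathogenicity classification of candidate structural variants.

The cascade mirrors a best-fit workflow for cohorts that are poorly
represented in clinical archives:

1. **Impact-score consensus** — four SV impact predictors score each
   variant (StrVCTVRE, CADD-SV, POSTRE, PhenoSV; each covers only some
   SV types).  A variant is a *candidate* when at least two tools reach
   their pathogenicity threshold (0.37 / 10 / 0.8 / 0.5).
2. **Cancer relevance** — the genes disrupted by a candidate must cover
   at least two of three cancer gene collections (hallmark sets,
   oncogenic signature sets, a cancer gene census).
3. **Rarity** — the candidate must be rare (MAF <= 1%) in both ancestry
   groups, and not already reported at >= 1% population frequency.
4. **Gene-role rule engine** — the curated tumour-suppressor / oncogene
   roles of the disrupted genes decide the final class: potentially
   pathogenic (PP_SV), ``cautionary`` when the role evidence conflicts,
   or ``unlikely``.  A pathogenic / likely-pathogenic clinical archive
   match overrides the role rules (flagged for manual review).

Every final call records the rule that fired, for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .impact import CG, IED, PLOF, ImpactAnnotation
from .known import LIKELY_PATHOGENIC, PATHOGENIC, MatchResult
from .model import SVRecord, SVType

# gene roles
TSG = "TSG"
ONCOGENE = "oncogene"
CONFLICTING = "conflicting"
UNCLEAR = "unclear"
NO_ROLE = "none"
ROLES = (TSG, ONCOGENE, CONFLICTING, UNCLEAR, NO_ROLE)

# final classes
PP_SV = "PP_SV"
CAUTIONARY = "cautionary"
UNLIKELY = "unlikely"
NOT_CANDIDATE = "not_candidate"

TOOLS = ("strvctvre", "cadd_sv", "postre", "phenosv")
DEFAULT_THRESHOLDS = {"strvctvre": 0.37, "cadd_sv": 10.0, "postre": 0.8, "phenosv": 0.5}

#: SV types each predictor can score (absent scores are structural, not noise).
TOOL_SCOPE = {
    "strvctvre": frozenset({SVType.DEL, SVType.DUP}),  # exon-overlapping only
    "cadd_sv": frozenset({SVType.DEL, SVType.DUP, SVType.INS}),
    "postre": frozenset({SVType.DEL, SVType.DUP, SVType.INV, SVType.TRA}),
    "phenosv": frozenset({SVType.DEL, SVType.DUP, SVType.INS, SVType.INV, SVType.TRA}),
}


@dataclass
class ScorePanel:
    """Per-SV scores from the four impact predictors; None = unscoreable."""

    sv_id: str
    strvctvre: Optional[float] = None
    cadd_sv: Optional[float] = None
    postre: Optional[float] = None
    phenosv: Optional[float] = None

    def score(self, tool: str) -> Optional[float]:
        return getattr(self, tool)


@dataclass
class GeneSetCollection:
    """The three cancer gene collections used for the relevance gate."""

    hallmark: frozenset[str]
    oncogenic_signatures: frozenset[str]
    cancer_census: frozenset[str]

    def __post_init__(self) -> None:
        self.hallmark = frozenset(self.hallmark)
        self.oncogenic_signatures = frozenset(self.oncogenic_signatures)
        self.cancer_census = frozenset(self.cancer_census)
        for name in ("hallmark", "oncogenic_signatures", "cancer_census"):
            if not getattr(self, name):
                raise ValueError(f"gene set {name!r} is empty")

    def sets(self) -> tuple[frozenset[str], ...]:
        return (self.hallmark, self.oncogenic_signatures, self.cancer_census)

    def membership(self, gene: str) -> int:
        """Number of collections containing the gene."""
        return sum(1 for s in self.sets() if gene in s)


@dataclass
class PathogenicityCall:
    sv_id: str
    n_tools_scored: int = 0
    n_tools_passed: int = 0
    candidate: bool = False
    cancer_related: bool = False
    rarity_ok: bool = False
    final_class: str = NOT_CANDIDATE
    clinvar_override: bool = False
    rule: Optional[str] = None


def consensus_candidate(
    panel: ScorePanel,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    min_pass: int = 2,
    min_pass_relative: bool = False,
) -> tuple[bool, int, int]:
    """Apply the multi-tool consensus rule to one score panel.

    A tool passes when its score is present and at or above its
    threshold; absent scores count as non-passing.  With the default
    absolute counting, candidacy requires ``min_pass`` passes regardless
    of how many tools could score the SV type; ``min_pass_relative``
    instead requires min(``min_pass``, number of scored tools) passes.

    Returns ``(candidate, n_passed, n_scored)``.
    """
    n_scored = n_passed = 0
    for tool in TOOLS:
        score = panel.score(tool)
        if score is None:
            continue
        if score < 0:
            raise ValueError(f"{panel.sv_id}: negative {tool} score {score}")
        n_scored += 1
        if score >= thresholds[tool]:
            n_passed += 1
    required = min(min_pass, n_scored) if min_pass_relative and n_scored else min_pass
    return n_passed >= required, n_passed, n_scored


def cancer_relevance(
    genes: Iterable[str],
    sets: GeneSetCollection,
    min_sets: int = 2,
    union: bool = True,
) -> bool:
    """Whether an SV's disrupted genes are cancer-relevant.

    Default (union reading): the union of the disrupted genes must cover
    at least ``min_sets`` of the three collections — a fusion joining two
    single-collection genes qualifies.  With ``union=False`` a single
    gene must itself sit in ``min_sets`` collections.
    """
    genes = list(genes)
    if union:
        covered = sum(1 for s in sets.sets() if any(g in s for g in genes))
        return covered >= min_sets
    return any(sets.membership(g) >= min_sets for g in genes)


def _roles_of(genes: Iterable[str], roles: Mapping[str, str]) -> list[str]:
    return [roles.get(g, NO_ROLE) for g in genes]


def classify_final(
    sv: SVRecord,
    impacts: Sequence[ImpactAnnotation],
    match: Optional[MatchResult],
    candidate: bool,
    rarity_ok: bool,
    roles: Mapping[str, str],
    n_tools_passed: int = 0,
    n_tools_scored: int = 0,
    cancer_related: bool = True,
    frequency_excluded: bool = False,
) -> PathogenicityCall:
    """Run the gene-role rule engine for one candidate SV.

    Rules fire in order; the first match wins and is recorded:

    R1  clinical-archive pathogenic / likely-pathogenic match -> PP_SV
        (override flagged; plausibility review stays manual);
    R2  loss-type impact (pLoF by DEL/INV/TRA): oncogene-only -> unlikely;
        all tumour suppressors -> PP_SV; mixed TSG/oncogene, any
        conflicting role, or TSG with unclear partners -> cautionary;
        no role evidence -> unlikely;
    R3  dosage-type impact (CG/IED): duplicated oncogene -> PP_SV;
        unremarkable dosage gene with a TSG/oncogene disrupted at a
        breakpoint -> cautionary; otherwise unlikely;
    R4  anything else -> unlikely.
    """
    call = PathogenicityCall(
        sv_id=sv.id,
        n_tools_scored=n_tools_scored,
        n_tools_passed=n_tools_passed,
        candidate=candidate,
        cancer_related=cancer_related,
        rarity_ok=rarity_ok,
    )
    if not candidate or not rarity_ok or not cancer_related or frequency_excluded:
        call.final_class = NOT_CANDIDATE
        call.rule = "gate"
        return call

    if match is not None and match.significance in (PATHOGENIC, LIKELY_PATHOGENIC):
        call.final_class = PP_SV
        call.clinvar_override = True
        call.rule = "R1"
        return call

    loss_genes = [
        a.gene_id
        for a in impacts
        if a.category == PLOF
        and a.gene_id is not None
        and sv.svtype in (SVType.DEL, SVType.INV, SVType.TRA)
    ]
    dosage_genes = [
        a.gene_id for a in impacts if a.category in (CG, IED) and a.gene_id is not None
    ]
    breakpoint_genes = sorted(
        {g for a in impacts for g in a.breakpoint_genes}
    )

    if loss_genes:
        gene_roles = _roles_of(loss_genes, roles)
        has_tsg = TSG in gene_roles
        has_onc = ONCOGENE in gene_roles
        if has_onc and not has_tsg:
            call.final_class, call.rule = UNLIKELY, "R2-oncogene-loss"
        elif all(r == TSG for r in gene_roles):
            call.final_class, call.rule = PP_SV, "R2-tsg-loss"
        elif has_tsg and has_onc:
            call.final_class, call.rule = CAUTIONARY, "R2-mixed"
        elif CONFLICTING in gene_roles:
            call.final_class, call.rule = CAUTIONARY, "R2-conflicting"
        elif has_tsg:
            call.final_class, call.rule = CAUTIONARY, "R2-tsg-unclear-partner"
        else:
            call.final_class, call.rule = UNLIKELY, "R2-no-role"
        return call

    if dosage_genes:
        gene_roles = _roles_of(dosage_genes, roles)
        if ONCOGENE in gene_roles:
            call.final_class, call.rule = PP_SV, "R3-oncogene-gain"
            return call
        bp_roles = _roles_of(
            [g for g in breakpoint_genes if g not in dosage_genes], roles
        )
        if any(r in (TSG, ONCOGENE) for r in bp_roles):
            call.final_class, call.rule = CAUTIONARY, "R3-breakpoint-role"
        else:
            call.final_class, call.rule = UNLIKELY, "R3-no-role"
        return call

    call.final_class, call.rule = UNLIKELY, "R4"
    return call


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_score_panels(path: str) -> dict[str, ScorePanel]:
    """Score-panel TSV: sv_id, strvctvre, cadd_sv, postre, phenosv
    (empty cell = tool cannot score the SV)."""
    df = pd.read_csv(path, sep="\t")
    panels = {}
    for row in df.itertuples(index=False):
        panels[row.sv_id] = ScorePanel(
            sv_id=row.sv_id,
            **{
                tool: None if pd.isna(getattr(row, tool)) else float(getattr(row, tool))
                for tool in TOOLS
            },
        )
    return panels


def write_score_panels(panels: Iterable[ScorePanel], path: str) -> None:
    rows = [
        {"sv_id": p.sv_id, **{t: p.score(t) for t in TOOLS}} for p in panels
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_roles(path: str) -> dict[str, str]:
    """Role TSV with columns gene_id, role (and optional evidence note)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        role = str(row.role)
        if role not in ROLES:
            raise ValueError(f"{row.gene_id}: unknown gene role {role!r}")
        out[str(row.gene_id)] = role
    return out


def write_gene_roles(roles: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        [{"gene_id": g, "role": r} for g, r in sorted(roles.items())]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, frozenset[str]]:
    """Read gene sets in GMT layout (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
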