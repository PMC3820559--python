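"""Decision-support tree for selecting suspected Lynch-syndrome cases.

Given the per-tumor assay calls, each screened endometrial-cancer patient is
classified as:

* ``proficient`` — no MSI and no MMR protein loss; screening ends.
* ``sporadic_methylated`` — MLH1 loss explained by tumor MLH1-promoter
  hypermethylation (the common somatic route); no germline testing.
* ``constitutional_epimutation_suspected`` — tumor *and* blood methylated,
  mimicking a germline mutation; referred for dedicated work-up.
* ``suspected_ls`` — MMR-deficient with no somatic explanation; an ordered,
  conditional germline gene-testing plan is attached.

Two bookkeeping states make the tree total: ``pending_methylation`` when an
MLH1-loss tumor has no methylation result yet, and ``unresolvable`` when the
MSI call is indeterminate and IHC shows no loss.

The gene plans mirror routine practice: isolated MLH1 loss without
methylation tests MLH1; MSH2 loss tests MSH2, then MSH6, then EPCAM (3'
deletions upstream of MSH2 silence it); isolated MSH6 or PMS2 loss tests
that gene; MSI with intact IHC tests all four genes.  ``next_gene`` walks a
plan given accumulated germline results, stopping at the first pathogenic
finding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .assay_calls import (
    IhcPanel,
    IhcPattern,
    MethylationStatus,
    MsiCall,
    MsiStatus,
    ProteinStatus,
)

__all__ = [
    "MmrStatus",
    "TriageLabel",
    "GermlineOutcome",
    "GermlineResult",
    "TriageDecision",
    "TwoAntibodyResult",
    "GENES",
    "mmr_status",
    "triage_patient",
    "next_gene",
    "two_antibody_triage",
    "triage_cohort",
]

#: Genes appearing in germline testing plans, in screening-prevalence order.
GENES = ("MLH1", "MSH2", "MSH6", "PMS2", "EPCAM")


class MmrStatus(str, enum.Enum):
    """Tumor mismatch-repair status: deficient iff MSI and/or any IHC loss."""

    DEFICIENT = "deficient"
    PROFICIENT = "proficient"
    #: MSI indeterminate with no IHC loss: neither rule applies.
    UNRESOLVABLE = "unresolvable"


class TriageLabel(str, enum.Enum):
    PROFICIENT = "proficient"
    SPORADIC_METHYLATED = "sporadic_methylated"
    SUSPECTED_LS = "suspected_ls"
    CONSTITUTIONAL_EPIMUTATION_SUSPECTED = "constitutional_epimutation_suspected"
    PENDING_METHYLATION = "pending_methylation"
    UNRESOLVABLE = "unresolvable"


class GermlineOutcome(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    VUS = "vus"
    NEGATIVE = "negative"
    NOT_DONE = "not_done"


class TwoAntibodyResult(str, enum.Enum):
    ABNORMAL = "abnormal"
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GermlineResult:
    """Outcome of germline analysis of one gene for one patient."""

    gene: str
    outcome: GermlineOutcome
    variant_label: str = ""

    def __post_init__(self):
        gene = self.gene.upper()
        if gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        object.__setattr__(self, "gene", gene)
        if not isinstance(self.outcome, GermlineOutcome):
            object.__setattr__(self, "outcome", GermlineOutcome(str(self.outcome).lower()))


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of the decision tree for one patient.

    Besides the label and gene plan, the decision carries the assay context
    it was derived from (loss set, MSI status, methylation calls) so that
    cohort-level accounting needs no second pass over raw data, and an
    ordered ``rationale`` trail of rule identifiers (R1..R7, plus R0 for
    unresolvable and RP for pending) for audit.
    """

    mmr: MmrStatus
    label: TriageLabel
    gene_plan: tuple[str, ...] = ()
    rationale: tuple[str, ...] = ()
    patient_id: Optional[str] = None
    lost: frozenset[str] = field(default_factory=frozenset)
    msi_status: MsiStatus = MsiStatus.MSS
    meth_tumor: Optional[MethylationStatus] = None
    meth_blood: Optional[MethylationStatus] = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if (self.label is TriageLabel.SUSPECTED_LS) != bool(self.gene_plan):
            raise ValueError(
                "gene_plan must be non-empty exactly when the label is suspected_ls"
            )


def mmr_status(msi: MsiCall, pattern: IhcPattern) -> MmrStatus:
    """Combine MSI call and IHC pattern into an MMR status.

    Deficient iff the tumor is MSI and/or any MMR protein is lost;
    proficient iff MSS with no loss.  An indeterminate MSI call with no
    loss resolves neither way and is flagged for review.
    """
    if msi.status is MsiStatus.MSI or pattern.lost:
        return MmrStatus.DEFICIENT
    if msi.status is MsiStatus.INDETERMINATE:
        return MmrStatus.UNRESOLVABLE
    return MmrStatus.PROFICIENT


def _dedupe(genes: Iterable[str]) -> tuple[str, ...]:
    seen: list[str] = []
    for g in genes:
        if g not in seen:
            seen.append(g)
    return tuple(seen)


def triage_patient(
    pattern: IhcPattern,
    msi: MsiCall,
    meth_tumor: Optional[MethylationStatus] = None,
    meth_blood: Optional[MethylationStatus] = None,
    patient_id: Optional[str] = None,
) -> TriageDecision:
    """Run the decision tree for one patient.

    Rules fire in a fixed order and every fired rule is recorded:

    R1  MMR-proficient: end of screening.
    R2  MLH1 lost, tumor methylated: sporadic (blood methylated instead
        flags a suspected constitutional epimutation; a missing blood
        sample leaves the sporadic call with a "blood unconfirmed" note).
    R3  MLH1 lost, tumor unmethylated: suspected, test MLH1.
    R4  MSH2 lost: suspected, test MSH2 -> MSH6 -> EPCAM.
    R5  MSH6 lost with MSH2 retained: suspected, test MSH6.
    R6  PMS2 lost with MLH1 retained: suspected, test PMS2.
    R7  MSI with intact IHC: suspected, test all four MMR genes.

    MLH1-branch rules take precedence, then rules 4-6 append their plans;
    a methylation-explained MLH1 loss therefore does not silence an
    independent MSH2/MSH6 loss.  An MLH1-loss tumor without a tumor
    methylation result is returned as pending, never silently defaulted.
    """

    def _make(label, plan=(), rationale=(), notes=()):
        return TriageDecision(
            mmr=mmr,
            label=label,
            gene_plan=_dedupe(plan),
            rationale=tuple(rationale),
            patient_id=patient_id,
            lost=pattern.lost,
            msi_status=msi.status,
            meth_tumor=meth_tumor,
            meth_blood=meth_blood,
            notes=tuple(notes),
        )

    mmr = mmr_status(msi, pattern)
    if mmr is MmrStatus.UNRESOLVABLE:
        return _make(TriageLabel.UNRESOLVABLE, rationale=("R0",),
                     notes=("indeterminate MSI with no IHC loss; review",))
    if mmr is MmrStatus.PROFICIENT:
        return _make(TriageLabel.PROFICIENT, rationale=("R1",))

    rationale: list[str] = []
    plan: list[str] = []
    notes: list[str] = []
    label: Optional[TriageLabel] = None

    if "MLH1" in pattern.lost:
        if meth_tumor is None:
            return _make(
                TriageLabel.PENDING_METHYLATION,
                rationale=("RP",),
                notes=("MLH1 lost but tumor methylation result missing",),
            )
        if meth_tumor is MethylationStatus.METHYLATED:
            rationale.append("R2")
            if meth_blood is MethylationStatus.METHYLATED:
                label = TriageLabel.CONSTITUTIONAL_EPIMUTATION_SUSPECTED
            else:
                label = TriageLabel.SPORADIC_METHYLATED
                if meth_blood is None:
                    notes.append("blood methylation unconfirmed")
        else:
            rationale.append("R3")
            label = TriageLabel.SUSPECTED_LS
            plan.append("MLH1")

    if "MSH2" in pattern.lost:
        rationale.append("R4")
        plan.extend(("MSH2", "MSH6", "EPCAM"))
    if "MSH6" in pattern.lost and "MSH2" not in pattern.lost:
        rationale.append("R5")
        plan.append("MSH6")
    if "PMS2" in pattern.lost and "MLH1" not in pattern.lost:
        rationale.append("R6")
        plan.append("PMS2")
    if msi.status is MsiStatus.MSI and not pattern.lost:
        rationale.append("R7")
        plan.extend(("MLH1", "MSH2", "MSH6", "PMS2"))

    if plan:
        if label is TriageLabel.CONSTITUTIONAL_EPIMUTATION_SUSPECTED:
            # epimutation work-up takes precedence; record the deferred plan
            notes.append("deferred gene plan: " + "/".join(_dedupe(plan)))
            plan = []
        else:
            label = TriageLabel.SUSPECTED_LS
    if label is None:
        raise AssertionError("deficient tumor matched no rule")  # pragma: no cover
    return _make(label, plan=plan, rationale=rationale, notes=notes)


def next_gene(
    decision: TriageDecision, results: Sequence[GermlineResult]
) -> Optional[str]:
    """Next gene to test under the decision's conditional plan.

    Returns the first plan gene without a completed result, provided every
    earlier gene tested non-pathogenic; returns ``None`` (done) once a
    pathogenic result exists or the plan is exhausted.  A VUS does not
    stop the chain — only a pathogenic finding is diagnostic.
    """
    if decision.label is not TriageLabel.SUSPECTED_LS:
        raise ValueError("next_gene applies only to suspected_ls decisions")
    by_gene: dict[str, GermlineResult] = {}
    for r in results:
        if r.gene not in decision.gene_plan:
            raise ValueError(f"result for {r.gene} outside the plan {decision.gene_plan}")
        by_gene[r.gene] = r
    if any(r.outcome is GermlineOutcome.PATHOGENIC for r in by_gene.values()):
        return None
    for gene in decision.gene_plan:
        r = by_gene.get(gene)
        if r is None or r.outcome is GermlineOutcome.NOT_DONE:
            return gene
    return None


def two_antibody_triage(panel: IhcPanel) -> TwoAntibodyResult:
    """Screen with the reduced PMS2/MSH6 antibody pair.

    Because MLH1 loss destabilises PMS2 and MSH2 loss destabilises MSH6
    (obligate heterodimers), staining only PMS2 and MSH6 is expected to
    capture any four-protein loss pattern.  Abnormal iff PMS2 or MSH6 is
    lost; indeterminate when both are unreliable.
    """
    if (
        panel.pms2 is ProteinStatus.UNRELIABLE
        and panel.msh6 is ProteinStatus.UNRELIABLE
    ):
        return TwoAntibodyResult.INDETERMINATE
    if panel.pms2 is ProteinStatus.LOST or panel.msh6 is ProteinStatus.LOST:
        return TwoAntibodyResult.ABNORMAL
    return TwoAntibodyResult.NORMAL


def triage_cohort(cohort, config=None) -> list[TriageDecision]:
    """Run assay calling plus the decision tree over a whole cohort.

    ``cohort`` is any iterable of patient records exposing ``patient_id``,
    ``msi`` (marker panel), ``ihc`` (IHC panel) and optional
    ``meth_tumor`` / ``meth_blood`` measurements (see
    :mod:`lynchtriage.synthetic_cohort`).  ``config`` optionally carries
    ``msi_min_informative`` and ``methylation_threshold`` overrides.
    """
    from .assay_calls import call_ihc_pattern, call_methylation, call_msi

    min_informative = getattr(config, "msi_min_informative", 3)
    threshold = getattr(config, "methylation_threshold", 0.15)
    decisions = []
    for patient in cohort:
        msi = call_msi(patient.msi, min_informative=min_informative)
        pattern = call_ihc_pattern(patient.ihc)
        meth_tumor = (
            call_methylation(patient.meth_tumor, threshold=threshold)
            if patient.meth_tumor is not None
            else None
        )
        meth_blood = (
            call_methylation(patient.meth_blood, threshold=threshold)
            if patient.meth_blood is not None
            else None
        )
        decisions.append(
            triage_patient(
                pattern,
                msi,
                meth_tumor=meth_tumor,
                meth_blood=meth_blood,
                patient_id=patient.patient_id,
            )
        )
    return decisions
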