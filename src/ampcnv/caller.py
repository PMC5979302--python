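"""Integrated CNV calling and the whole-gene ambiguity rule.

Evidence per amplicon:

* ``fa_cross`` -- fragment-analysis flag under the normalization anchored
  on the *other* gene (sensitive to whole-gene events);
* ``fa_same`` -- flag under the normalization anchored on the amplicon's
  *own* gene (a whole-gene event self-normalizes away here; only partial
  events show);
* ``rc`` -- read-count frequency flag against the run CI99% (MISSING when
  sequencing evidence is unavailable -- fragment analysis alone can carry
  a partial event).

The integration truth table is explicit, versioned data
(:data:`DEFAULT_TRUTH_TABLE`, version ``v1``) so laboratories can tune
it; the default is conservative: contradictions yield ``NO_CALL``, a
whole-gene-shaped pattern (cross flagged, same in-range) requires
read-count corroboration or its absence, and an agreeing pair of FA
flags suffices on its own.

The central safety rule: intra-sample cross-gene normalization cannot
distinguish a whole deletion of one gene from a whole duplication of the
other (ratios r versus 1/r).  :func:`detect_ambiguity` therefore emits a
``WHOLE_GENE_AMBIGUITY`` verdict carrying both rival hypotheses, and
:func:`resolve_with_dosage` is the *only* path to a whole-gene final
call -- resolution is permitted exclusively by orthogonal dosage
(MAQ/MLPA) evidence, never by re-weighting intra-panel evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ampcnv.dosage import DosageResult
from ampcnv.panel import PanelDesign
from ampcnv.states import CallState, FaFlag, GeneState, RcFlag

TRUTH_TABLE_VERSION = "v1"

_FA = (FaFlag.LOW, FaFlag.IN_RANGE, FaFlag.HIGH, FaFlag.MISSING)
_RC = (RcFlag.LOW, RcFlag.IN_CI, RcFlag.HIGH, RcFlag.MISSING)

TruthTable = dict[tuple[FaFlag, FaFlag, RcFlag], CallState]


def _default_rules(cross: FaFlag, same: FaFlag, rc: RcFlag) -> CallState:
    if cross is FaFlag.MISSING or same is FaFlag.MISSING:
        return CallState.NO_CALL
    if cross is FaFlag.LOW and same is FaFlag.LOW:
        # both normalizations agree on a loss: FA evidence alone suffices
        # unless read counts actively contradict it
        return CallState.NO_CALL if rc is RcFlag.HIGH else CallState.LOSS
    if cross is FaFlag.HIGH and same is FaFlag.HIGH:
        return CallState.NO_CALL if rc is RcFlag.LOW else CallState.GAIN
    if cross is FaFlag.LOW and same is FaFlag.IN_RANGE:
        # whole-gene-shaped pattern: needs RC support (or no RC at all)
        return (
            CallState.LOSS
            if rc in (RcFlag.LOW, RcFlag.MISSING)
            else CallState.NO_CALL
        )
    if cross is FaFlag.HIGH and same is FaFlag.IN_RANGE:
        return (
            CallState.GAIN
            if rc in (RcFlag.HIGH, RcFlag.MISSING)
            else CallState.NO_CALL
        )
    if cross is FaFlag.IN_RANGE and same is FaFlag.IN_RANGE:
        return (
            CallState.NEUTRAL
            if rc in (RcFlag.IN_CI, RcFlag.MISSING)
            else CallState.NO_CALL
        )
    # mixed LOW/HIGH, or same-gene flagged while cross is quiet
    return CallState.NO_CALL


def build_default_truth_table() -> TruthTable:
    return {
        (c, s, r): _default_rules(c, s, r)
        for c in _FA
        for s in _FA
        for r in _RC
    }


DEFAULT_TRUTH_TABLE: TruthTable = build_default_truth_table()


def save_truth_table(table: TruthTable, path: str | Path) -> None:
    payload = {
        "version": TRUTH_TABLE_VERSION,
        "entries": [
            {"fa_cross": c.value, "fa_same": s.value, "rc": r.value,
             "call": v.value}
            for (c, s, r), v in table.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_truth_table(path: str | Path) -> TruthTable:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        (FaFlag(e["fa_cross"]), FaFlag(e["fa_same"]), RcFlag(e["rc"])):
            CallState(e["call"])
        for e in payload["entries"]
    }


@dataclass(frozen=True)
class AmpliconCall:
    """Integrated per-amplicon call with the evidence that produced it."""

    amplicon_id: str
    state: CallState
    fa_cross: FaFlag
    fa_same: FaFlag
    rc: RcFlag


def classify_amplicon(
    amplicon_id: str,
    fa_cross: FaFlag | str,
    fa_same: FaFlag | str,
    rc: RcFlag | str = RcFlag.MISSING,
    table: Optional[TruthTable] = None,
) -> AmpliconCall:
    """Look one evidence triple up in the (default or custom) truth table."""
    try:
        c, s, r = FaFlag(fa_cross), FaFlag(fa_same), RcFlag(rc)
    except ValueError as exc:
        raise ValueError(f"unknown evidence flag: {exc}") from exc
    tab = DEFAULT_TRUTH_TABLE if table is None else table
    return AmpliconCall(
        amplicon_id=amplicon_id, state=tab[(c, s, r)],
        fa_cross=c, fa_same=s, rc=r,
    )


@dataclass
class Ambiguity:
    """Two rival whole-gene hypotheses that intra-panel data cannot separate."""

    hypotheses: list[dict[str, GeneState]]


@dataclass
class CnvVerdict:
    """Per-amplicon calls plus gene-level states and the ambiguity flag."""

    calls: dict[str, AmpliconCall]
    gene_level: dict[str, GeneState]
    ambiguity: Optional[Ambiguity]
    recommendation: str

    def to_json_dict(self) -> dict:
        return {
            "calls": {
                aid: {
                    "state": c.state.value,
                    "fa_cross": c.fa_cross.value,
                    "fa_same": c.fa_same.value,
                    "rc": c.rc.value,
                }
                for aid, c in self.calls.items()
            },
            "gene_level": {g: s.value for g, s in self.gene_level.items()},
            "ambiguity": (
                None
                if self.ambiguity is None
                else [
                    {g: s.value for g, s in h.items()}
                    for h in self.ambiguity.hypotheses
                ]
            ),
            "recommendation": self.recommendation,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CnvVerdict":
        return cls(
            calls={
                aid: AmpliconCall(
                    amplicon_id=aid,
                    state=CallState(c["state"]),
                    fa_cross=FaFlag(c["fa_cross"]),
                    fa_same=FaFlag(c["fa_same"]),
                    rc=RcFlag(c["rc"]),
                )
                for aid, c in d["calls"].items()
            },
            gene_level={
                g: GeneState(s) for g, s in d["gene_level"].items()
            },
            ambiguity=(
                None
                if d["ambiguity"] is None
                else Ambiguity(
                    hypotheses=[
                        {g: GeneState(s) for g, s in h.items()}
                        for h in d["ambiguity"]
                    ]
                )
            ),
            recommendation=d["recommendation"],
        )


_ORTHOGONAL = (
    "Whole-gene copy-number ambiguity: intra-panel evidence cannot "
    "distinguish the rival hypotheses. Orthogonal dosage testing "
    "(MLPA/MAQ) is REQUIRED before reporting."
)


def _gene_pattern(
    calls: dict[str, AmpliconCall],
    panel: PanelDesign,
    gene: str,
    target: CallState,
    no_call_tolerance: float,
) -> bool:
    """True when (tolerating some NO_CALLs) every called amplicon of the
    gene has state ``target`` and at least one call exists."""
    amps = panel.amplicons_for_gene(gene)
    states = [calls[a.id].state for a in amps]
    n_nc = sum(1 for s in states if s is CallState.NO_CALL)
    if n_nc > no_call_tolerance * len(states):
        return False
    called = [s for s in states if s is not CallState.NO_CALL]
    return bool(called) and all(s is target for s in called)


def detect_ambiguity(
    calls: dict[str, AmpliconCall],
    panel: PanelDesign,
    no_call_tolerance: float = 0.10,
) -> CnvVerdict:
    """Lift per-amplicon calls to gene level, flagging the whole-gene
    degeneracy.

    A full-gene LOSS pattern on one gene paired with a full-gene GAIN
    pattern on the other (or either pattern alone -- the mirror
    hypothesis is implied by the normalization algebra) emits
    ``WHOLE_GENE_AMBIGUITY`` with both rival hypotheses.  A proper subset
    of one gene's amplicons flagged yields an unambiguous PARTIAL event.
    ``no_call_tolerance`` is the fraction of NO_CALL amplicons a
    whole-gene pattern may contain (dropout robustness).
    """
    missing = [a.id for a in panel.amplicons if a.id not in calls]
    if missing:
        raise ValueError(f"calls do not cover the panel: missing {missing[:5]}")
    g1, g2 = panel.gene_labels

    whole = {
        (g, st): _gene_pattern(calls, panel, g, st, no_call_tolerance)
        for g in (g1, g2)
        for st in (CallState.LOSS, CallState.GAIN)
    }

    def verdict_whole(loss_gene: str, gain_gene: str) -> CnvVerdict:
        return CnvVerdict(
            calls=calls,
            gene_level={
                loss_gene: GeneState.WHOLE_LOSS,
                gain_gene: GeneState.WHOLE_GAIN,
            },
            ambiguity=Ambiguity(
                hypotheses=[
                    {loss_gene: GeneState.WHOLE_LOSS, gain_gene: GeneState.NEUTRAL},
                    {gain_gene: GeneState.WHOLE_GAIN, loss_gene: GeneState.NEUTRAL},
                ]
            ),
            recommendation=_ORTHOGONAL,
        )

    # whole-gene patterns, two-sided or one-sided, are always ambiguous
    if whole[(g2, CallState.LOSS)] or whole[(g1, CallState.GAIN)]:
        return verdict_whole(loss_gene=g2, gain_gene=g1)
    if whole[(g1, CallState.LOSS)] or whole[(g2, CallState.GAIN)]:
        return verdict_whole(loss_gene=g1, gain_gene=g2)

    gene_level: dict[str, GeneState] = {}
    for g in (g1, g2):
        states = [calls[a.id].state for a in panel.amplicons_for_gene(g)]
        n_loss = states.count(CallState.LOSS)
        n_gain = states.count(CallState.GAIN)
        if n_loss and n_loss >= n_gain:
            gene_level[g] = GeneState.PARTIAL_LOSS
        elif n_gain:
            gene_level[g] = GeneState.PARTIAL_GAIN
        else:
            gene_level[g] = GeneState.NEUTRAL
    partial = any(s is not GeneState.NEUTRAL for s in gene_level.values())
    return CnvVerdict(
        calls=calls,
        gene_level=gene_level,
        ambiguity=None,
        recommendation=(
            "Partial event detected; confirm with orthogonal dosage testing."
            if partial
            else "No copy-number event detected."
        ),
    )


@dataclass
class FinalCall:
    """A verdict joined with dosage evidence; the only whole-gene authority."""

    verdict: CnvVerdict
    dosage: DosageResult
    status: str  # RESOLVED | UNRESOLVED | NO_AMBIGUITY
    resolved_gene_level: dict[str, GeneState]
    provenance: str
    retained_hypotheses: list[dict[str, GeneState]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "resolved_gene_level": {
                g: s.value for g, s in self.resolved_gene_level.items()
            },
            "provenance": self.provenance,
            "retained_hypotheses": [
                {g: s.value for g, s in h.items()}
                for h in self.retained_hypotheses
            ],
            "verdict": self.verdict.to_json_dict(),
            "dosage": self.dosage.to_json_dict(),
        }


def _hypothesis_consistent(
    hypothesis: dict[str, GeneState], dosage: DosageResult
) -> bool:
    for gene, state in hypothesis.items():
        summary = dosage.gene_summary.get(gene)
        if summary is None:
            continue  # dosage panel does not cover this gene
        if state is GeneState.NEUTRAL and summary is not GeneState.NEUTRAL:
            return False
        if state is not GeneState.NEUTRAL and summary is not state:
            return False
    return True


def resolve_with_dosage(verdict: CnvVerdict, dosage: DosageResult) -> FinalCall:
    """Resolve a whole-gene ambiguity with classified dosage evidence.

    The hypothesis consistent with the dosage per-gene summary is
    selected; if dosage contradicts both hypotheses the call stays
    UNRESOLVED with both retained.  ``dosage`` must be classified
    (:func:`ampcnv.dosage.classify_dq`) and must cover at least one
    ambiguous gene.
    """
    if not dosage.gene_summary:
        raise ValueError(
            "dosage result carries no gene summary; run classify_dq first"
        )
    if verdict.ambiguity is None:
        return FinalCall(
            verdict=verdict,
            dosage=dosage,
            status="NO_AMBIGUITY",
            resolved_gene_level=dict(verdict.gene_level),
            provenance="intra-panel evidence; dosage corroboration attached",
        )

    ambiguous_genes = {g for h in verdict.ambiguity.hypotheses for g in h}
    if not ambiguous_genes & set(dosage.gene_summary):
        raise ValueError(
            f"dosage panel covers none of the ambiguous genes "
            f"{sorted(ambiguous_genes)}"
        )

    consistent = [
        h for h in verdict.ambiguity.hypotheses
        if _hypothesis_consistent(h, dosage)
    ]
    if len(consistent) == 1:
        winner = consistent[0]
        resolved = {g: GeneState.NEUTRAL for g in verdict.gene_level}
        resolved.update(winner)
        return FinalCall(
            verdict=verdict,
            dosage=dosage,
            status="RESOLVED",
            resolved_gene_level=resolved,
            provenance=f"dosage panel {dosage.panel.name!r} (MAQ/MLPA evidence)",
        )
    return FinalCall(
        verdict=verdict,
        dosage=dosage,
        status="UNRESOLVED",
        resolved_gene_level={},
        provenance=(
            "dosage evidence consistent with "
            + ("both hypotheses" if consistent else "neither hypothesis")
        ),
        retained_hypotheses=list(verdict.ambiguity.hypotheses),
    )
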