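"""Dollo-parsimony event placement and rescue calling.

Y-linked presence/absence patterns are explained under Dollo parsimony
(single origin at the root of the family's scope, irreversible losses):
the minimal loss set is the set of maximal branches whose entire subtree
lacks the gene.  Autosomal gains are placed on the stem of the MRCA of the
carriers of each shared-origin locus group.  A gain becomes a *rescue*
when its carriers lie in lineages that lost the Y-linked copy and at least
one carrier copy is intact, transcribed, and old enough to have been
vetted by selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .tree import SpeciesTree, branch_id_for
from .types import AnalysisConfig, EvidenceRecord, ValidationError

log = logging.getLogger("yrescue.rescue")


@dataclass(frozen=True)
class LossEvent:
    family: str
    branch_id: str
    affected_species: frozenset[str]


@dataclass(frozen=True)
class GainEvent:
    family: str
    branch_id: str
    carrier_species: frozenset[str]
    locus_groups: tuple[frozenset[tuple[str, str]], ...]
    mechanism: str = "retro"
    origin_verdict: str = "unresolved"
    origin_support: Optional[float] = None

    @property
    def n_loci(self) -> int:
        return len(self.locus_groups)


@dataclass(frozen=True)
class RescueEvent:
    family: str
    gain: GainEvent
    matched_losses: tuple[LossEvent, ...]
    evidence: tuple[EvidenceRecord, ...]
    min_origin_age: float
    ordering_ambiguous: bool  # loss-lineage/carrier containment direction


@dataclass
class EventReport:
    rescues: list[RescueEvent] = field(default_factory=list)
    excluded_gains: list[tuple[GainEvent, str]] = field(default_factory=list)
    losses: list[LossEvent] = field(default_factory=list)
    filter_counts: dict[str, int] = field(default_factory=dict)

    def n_rescues(self) -> int:
        return len(self.rescues)

    def to_json(self) -> str:
        def ev(e: EvidenceRecord):
            return {
                "family": e.family,
                "species": e.species,
                "locus_id": e.locus_id,
                "orf_status": e.orf_status,
                "transcribed": e.transcribed,
                "recency": e.recency,
                "omega": e.omega,
                "expression_pattern": e.expression_pattern,
            }

        def gain(g: GainEvent):
            return {
                "family": g.family,
                "branch_id": g.branch_id,
                "carriers": sorted(g.carrier_species),
                "n_loci": g.n_loci,
                "loci": [sorted(f"{s}:{l}" for s, l in grp) for grp in g.locus_groups],
                "mechanism": g.mechanism,
                "origin_verdict": g.origin_verdict,
                "origin_support": g.origin_support,
            }

        payload = {
            "rescues": [
                {
                    "family": r.family,
                    "gain": gain(r.gain),
                    "matched_loss_branches": sorted(l.branch_id for l in r.matched_losses),
                    "evidence": [ev(e) for e in r.evidence],
                    "min_origin_age_mya": r.min_origin_age,
                    "ordering_ambiguous": r.ordering_ambiguous,
                }
                for r in self.rescues
            ],
            "excluded_gains": [
                {"gain": gain(g), "reason": reason} for g, reason in self.excluded_gains
            ],
            "losses": [
                {
                    "family": l.family,
                    "branch_id": l.branch_id,
                    "affected_species": sorted(l.affected_species),
                }
                for l in self.losses
            ],
            "filter_counts": dict(sorted(self.filter_counts.items())),
            "n_rescues": self.n_rescues(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        rows = []
        for r in self.rescues:
            rows.append(
                {
                    "family": r.family,
                    "status": "rescue",
                    "branch_id": r.gain.branch_id,
                    "carriers": ",".join(sorted(r.gain.carrier_species)),
                    "n_loci": r.gain.n_loci,
                    "mechanism": r.gain.mechanism,
                    "origin": r.gain.origin_verdict,
                    "min_origin_age_mya": r.min_origin_age,
                    "reason": "",
                }
            )
        for g, reason in self.excluded_gains:
            rows.append(
                {
                    "family": g.family,
                    "status": "excluded",
                    "branch_id": g.branch_id,
                    "carriers": ",".join(sorted(g.carrier_species)),
                    "n_loci": g.n_loci,
                    "mechanism": g.mechanism,
                    "origin": g.origin_verdict,
                    "min_origin_age_mya": "",
                    "reason": reason,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "family",
                "status",
                "branch_id",
                "carriers",
                "n_loci",
                "mechanism",
                "origin",
                "min_origin_age_mya",
                "reason",
            ],
        )
        return df.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dollo parsimony

def dollo_losses(
    tree: SpeciesTree, family: str, presence: dict[str, bool]
) -> list[LossEvent]:
    """Minimal irreversible-loss placement for a presence/absence pattern.

    ``presence`` maps every leaf of ``tree`` to whether the Y-linked copy is
    present.  Returns one LossEvent per maximal all-absent subtree.  A gene
    absent from every species has no inferable origin and is an error.
    """
    leaves = set(tree.leaf_labels)
    missing = leaves - set(presence)
    if missing:
        raise ValidationError(f"presence undefined for {sorted(missing)}")
    if not any(presence[s] for s in leaves):
        raise ValidationError(f"{family}: gene absent from all species; no origin")
    losses: list[LossEvent] = []

    def walk(node, parent_all_absent: bool) -> None:
        below = tree.leaves_below(node)
        all_absent = all(not presence[s] for s in below)
        if all_absent and not parent_all_absent:
            losses.append(
                LossEvent(
                    family=family,
                    branch_id=branch_id_for(below),
                    affected_species=frozenset(below),
                )
            )
        for child in node.child_nodes():
            walk(child, all_absent)

    walk(tree.tree.seed_node, False)
    return sorted(losses, key=lambda l: l.branch_id)


def dollo_gains(
    tree: SpeciesTree,
    family: str,
    groups: list[frozenset[tuple[str, str]]],
    mechanism_by_locus: Optional[dict[tuple[str, str], str]] = None,
) -> list[GainEvent]:
    """Place one gain per locus group on the stem of its carriers' MRCA.

    Locus groups of the same family that land on the same branch are
    collapsed into a single GainEvent (one origination) that retains all
    its locus groups; per-locus counts stay recoverable via ``n_loci``.
    """
    by_branch: dict[str, dict] = {}
    for group in groups:
        carriers = frozenset(s for s, _ in group)
        if len(carriers) == 1:
            branch = branch_id_for(carriers)
        else:
            branch = tree.branch_id(tree.mrca(sorted(carriers)))
        mechs = set()
        if mechanism_by_locus:
            mechs = {mechanism_by_locus.get(k, "retro") for k in group}
        entry = by_branch.setdefault(
            branch, {"carriers": set(), "groups": [], "mechs": set()}
        )
        entry["carriers"] |= carriers
        entry["groups"].append(group)
        entry["mechs"] |= mechs
    events = []
    for branch, entry in sorted(by_branch.items()):
        mechs = entry["mechs"] or {"retro"}
        events.append(
            GainEvent(
                family=family,
                branch_id=branch,
                carrier_species=frozenset(entry["carriers"]),
                locus_groups=tuple(
                    sorted(entry["groups"], key=lambda g: sorted(g))
                ),
                mechanism=sorted(mechs)[0] if len(mechs) == 1 else "mixed",
            )
        )
    return events


# ---------------------------------------------------------------------------
# Rescue calling

def call_rescues(
    losses: list[LossEvent],
    gains: list[GainEvent],
    evidence: list[EvidenceRecord],
    tree: SpeciesTree,
    config: AnalysisConfig,
) -> EventReport:
    """Pair gains with Y-losses and screen them through the evidence bundle.

    A gain becomes a rescue iff (i) every carrier species belongs to a
    lineage with a loss of the same family, or — for ancient gains that
    predate the loss — some loss lineage is contained in the carriers
    (flagged as ordering-ambiguous); and (ii) at least one carrier copy is
    intact, transcribed, and passes the recency filter.  Gains failing the
    evidence screen are reported as excluded (pseudogenes when the ORF or
    transcription failed).
    """
    ev_by_key = {(e.family, e.species, e.locus_id): e for e in evidence}
    report = EventReport(losses=sorted(losses, key=lambda l: (l.family, l.branch_id)))
    counts = {
        "gains_total": len(gains),
        "rescues": 0,
        "excluded_no_matched_loss": 0,
        "excluded_pseudogene": 0,
        "excluded_recent": 0,
        "excluded_no_evidence": 0,
    }
    for gain in sorted(gains, key=lambda g: (g.family, g.branch_id)):
        fam_losses = [l for l in losses if l.family == gain.family]
        lost_species = set().union(*(l.affected_species for l in fam_losses)) if fam_losses else set()
        carriers = set(gain.carrier_species)
        forward = carriers <= lost_species
        matched = [
            l
            for l in fam_losses
            if (l.affected_species & carriers)
            or (forward and carriers <= l.affected_species)
        ]
        reverse = any(l.affected_species <= carriers for l in fam_losses)
        loss_matched = forward or reverse
        group_ev: list[EvidenceRecord] = []
        for grp in gain.locus_groups:
            for s, locus in sorted(grp):
                e = ev_by_key.get((gain.family, s, locus))
                if e is not None:
                    group_ev.append(e)
        if loss_matched and group_ev and any(e.passes for e in group_ev):
            age = 0.0
            for grp in gain.locus_groups:
                sp = sorted({s for s, _ in grp})
                for i, sa in enumerate(sp):
                    for sb in sp[i + 1 :]:
                        age = max(age, tree.divergence_time(sa, sb))
            report.rescues.append(
                RescueEvent(
                    family=gain.family,
                    gain=gain,
                    matched_losses=tuple(
                        sorted(matched, key=lambda l: l.branch_id)
                    ),
                    evidence=tuple(group_ev),
                    min_origin_age=age,
                    ordering_ambiguous=bool(reverse and not forward) or (reverse and forward),
                )
            )
            counts["rescues"] += 1
        else:
            reasons = []
            if not group_ev:
                counts["excluded_no_evidence"] += 1
                reasons.append("no evidence records for carriers")
            elif not any(e.passes for e in group_ev):
                if all(e.recency == "dismiss" for e in group_ev):
                    counts["excluded_recent"] += 1
                    reasons.append(
                        "all carrier copies <2% diverged from parent (too recent)"
                    )
                else:
                    counts["excluded_pseudogene"] += 1
                    bad = group_ev[0]
                    reasons.append(
                        f"pseudogene: orf={bad.orf_status}, transcribed={bad.transcribed}"
                    )
            if not loss_matched:
                counts["excluded_no_matched_loss"] += 1
                reasons.append("Y-linked copy retained in carrier lineages (no matched loss)")
            report.excluded_gains.append((gain, "; ".join(reasons)))
    for name, value in counts.items():
        log.info("call_rescues: %s = %d", name, value)
    report.filter_counts = counts
    return report
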