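"""End-to-end orchestration: homologs + tree + reads + synteny -> rescues.

The pipeline is a funnel of the three functionality criteria (intact ORF,
transcription, non-recent origin) wrapped around the comparative stages
(parental-origin trees, synteny grouping/dating, Dollo placement).  It can
run in two modes: *computed*, where the evidence bundle is derived from
sequences and reads, and *curated*, where a pre-assembled evidence table
stands in for stages whose raw inputs are not available.  Each stage logs
record counts in and out, and the whole run is deterministic given the
configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import divergence as dv
from . import expression as xp
from . import orf as orf_mod
from . import phylo as ph
from . import rescue as rc
from . import synteny as sy
from .align import align_codons
from .tree import SpeciesTree
from .types import AnalysisConfig, EvidenceRecord, GeneCopy, HomologTable, ValidationError

log = logging.getLogger("yrescue.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, family: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for family {family!r}: {cause}")
        self.stage = stage
        self.family = family


@dataclass
class PipelineResult:
    report: rc.EventReport
    evidence: list[EvidenceRecord] = field(default_factory=list)
    origin_calls: list[ph.OriginCall] = field(default_factory=list)
    orf_reports: dict = field(default_factory=dict)       # (family, species, locus) -> OrfReport
    locus_groups: dict = field(default_factory=dict)      # family -> [groups]
    profiles: dict = field(default_factory=dict)          # (family, species, locus) -> ExpressionProfile
    losses: list = field(default_factory=list)
    gains: list = field(default_factory=list)


def _nearest_copy(
    copies: list[GeneCopy], species: str, tree: SpeciesTree
) -> Optional[GeneCopy]:
    best = None
    best_t = None
    for c in sorted(copies, key=lambda c: c.label):
        t = 0.0 if c.species == species else tree.divergence_time(c.species, species)
        if best is None or t < best_t:
            best, best_t = c, t
    return best


def choose_outgroup(copies: list[GeneCopy], tree: SpeciesTree) -> list[str]:
    """Outgroup labels: copies of the earliest-diverging species present.

    Picks the species maximizing its mean divergence to the others
    (marsupials when present); prefers its X-linked copy.
    """
    species = sorted({c.species for c in copies})
    if len(species) < 2:
        return [copies[0].label]
    best = None
    best_d = -1.0
    for s in species:
        d = sum(tree.divergence_time(s, t) for t in species if t != s) / (len(species) - 1)
        if d > best_d + 1e-9:
            best, best_d = s, d
    sp_copies = [c for c in copies if c.species == best]
    x = [c for c in sp_copies if c.chrom_class == "X"]
    chosen = x if x else sp_copies
    return [c.label for c in chosen]


def run_pipeline(
    homologs: HomologTable,
    tree: SpeciesTree,
    reads: Optional[dict] = None,
    synteny_records: Optional[list] = None,
    config: Optional[AnalysisConfig] = None,
    curated_evidence: Optional[list[EvidenceRecord]] = None,
    mismatch_tolerance: int = 3,
    tissue_panel: tuple[str, ...] = ("brain", "heart", "kidney", "liver", "testis"),
) -> PipelineResult:
    """Run every stage and call rescue events.

    ``reads`` maps species -> ReadSet (may be None in curated mode);
    ``curated_evidence`` replaces the computed ORF/expression/recency
    verdicts when the raw sequence/read inputs are unavailable.
    """
    config = config or AnalysisConfig()
    synteny_records = synteny_records or []
    result = PipelineResult(report=rc.EventReport())
    all_losses: list[rc.LossEvent] = []
    all_gains: list[rc.GainEvent] = []
    evidence: list[EvidenceRecord] = list(curated_evidence or [])

    for fam_idx, family in enumerate(homologs.families()):
        a_copies = homologs.copies(family=family, chrom_class="A")
        scope = homologs.family_scope(family)
        scope_tree = tree.restrict_to(scope) if len(scope) > 1 else tree

        # --- Dollo Y-loss placement -----------------------------------
        try:
            presence = {s: homologs.presence(family, s, "Y") for s in scope}
            losses = rc.dollo_losses(scope_tree, family, presence)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("dollo_losses", family, e) from e
        all_losses.extend(losses)
        log.info("%s: %d Y-loss events on %d-species scope", family, len(losses), len(scope))
        if not a_copies:
            continue

        # --- synteny grouping -----------------------------------------
        try:
            fam_records = [r for r in synteny_records if r.family == family]
            groups = sy.locus_groups(fam_records, config) if fam_records else []
            grouped = {k for g in groups for k in g}
            for c in a_copies:  # loci without a synteny record are singletons
                if (c.species, c.locus_id) not in grouped:
                    groups.append(frozenset({(c.species, c.locus_id)}))
            groups = sorted(groups, key=lambda g: sorted(g))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("synteny", family, e) from e
        result.locus_groups[family] = groups
        log.info("%s: %d autosomal loci in %d shared-origin groups", family, len(a_copies), len(groups))

        mech = {
            (c.species, c.locus_id): c.mechanism_hint
            if c.mechanism_hint in ("retro", "dna")
            else "retro"
            for c in a_copies
        }
        try:
            gains = rc.dollo_gains(scope_tree, family, groups, mech)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("dollo_gains", family, e) from e

        if curated_evidence is None:
            fam_evidence, calls = _computed_evidence(
                family,
                fam_idx,
                homologs,
                tree,
                reads,
                groups,
                config,
                mismatch_tolerance,
                tissue_panel,
                result,
            )
            evidence.extend(fam_evidence)
            result.origin_calls.extend(calls)
            verdicts = {}
            for call in calls:
                for label in call.clade:
                    verdicts[label] = (call.verdict, call.support)
            gains = [
                _annotate_gain(g, verdicts, homologs) for g in gains
            ]
        all_gains.extend(gains)

    report = rc.call_rescues(all_losses, all_gains, evidence, tree, config)
    result.report = report
    result.evidence = evidence
    result.losses = all_losses
    result.gains = all_gains
    return result


def _annotate_gain(gain: rc.GainEvent, verdicts: dict, homologs: HomologTable) -> rc.GainEvent:
    labels = []
    for grp in gain.locus_groups:
        for s, locus in grp:
            for c in homologs.copies(family=gain.family, species=s):
                if c.locus_id == locus:
                    labels.append(c.label)
    found = [verdicts[l] for l in labels if l in verdicts]
    if not found:
        return gain
    vs = {v for v, _ in found}
    verdict = vs.pop() if len(vs) == 1 else "unresolved"
    supports = [s for _, s in found if s is not None]
    return rc.GainEvent(
        family=gain.family,
        branch_id=gain.branch_id,
        carrier_species=gain.carrier_species,
        locus_groups=gain.locus_groups,
        mechanism=gain.mechanism,
        origin_verdict=verdict,
        origin_support=min(supports) if supports else None,
    )


def _computed_evidence(
    family: str,
    fam_idx: int,
    homologs: HomologTable,
    tree: SpeciesTree,
    reads: Optional[dict],
    groups,
    config: AnalysisConfig,
    mismatch_tolerance: int,
    tissue_panel,
    result: PipelineResult,
):
    """Derive the evidence bundle for one family from sequences and reads."""
    a_copies = homologs.copies(family=family, chrom_class="A")
    x_copies = homologs.copies(family=family, chrom_class="X")
    y_copies = homologs.copies(family=family, chrom_class="Y")
    fam_copies = [c for c in homologs.copies(family=family) if c.cds]

    # --- ORF integrity -------------------------------------------------
    orf_status: dict[str, str] = {}
    try:
        for c in a_copies:
            ref = _nearest_copy(
                [r for r in x_copies if r.cds], c.species, tree
            ) or _nearest_copy([r for r in y_copies if r.cds], c.species, tree)
            if ref is None or c.cds is None:
                raise ValidationError(f"no sex-linked reference for {c.label}")
            rep = orf_mod.assess_integrity(c, ref, config)
            orf_status[c.label] = rep.status
            result.orf_reports[(family, c.species, c.locus_id)] = rep
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("orf_integrity", family, e) from e

    # --- alignment + origin trees --------------------------------------
    calls: list[ph.OriginCall] = []
    aln = None
    ptree = None
    try:
        if len(fam_copies) >= 3:
            aln = align_codons(fam_copies)
            ptree = ph.bootstrap_supports(
                aln,
                config.bootstrap_replicates,
                seed=(config.random_seed * 1009 + fam_idx) % (2**31 - 1),
            )
            outgroup = choose_outgroup(fam_copies, tree)
            by_key = {(c.species, c.locus_id): c for c in fam_copies}
            for group in groups:
                labels = [
                    by_key[k].label
                    for k in sorted(group)
                    if k in by_key and by_key[k].chrom_class == "A"
                ]
                labels = [l for l in labels if l in ptree.taxa and l not in outgroup]
                if not labels:
                    continue
                calls.append(
                    ph.classify_origin(
                        ptree, family, outgroup, config, autosomal_labels=labels
                    )
                )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("phylo_origin", family, e) from e
    verdict_by_label: dict[str, str] = {}
    for call in calls:
        for l in call.clade:
            verdict_by_label[l] = call.verdict

    # --- recency -------------------------------------------------------
    recency: dict[str, str] = {}
    try:
        for c in a_copies:
            if c.cds is None or aln is None or c.label not in aln.taxa:
                recency[c.label] = "keep"
                continue
            parent_class = verdict_by_label.get(c.label, "unresolved")
            if parent_class not in ("X", "Y"):
                parent_class = "X" if x_copies else "Y"
            pool = x_copies if parent_class == "X" else y_copies
            pool = [p for p in pool if p.cds and p.label in aln.taxa]
            if not pool:
                pool = [
                    p
                    for p in (x_copies + y_copies)
                    if p.cds and p.label in aln.taxa
                ]
            parent = _nearest_copy(pool, c.species, tree)
            if parent is None:
                recency[c.label] = "keep"
                continue
            div = dv.p_distance(*aln.pair(c.label, parent.label))
            recency[c.label] = dv.recency_filter(div, config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("recency", family, e) from e

    # --- dN/dS within locus groups --------------------------------------
    omegas: dict[str, Optional[float]] = {}
    by_key = {(c.species, c.locus_id): c for c in fam_copies}
    for group in groups:
        members = [by_key[k] for k in sorted(group) if k in by_key]
        members = [m for m in members if aln is not None and m.label in aln.taxa]
        omega = None
        if len(members) >= 2:
            pair = _most_divergent_pair(members, tree)
            try:
                res = dv.ng86_dnds(*aln.pair(pair[0].label, pair[1].label))
                omega = res.omega
            except ValidationError:
                omega = None
        for m in members:
            omegas[m.label] = omega

    # --- expression -----------------------------------------------------
    transcribed: dict[str, bool] = {}
    patterns: dict[str, Optional[str]] = {}
    try:
        for c in a_copies:
            if not reads or c.species not in reads or c.cds is None:
                transcribed[c.label] = False
                patterns[c.label] = None
                continue
            sp_copies = [
                h for h in homologs.copies(family=family, species=c.species) if h.cds
            ]
            assignment = xp.assign_reads(
                reads[c.species], sp_copies, mismatch_tolerance
            )
            x_same = next((h for h in sp_copies if h.chrom_class == "X"), None)
            profile = xp.build_profile(c, assignment, tuple(tissue_panel), config, x_same)
            transcribed[c.label] = xp.has_transcription_evidence(profile, config)
            patterns[c.label] = profile.pattern
            result.profiles[(family, c.species, c.locus_id)] = profile
    except Exception as e:  # noqa: BLE001
        raise PipelineError("expression", family, e) from e

    fam_evidence = [
        EvidenceRecord(
            family=family,
            species=c.species,
            locus_id=c.locus_id,
            orf_status=orf_status.get(c.label, "disrupted"),
            transcribed=transcribed.get(c.label, False),
            recency=recency.get(c.label, "keep"),
            omega=omegas.get(c.label),
            expression_pattern=patterns.get(c.label),
        )
        for c in a_copies
    ]
    log.info(
        "%s: evidence for %d autosomal copies (%d intact, %d transcribed, %d kept)",
        family,
        len(fam_evidence),
        sum(e.orf_status == "intact" for e in fam_evidence),
        sum(e.transcribed for e in fam_evidence),
        sum(e.recency == "keep" for e in fam_evidence),
    )
    return fam_evidence, calls


def _most_divergent_pair(members: list[GeneCopy], tree: SpeciesTree):
    best = (members[0], members[-1])
    best_d = -1.0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if a.species == b.species:
                continue
            d = tree.divergence_time(a.species, b.species)
            if d > best_d:
                best, best_d = (a, b), d
    return best
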