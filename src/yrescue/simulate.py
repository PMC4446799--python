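"""Synthetic gene families, transposition events and tissue read sets.

The generator plays forward the processes the pipeline is meant to
recover: a stop-free ancestral CDS diverges along the dated species tree
under purifying selection (attempted point mutations arrive as a Poisson
process; synonymous changes always fix, nonsynonymous changes fix with
probability omega, changes creating stops never fix), the X and Y
gametologs split at a chosen age, transposed autosomal copies are planted
on chosen branches with fresh (retro) or parent-derived (DNA transposition)
flanking-gene contexts, Y copies are deleted along chosen lineages, and
tissue-stratified reads are drawn from each surviving copy with uniform
start positions and i.i.d. per-base errors.  Every random choice is
recorded in a truth table so each pipeline stage can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .orf import STOP_CODONS, translate_codon
from .synteny import SyntenyRecord
from .tree import SpeciesTree
from .types import GeneCopy, HomologTable, Read, ReadSet, ValidationError

log = logging.getLogger("yrescue.simulate")

BASES = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]
RECENT_DIVERGENCE = 0.005  # subs/site planted for 'recent' copies (<2% pairwise)


@dataclass(frozen=True)
class EventSpec:
    """A planted transposition: duplication of the parent-class copy onto a
    new autosomal locus at a point ``position`` (fraction of the way down)
    along the named branch.  ``position`` must leave the copy old enough to
    accumulate measurable divergence unless ``recent`` is set, which instead
    plants the copy just before the present (<2% diverged)."""

    family: str
    parent_class: str            # X | Y
    branch_id: str
    mechanism: str = "retro"     # retro | dna
    pseudogenize: bool = False
    recent: bool = False
    position: float = 0.5        # 0 = branch start (older), 1 = branch end

    def __post_init__(self) -> None:
        if self.parent_class not in ("X", "Y"):
            raise ValidationError("parent_class must be X or Y")
        if self.mechanism not in ("retro", "dna"):
            raise ValidationError("mechanism must be retro or dna")
        if not 0.0 <= self.position <= 1.0:
            raise ValidationError("position must be in [0, 1]")


@dataclass
class SimConfig:
    tree: SpeciesTree
    subs_rate: float = 0.002             # substitutions/site/my
    omega_by_copy_class: dict = field(
        default_factory=lambda: {
            "X": 0.1,
            "Y": 0.15,
            "A_functional": 0.1,
            "A_pseudo": 1.0,
        }
    )
    gametolog_split_my: float = 180.0
    event_specs: list = field(default_factory=list)      # list[EventSpec]
    loss_specs: list = field(default_factory=list)       # list[(family, branch_id)]
    cds_length_codons: int = 300
    tissue_panel: tuple[str, ...] = ("brain", "heart", "kidney", "liver", "testis")
    expression_specs: dict = field(default_factory=dict) # key -> (pattern, fold)
    depth: float = 50.0                                  # reads per kb per tissue
    read_length: int = 75
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.omega_by_copy_class.items():
            if v < 0:
                raise ValidationError(f"omega for {k} must be >= 0")
        if "testis" not in self.tissue_panel:
            raise ValidationError("tissue panel must include 'testis'")


@dataclass
class SimTruth:
    parent_class: dict = field(default_factory=dict)      # (family, locus) -> X|Y
    origin_branch: dict = field(default_factory=dict)     # (family, locus) -> branch_id
    pseudogenized: dict = field(default_factory=dict)     # (family, locus) -> bool
    recent: dict = field(default_factory=dict)            # (family, locus) -> bool
    locus_groups: dict = field(default_factory=dict)      # (family, locus) -> carrier set
    substitutions: dict = field(default_factory=dict)     # label -> (syn, nonsyn)
    read_origin: dict = field(default_factory=dict)       # (species, read id) -> copy label


# ---------------------------------------------------------------------------
# Codon-level evolution

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Stop-free CDS: ATG + random sense codons + terminal TAA."""
    if n_codons < 3:
        raise ValidationError("need at least 3 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def evolve_codon_sequence(
    cds: str,
    branch_length_subs_per_site: float,
    omega: float,
    rng,
) -> tuple[str, tuple[int, int]]:
    """Evolve a stop-free in-frame CDS along a branch.

    The number of attempted mutations is Poisson(branch_length x length);
    each attempt picks a uniform site and a uniform alternative base.
    Synonymous changes are always accepted, nonsynonymous changes with
    probability omega, and changes creating a stop codon are rejected.
    Returns (new_cds, (synonymous, nonsynonymous) accepted counts).
    """
    if branch_length_subs_per_site < 0:
        raise ValidationError("branch length must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    seq = list(cds)
    L = len(seq)
    n_attempts = rng.poisson(branch_length_subs_per_site * L)
    syn = nonsyn = 0
    for _ in range(int(n_attempts)):
        site = int(rng.integers(0, L))
        old = seq[site]
        alt = [b for b in BASES if b != old][int(rng.integers(0, 3))]
        codon_start = site - site % 3
        codon = "".join(seq[codon_start : codon_start + 3])
        mutant = codon[: site % 3] + alt + codon[site % 3 + 1 :]
        if mutant in STOP_CODONS:
            continue
        if translate_codon(mutant) == translate_codon(codon):
            seq[site] = alt
            syn += 1
        elif rng.random() < omega:
            seq[site] = alt
            nonsyn += 1
    return "".join(seq), (syn, nonsyn)


# ---------------------------------------------------------------------------
# Family simulation

def _fresh_flanks(family: str, tag: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return (
        (f"{family}_{tag}_U1", f"{family}_{tag}_U2"),
        (f"{family}_{tag}_D1", f"{family}_{tag}_D2"),
    )


def simulate_family(
    config: SimConfig, family: str = "FAM1", rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneCopy], list[SyntenyRecord], HomologTable, SimTruth]:
    """Simulate one gene family along the configured species tree.

    The ancestral CDS splits into X and Y gametologs ``gametolog_split_my``
    ago, both evolve down the tree, autosomal copies are planted per the
    family's event specs (on the stem of the named branch; or near the tip
    for ``recent`` events so the copy stays <2% diverged), and Y copies are
    deleted below the family's loss specs.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _stable_hash(family)])
    tree = config.tree
    events = [e for e in config.event_specs if e.family == family]
    losses = [(f, b) for f, b in config.loss_specs if f == family]
    branch_ids = {tree.branch_id(n) for n in tree.tree.preorder_node_iter()}
    for e in events:
        if e.branch_id not in branch_ids:
            raise ValidationError(f"event branch {e.branch_id!r} not in tree")
    for _, b in losses:
        if b not in branch_ids:
            raise ValidationError(f"loss branch {b!r} not in tree")
    omega = config.omega_by_copy_class
    anc = random_cds(config.cds_length_codons, rng)
    core = anc[3:-3]  # evolve between the fixed start and terminal stop
    truth = SimTruth()

    root_age = tree.root_age
    extra_my = max(0.0, config.gametolog_split_my - root_age)
    x0, _ = evolve_codon_sequence(core, config.subs_rate * extra_my, omega["X"], rng)
    y0, _ = evolve_codon_sequence(core, config.subs_rate * extra_my, omega["Y"], rng)

    events_by_branch: dict[str, list[EventSpec]] = {}
    for idx, e in enumerate(events):
        events_by_branch.setdefault(e.branch_id, []).append(e)
    event_index = {id(e): i for i, e in enumerate(events)}
    loss_branches = {b for _, b in losses}
    pseudo_stop_pos: dict[int, int] = {}
    flanks_by_event: dict[int, tuple] = {}
    for i, e in enumerate(events):
        if e.mechanism == "dna":
            # DNA transposition carries the parent chromosome's neighborhood
            flanks_by_event[i] = _fresh_flanks(family, f"{e.parent_class}chrom")
        else:
            flanks_by_event[i] = _fresh_flanks(family, f"ev{i}")

    copies: list[GeneCopy] = []
    synteny: list[SyntenyRecord] = []

    def locus_name(i: int) -> str:
        return f"{family}_A{i}"

    def _omega_for(key) -> float:
        if key in ("X", "Y"):
            return omega[key]
        return (
            omega["A_pseudo"]
            if truth.pseudogenized.get((family, locus_name(key[1])))
            else omega["A_functional"]
        )

    def _evolve_all(seqs: dict, bl: float) -> dict:
        return {
            key: evolve_codon_sequence(seq, bl, _omega_for(key), rng)[0]
            for key, seq in seqs.items()
        }

    def descend(node, seqs: dict):
        bid = tree.branch_id(node)
        my = node.edge.length or 0.0
        bl = config.subs_rate * my
        branch_events = [
            e for e in events_by_branch.get(bid, []) if not e.recent
        ]
        if branch_events:
            # duplications happen part-way along the branch (never at its
            # ends), so the new copy shares an internal branch with its
            # parent lineage in the gene tree
            new_seqs = dict(seqs)
            t = 0.0
            for e in sorted(branch_events, key=lambda e: (e.position, event_index[id(e)])):
                i = event_index[id(e)]
                new_seqs = _evolve_all(new_seqs, (e.position - t) * bl)
                t = e.position
                if e.parent_class not in new_seqs:
                    raise ValidationError(
                        f"event on branch {bid} copies from deleted parent {e.parent_class}"
                    )
                seed_seq = new_seqs[e.parent_class]
                if e.pseudogenize:
                    # disruption position chosen once per event; applied at
                    # emission so later evolution cannot silently revert it
                    pseudo_stop_pos[i] = int(rng.integers(0, len(seed_seq) // 3))
                    truth.pseudogenized[(family, locus_name(i))] = True
                new_seqs[("A", i)] = seed_seq
                truth.parent_class[(family, locus_name(i))] = e.parent_class
                truth.origin_branch[(family, locus_name(i))] = bid
                truth.recent[(family, locus_name(i))] = False
                truth.pseudogenized.setdefault((family, locus_name(i)), False)
            new_seqs = _evolve_all(new_seqs, (1.0 - t) * bl)
        else:
            new_seqs = _evolve_all(seqs, bl)
        if bid in loss_branches:
            new_seqs.pop("Y", None)
        if node.is_leaf():
            species = node.taxon.label
            # recent events target this terminal branch
            for e in events_by_branch.get(bid, []):
                if not e.recent:
                    continue
                i = event_index[id(e)]
                if e.parent_class not in new_seqs:
                    raise ValidationError(
                        f"recent event on {bid}: parent {e.parent_class} deleted"
                    )
                seed_seq = new_seqs[e.parent_class]
                if e.pseudogenize:
                    pseudo_stop_pos[i] = int(rng.integers(0, len(seed_seq) // 3))
                    truth.pseudogenized[(family, locus_name(i))] = True
                evolved, _ = evolve_codon_sequence(
                    seed_seq, RECENT_DIVERGENCE, omega["A_functional"], rng
                )
                new_seqs[("A", i)] = evolved
                truth.parent_class[(family, locus_name(i))] = e.parent_class
                truth.origin_branch[(family, locus_name(i))] = bid
                truth.recent[(family, locus_name(i))] = True
                truth.pseudogenized.setdefault((family, locus_name(i)), False)
            for key, seq in sorted(new_seqs.items(), key=str):
                cds = "ATG" + seq + "TAA"
                if key == "X":
                    copies.append(
                        GeneCopy(family, species, "X", f"{family}_X", cds=cds)
                    )
                elif key == "Y":
                    copies.append(
                        GeneCopy(family, species, "Y", f"{family}_Y", cds=cds)
                    )
                else:
                    i = key[1]
                    e = events[i]
                    locus = locus_name(i)
                    if i in pseudo_stop_pos:
                        p = pseudo_stop_pos[i]
                        core_seq = seq[: 3 * p] + "TAA" + seq[3 * p + 3 :]
                        cds = "ATG" + core_seq + "TAA"
                    copies.append(
                        GeneCopy(
                            family,
                            species,
                            "A",
                            locus,
                            cds=cds,
                            has_introns=(e.mechanism == "dna"),
                            mechanism_hint=e.mechanism,
                        )
                    )
                    up, down = flanks_by_event[i]
                    synteny.append(
                        SyntenyRecord(
                            family=family,
                            species=species,
                            locus_id=locus,
                            upstream=up,
                            downstream=down,
                        )
                    )
                    truth.locus_groups.setdefault((family, locus), set()).add(species)
        else:
            for child in node.child_nodes():
                descend(child, new_seqs)

    descend(tree.tree.seed_node, {"X": x0, "Y": y0})
    table = HomologTable(copies)
    return copies, synteny, table, truth


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# Standard four-family scenario

def standard_scenario(tree: SpeciesTree, seed: int) -> dict[str, SimConfig]:
    """Per-family configurations for the standard benchmark scenario.

    Four families mirror the canonical rescue cases: a Y-derived rodent
    retrogene (with rodent-stem Y loss), an X-derived ape retrogene with
    simian-wide Y loss, an X-derived marsupial-stem retrogene, and a
    Y-derived DNA transposition on the marmoset branch.  Each family's
    autosomal omega follows the published pairwise estimate for the case
    it emulates (0.0010, 0.075, 0.0132, 0.3381), and events sit early
    enough on their branches that the copies are diverged well past the
    2% recency cutoff — as every reported real event is.
    """
    rodent = tree.branch_id(tree.mrca(["mouse", "rat"]))
    apes = tree.branch_id(tree.mrca(["human", "chimpanzee", "gorilla", "orangutan"]))
    simians = tree.branch_id(tree.mrca(["human", "baboon", "marmoset"]))
    marsup = tree.branch_id(tree.mrca(["opossum", "wallaby"]))
    cases = {
        "FAM1": (EventSpec("FAM1", "Y", rodent, position=0.5), rodent, 0.0010),
        "FAM2": (EventSpec("FAM2", "X", apes, position=0.1), simians, 0.075),
        "FAM3": (EventSpec("FAM3", "X", marsup, position=0.5), marsup, 0.0132),
        "FAM4": (
            EventSpec("FAM4", "Y", "marmoset", mechanism="dna", position=0.1),
            "marmoset",
            0.3381,
        ),
    }
    configs = {}
    for fam, (event, loss_branch, omega_a) in cases.items():
        cfg = SimConfig(tree=tree, seed=seed)
        cfg.omega_by_copy_class = dict(cfg.omega_by_copy_class, A_functional=omega_a)
        cfg.event_specs = [event]
        cfg.loss_specs = [(fam, loss_branch)]
        configs[fam] = cfg
    return configs


def simulate_scenario(tree: SpeciesTree, seed: int, read_seed: Optional[int] = None):
    """Simulate the standard scenario end to end.

    Returns (HomologTable, synteny records, reads-by-species, truth events
    as a set of (family, branch_id)).
    """
    configs = standard_scenario(tree, seed)
    copies, synteny, truth_events = [], [], set()
    for fam, cfg in configs.items():
        c, s, _, truth = simulate_family(cfg, fam)
        copies += c
        synteny += s
        for (f, _locus), branch in truth.origin_branch.items():
            truth_events.add((f, branch))
    any_cfg = next(iter(configs.values()))
    reads, _ = simulate_reads(
        copies,
        {},
        depth=any_cfg.depth,
        read_length=any_cfg.read_length,
        error_rate=any_cfg.error_rate,
        seed=read_seed if read_seed is not None else seed + 1,
        tissue_panel=any_cfg.tissue_panel,
    )
    return HomologTable(copies), synteny, reads, truth_events


# ---------------------------------------------------------------------------
# Read simulation

def _tissue_multiplier(pattern: str, fold: float, tissue: str) -> float:
    if pattern == "silent":
        return 0.0
    if pattern == "testis_specific":
        return 1.0 if tissue == "testis" else 1.0 / fold
    return 1.0  # broad


def simulate_reads(
    copies: list[GeneCopy],
    expression_specs: dict,
    depth: float,
    read_length: int,
    error_rate: float,
    seed,
    tissue_panel: tuple[str, ...] = ("brain", "heart", "kidney", "liver", "testis"),
) -> tuple[dict[str, ReadSet], SimTruth]:
    """Draw tissue-stratified reads from each copy.

    Per tissue and copy the read count is round(depth x CDS-kb x pattern
    multiplier); start positions are uniform; per-base errors are i.i.d.
    at ``error_rate``.  Returns one ReadSet per species plus per-read truth
    origins.  ``expression_specs`` maps a copy label — or a
    (family, chrom_class) fallback — to (pattern, fold).
    """
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = SimTruth()
    by_species: dict[str, list[Read]] = {}
    for copy in sorted(copies, key=lambda c: c.label):
        if copy.cds is None:
            continue
        if read_length > len(copy.cds):
            raise ValidationError(
                f"read_length {read_length} exceeds CDS length of {copy.label}"
            )
        spec = expression_specs.get(copy.label) or expression_specs.get(
            (copy.family, copy.chrom_class), ("broad", 1.0)
        )
        pattern, fold = spec
        len_kb = len(copy.cds) / 1000.0
        arr = np.frombuffer(copy.cds.encode(), dtype=np.uint8)
        base_idx = {ord(b): k for k, b in enumerate(BASES)}
        for tissue in tissue_panel:
            count = int(round(depth * len_kb * _tissue_multiplier(pattern, fold, tissue)))
            if count <= 0:
                continue
            starts = rng.integers(0, len(copy.cds) - read_length + 1, size=count)
            for ri, start in enumerate(starts):
                seq = bytearray(arr[start : start + read_length])
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                for pos in errs:
                    old = base_idx.get(seq[pos], 0)
                    seq[pos] = ord(BASES[(old + 1 + int(rng.integers(0, 3))) % 4])
                rid = f"{copy.label}:{tissue}:{ri}"
                by_species.setdefault(copy.species, []).append(
                    Read(
                        identifier=rid,
                        sequence=seq.decode(),
                        tissue=tissue,
                        species=copy.species,
                    )
                )
                truth.read_origin[(copy.species, rid)] = copy.label
    readsets = {
        sp: ReadSet(reads=rl, read_length=read_length, tissue_panel=tuple(tissue_panel))
        for sp, rl in sorted(by_species.items())
    }
    return readsets, truth
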