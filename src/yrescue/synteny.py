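"""Synteny grouping and dating of transposed loci.

Two transposed loci in different species that sit in the same flanking-gene
context descend from a single insertion event; the divergence time of the
carrier species then lower-bounds the event's age.  Order consistency of
the shared flank symbols is checked with a longest-common-subsequence test;
an inverted-but-shared context needs one extra shared symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree import SpeciesTree
from .types import AnalysisConfig, ValidationError


@dataclass(frozen=True)
class SyntenyRecord:
    family: str
    species: str
    locus_id: str
    upstream: tuple[str, ...]   # ordered, nearest-last
    downstream: tuple[str, ...]  # ordered, nearest-first

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValidationError(
                f"flanking gene lists must be non-empty "
                f"({self.family}/{self.species}/{self.locus_id})"
            )

    @property
    def ordered_flanks(self) -> tuple[str, ...]:
        return self.upstream + self.downstream

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.locus_id)


def _lcs_length(xs, ys) -> int:
    prev = [0] * (len(ys) + 1)
    for x in xs:
        cur = [0]
        for j, y in enumerate(ys):
            cur.append(max(prev[j] + 1 if x == y else 0, prev[j + 1], cur[-1]))
        prev = cur
    return prev[-1]


def is_syntenic(a: SyntenyRecord, b: SyntenyRecord, config: AnalysisConfig) -> bool:
    """True iff the two loci share enough flank symbols in consistent order.

    Shared symbols in consistent relative order count toward
    ``synteny_min_shared_flanks``; if the shared symbols are present but
    order-inconsistent (inversion), one extra shared symbol is required.
    Symmetric in its arguments.
    """
    fa = a.ordered_flanks
    fb = b.ordered_flanks
    shared = set(fa) & set(fb)
    if not shared:
        return False
    sa = [g for g in fa if g in shared]
    sb = [g for g in fb if g in shared]
    n_shared = len(shared)
    ordered = _lcs_length(sa, sb) >= n_shared
    if ordered:
        return n_shared >= config.synteny_min_shared_flanks
    return n_shared >= config.synteny_min_shared_flanks + 1


def locus_groups(
    records: list[SyntenyRecord], config: AnalysisConfig
) -> list[frozenset[tuple[str, str]]]:
    """Partition (species, locus_id) pairs into shared-origin groups.

    Transitive closure of pairwise synteny; every group is one candidate
    origination event.  All records must belong to one gene family.
    """
    families = {r.family for r in records}
    if len(families) > 1:
        raise ValidationError(f"locus_groups called across families: {sorted(families)}")
    parent: dict[tuple[str, str], tuple[str, str]] = {r.key: r.key for r in records}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if a.species != b.species and is_syntenic(a, b, config):
                ra, rb = find(a.key), find(b.key)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for r in records:
        groups.setdefault(find(r.key), set()).add(r.key)
    return sorted(
        (frozenset(g) for g in groups.values()), key=lambda g: sorted(g)
    )


def min_origin_age(group, tree: SpeciesTree) -> float:
    """Lower bound (my) on the age of the insertion shared by a locus group.

    The maximum pairwise divergence time among the group's carrier species;
    0 for a singleton (no cross-species bound).
    """
    species = sorted({s for s, _ in group})
    if not species:
        raise ValidationError("empty locus group")
    age = 0.0
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            age = max(age, tree.divergence_time(sa, sb))
    return age
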