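"""Hennigian argumentation: synapomorphy grouping, conflict arbitration,
and cladogram construction.

The procedure mechanised here is the classical one: every character whose
derived state is shared by two or more taxa proposes a clade; two proposals
conflict when their taxon sets overlap without nesting; conflicts are
arbitrated by parsimony (keep the proposals that minimise the number of
characters demoted to convergence), and the accepted, pairwise-compatible
clades assemble into a rooted cladogram, unplaced taxa joining the root
polytomy.

Characters with missing cells support, by default, the clade of their
observed derived taxa, and may join an existing proposal whose extra
members are exactly taxa unscored for the character (``missing_mode=
"observed"``); the ``"strict"`` mode demotes such characters to unplaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix import ResolvedMatrix, derived_taxon_set, missing_taxon_set
from .parsimony import reconstruct
from .tree import Cladogram, tree_from_clades

__all__ = [
    "CladeHypothesis",
    "ArgumentationReport",
    "characters_compatible",
    "group_by_synapomorphy",
    "arbitrate",
    "build_cladogram",
]


@dataclass
class CladeHypothesis:
    """A candidate clade and the characters whose derived state defines it."""

    taxa: frozenset[str]
    supporting_chars: set[int]
    status: str = "proposed"  # proposed | accepted | conflicted

    @property
    def min_char(self) -> int:
        return min(self.supporting_chars)


@dataclass
class ArgumentationReport:
    """Character-by-character outcome of the argumentation.

    Every character id lands in exactly one bucket: support of an accepted
    clade (the all-taxa clade records the group's clade-level
    autapomorphies), an autapomorphy of a single taxon, or a convergence
    with its independent origins enumerated.
    """

    taxa: list[str]
    accepted_clades: list[CladeHypothesis]
    autapomorphies: dict[str, set[int]]
    convergences: dict[int, list[frozenset[str]]]
    conflicts: list[tuple[frozenset[int], frozenset[int], str]]
    uninformative: set[int] = field(default_factory=set)

    @property
    def convergent_ids(self) -> set[int]:
        return set(self.convergences)

    def character_accounting(self) -> dict[str, set[int]]:
        support = set().union(
            *(h.supporting_chars for h in self.accepted_clades), set()
        )
        autapo = set().union(*self.autapomorphies.values(), set())
        return {
            "clade_support": support,
            "autapomorphies": autapo,
            "convergences": set(self.convergences),
            "uninformative": set(self.uninformative),
        }


def characters_compatible(set_a: frozenset[str], set_b: frozenset[str]) -> bool:
    """Pairwise compatibility of two derived taxon sets: nested or disjoint."""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    return set_a <= set_b or set_b <= set_a or not (set_a & set_b)


def group_by_synapomorphy(
    matrix: ResolvedMatrix, missing_mode: str = "observed"
) -> tuple[list[CladeHypothesis], list[tuple[CladeHypothesis, CladeHypothesis]]]:
    """One clade hypothesis per distinct derived taxon set of size >= 2.

    Characters whose derived set is a singleton are routed to
    autapomorphies by :func:`arbitrate`; characters with missing cells
    join an existing hypothesis when the unobserved taxa account exactly
    for the difference.  Returns the hypotheses and the list of pairwise
    conflicts.
    """
    if missing_mode not in ("observed", "strict"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")
    by_taxa: dict[frozenset[str], CladeHypothesis] = {}
    complete: list[tuple[int, frozenset[str]]] = []
    with_missing: list[tuple[int, frozenset[str], frozenset[str]]] = []
    for char in matrix.characters:
        derived = frozenset(derived_taxon_set(matrix, char.id))
        missing = frozenset(missing_taxon_set(matrix, char.id))
        if len(derived) < 2:
            continue
        if missing and missing_mode == "strict":
            continue
        if missing:
            with_missing.append((char.id, derived, missing))
        else:
            complete.append((char.id, derived))

    for char_id, derived in complete:
        hyp = by_taxa.setdefault(derived, CladeHypothesis(derived, set()))
        hyp.supporting_chars.add(char_id)

    for char_id, derived, missing in with_missing:
        candidates = [
            taxa
            for taxa in by_taxa
            if derived <= taxa <= derived | missing
        ]
        if candidates:
            target = min(candidates, key=lambda t: (len(t), sorted(t)))
        else:
            target = derived
        hyp = by_taxa.setdefault(target, CladeHypothesis(target, set()))
        hyp.supporting_chars.add(char_id)

    hypotheses = sorted(by_taxa.values(), key=lambda h: (h.min_char,))
    conflicts = [
        (a, b)
        for i, a in enumerate(hypotheses)
        for b in hypotheses[i + 1 :]
        if not characters_compatible(a.taxa, b.taxa)
    ]
    return hypotheses, conflicts


def arbitrate(
    hypotheses: list[CladeHypothesis],
    conflicts: list[tuple[CladeHypothesis, CladeHypothesis]],
    matrix: ResolvedMatrix,
) -> ArgumentationReport:
    """Greedy maximum-weight compatible subset of clade hypotheses.

    A hypothesis weighs its own supporting characters plus those of every
    conflict-free hypothesis nested with it (the corroborating context of
    the groups it sits inside or contains).  Hypotheses are accepted in
    decreasing weight, ties to the lower minimum character id; a hypothesis
    incompatible with an accepted one is demoted, its characters becoming
    convergences whose independent origins are read off the resulting
    cladogram.  A hypothesis that conflicts with nothing is always accepted.
    """
    taxa = list(matrix.taxa)
    all_taxa = frozenset(taxa)
    in_conflict: set[int] = set()
    for a, b in conflicts:
        in_conflict.add(id(a))
        in_conflict.add(id(b))
    conflict_free = [h for h in hypotheses if id(h) not in in_conflict]

    def weight(h: CladeHypothesis) -> int:
        w = len(h.supporting_chars)
        for other in conflict_free:
            if other is h:
                continue
            if other.taxa <= h.taxa or h.taxa <= other.taxa:
                w += len(other.supporting_chars)
        return w

    ranked = sorted(hypotheses, key=lambda h: (-weight(h), h.min_char))
    accepted: list[CladeHypothesis] = []
    rejected: list[CladeHypothesis] = []
    for hyp in ranked:
        if all(characters_compatible(hyp.taxa, a.taxa) for a in accepted):
            hyp.status = "accepted"
            accepted.append(hyp)
        else:
            hyp.status = "conflicted"
            rejected.append(hyp)

    # autapomorphies and uninformative characters
    autapomorphies: dict[str, set[int]] = {}
    uninformative: set[int] = set()
    placed = set().union(*(h.supporting_chars for h in hypotheses), set())
    for char in matrix.characters:
        if char.id in placed:
            continue
        derived = derived_taxon_set(matrix, char.id)
        if len(derived) == 1:
            autapomorphies.setdefault(next(iter(derived)), set()).add(char.id)
        else:
            uninformative.add(char.id)

    accepted.sort(key=lambda h: (-len(h.taxa), h.min_char))
    tree = tree_from_clades((h.taxa for h in accepted), taxa)

    # enumerate the independent origins of each demoted character
    convergences: dict[int, list[frozenset[str]]] = {}
    if rejected:
        recs = {r.char_id: r for r in reconstruct(tree, matrix)}
        for hyp in rejected:
            for char_id in sorted(hyp.supporting_chars):
                origins = sorted(
                    recs[char_id].origin_edges, key=lambda e: (len(e), sorted(e))
                )
                convergences[char_id] = origins

    conflict_entries = [
        (
            frozenset(a.supporting_chars),
            frozenset(b.supporting_chars),
            _resolution_note(a, b),
        )
        for a, b in conflicts
    ]
    return ArgumentationReport(
        taxa=taxa,
        accepted_clades=accepted,
        autapomorphies=autapomorphies,
        convergences=convergences,
        conflicts=conflict_entries,
        uninformative=uninformative,
    )


def _resolution_note(a: CladeHypothesis, b: CladeHypothesis) -> str:
    def tag(h: CladeHypothesis) -> str:
        chars = ",".join(map(str, sorted(h.supporting_chars)))
        return f"chars {{{chars}}} ({h.status})"

    return f"{tag(a)} vs {tag(b)}"


def build_cladogram(report: ArgumentationReport, taxa: list[str] | None = None) -> Cladogram:
    """The minimal rooted tree displaying exactly the accepted clades."""
    taxa = list(taxa or report.taxa)
    return tree_from_clades((h.taxa for h in report.accepted_clades), taxa)
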