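"""Dichotomous identification keys.

A key is a numbered set of couplets; each couplet offers two contrasting
leads, and each lead points either to another couplet or to a terminal
taxon.  A valid key is an acyclic binary routing in which every taxon is
reached by exactly one lead — hence ``couplets == taxa - 1``.

Leads carry free text (keys routinely use characters that never enter a
phylogenetic matrix); an optional machine-readable predicate
``(char_id, state)`` allows consistency checks against a matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

from .matrix import ResolvedMatrix, derived_taxon_set, missing_taxon_set

__all__ = [
    "Lead",
    "DichotomousKey",
    "KeyViolation",
    "validate_key",
    "identify",
    "generate_key",
    "render_key",
    "load_key",
    "save_key",
]

Target = Union[int, str]  # couplet id or taxon label


@dataclass(frozen=True)
class Lead:
    """One half of a couplet: a statement and where agreeing with it leads."""

    text: str
    target: Target
    predicate: tuple[int, str] | None = None  # (char_id, "0"/"1")

    @property
    def is_terminal(self) -> bool:
        return isinstance(self.target, str)


@dataclass
class DichotomousKey:
    couplets: dict[int, tuple[Lead, Lead]]
    start: int = 1

    @property
    def taxa(self) -> list[str]:
        """Terminal taxa in couplet order (lead a before lead b)."""
        out = []
        for cid in sorted(self.couplets):
            for lead in self.couplets[cid]:
                if lead.is_terminal:
                    out.append(lead.target)
        return out


@dataclass(frozen=True)
class KeyViolation:
    couplet: int | None
    kind: str
    detail: str


def validate_key(key: DichotomousKey) -> list[KeyViolation]:
    """Check the key invariants; an empty report means the key is valid.

    Checks: two leads per couplet (by construction), the start couplet
    exists, lead targets exist, every couplet is reachable from the start,
    no couplet can reach itself, and every taxon is the target of exactly
    one lead.
    """
    violations: list[KeyViolation] = []
    if key.start not in key.couplets:
        violations.append(
            KeyViolation(None, "missing-start", f"start couplet {key.start} absent")
        )
        return violations

    successors: dict[int, list[int]] = {}
    taxon_hits: dict[str, int] = {}
    for cid, leads in key.couplets.items():
        successors[cid] = []
        for lead in leads:
            if lead.is_terminal:
                taxon_hits[lead.target] = taxon_hits.get(lead.target, 0) + 1
            elif lead.target not in key.couplets:
                violations.append(
                    KeyViolation(cid, "dangling-target",
                                 f"lead points to missing couplet {lead.target}")
                )
            else:
                successors[cid].append(lead.target)

    # reachability from start
    seen: set[int] = set()
    frontier = [key.start]
    while frontier:
        cid = frontier.pop()
        if cid in seen:
            continue
        seen.add(cid)
        frontier.extend(successors.get(cid, []))
    for cid in sorted(set(key.couplets) - seen):
        violations.append(
            KeyViolation(cid, "unreachable", "couplet unreachable from start")
        )

    # cycle detection (a couplet reachable from itself)
    state: dict[int, int] = {}

    def dfs(cid: int) -> bool:
        state[cid] = 1
        for nxt in successors.get(cid, []):
            if state.get(nxt) == 1:
                return True
            if state.get(nxt) is None and dfs(nxt):
                return True
        state[cid] = 2
        return False

    for cid in key.couplets:
        if state.get(cid) is None and dfs(cid):
            violations.append(KeyViolation(cid, "cycle", "couplet reaches itself"))

    for taxon, count in sorted(taxon_hits.items()):
        if count > 1:
            violations.append(
                KeyViolation(None, "duplicate-terminal",
                             f"taxon {taxon} is the target of {count} leads")
            )
    return violations


def identify(key: DichotomousKey, choices: Sequence[str]) -> Target:
    """Follow a/b choices from the start couplet.

    Returns the identified taxon if a terminal lead is reached, or the id of
    the pending couplet if the choices run out first.  Raises ``ValueError``
    on input left over after a terminal lead.
    """
    position: Target = key.start
    for step, choice in enumerate(choices):
        if isinstance(position, str):
            raise ValueError(
                f"trailing input {list(choices[step:])!r} after reaching "
                f"{position}"
            )
        if choice not in ("a", "b"):
            raise ValueError(f"choice {choice!r} at step {step}: must be 'a' or 'b'")
        lead_a, lead_b = key.couplets[position]
        position = (lead_a if choice == "a" else lead_b).target
    return position


def generate_key(
    matrix: ResolvedMatrix,
    descriptions: Mapping[int, tuple[str, str]] | None = None,
) -> DichotomousKey:
    """Build a key from a resolved matrix by greedy balanced splitting.

    At each node the character splitting the remaining taxa most evenly is
    chosen (only characters scored 0/1, without missing cells, across all
    remaining taxa are usable; ties go to the lowest character id).  Lead a
    carries the derived condition.  Raises ``ValueError`` naming a pair of
    taxa that no character separates.
    """
    if descriptions is None:
        descriptions = {
            c.id: (c.description, c.plesiomorphic_description or
                   f"not: {c.description}")
            for c in matrix.characters
        }
    char_ids = [c.id for c in matrix.characters]
    derived = {cid: derived_taxon_set(matrix, cid) for cid in char_ids}
    missing = {cid: missing_taxon_set(matrix, cid) for cid in char_ids}

    couplets: dict[int, tuple[Lead, Lead]] = {}
    counter = [0]

    def best_split(group: list[str]) -> int | None:
        group_set = set(group)
        best: tuple[int, int] | None = None
        for cid in char_ids:
            if group_set & missing[cid]:
                continue
            inside = len(group_set & derived[cid])
            if inside == 0 or inside == len(group_set):
                continue
            score = abs(2 * inside - len(group_set))
            if best is None or (score, cid) < best:
                best = (score, cid)
        return best[1] if best else None

    def build(group: list[str]) -> int:
        cid = best_split(group)
        if cid is None:
            a, b = sorted(group)[:2]
            raise ValueError(
                f"taxa {a!r} and {b!r} cannot be separated by any usable "
                "character"
            )
        counter[0] += 1
        my_id = counter[0]
        couplets[my_id] = (Lead("", 0), Lead("", 0))  # placeholder, keeps numbering
        on = sorted(t for t in group if t in derived[cid])
        off = sorted(t for t in group if t not in derived[cid])
        apo_text, plesio_text = descriptions[cid]

        def make_lead(text: str, members: list[str], state: str) -> Lead:
            if len(members) == 1:
                return Lead(text, members[0], predicate=(cid, state))
            return Lead(text, build(members), predicate=(cid, state))

        lead_a = make_lead(apo_text, on, "1")
        lead_b = make_lead(plesio_text, off, "0")
        couplets[my_id] = (lead_a, lead_b)
        return my_id

    start = build(list(matrix.taxa))
    return DichotomousKey(couplets=couplets, start=start)


def check_predicates(key: DichotomousKey, matrix: ResolvedMatrix) -> list[KeyViolation]:
    """For leads carrying a predicate, verify that every taxon reachable
    through the lead actually shows the stated state (missing cells pass)."""
    violations: list[KeyViolation] = []

    def taxa_below(target: Target) -> list[str]:
        if isinstance(target, str):
            return [target]
        out = []
        for lead in key.couplets[target]:
            out.extend(taxa_below(lead.target))
        return out

    for cid, leads in key.couplets.items():
        for lead in leads:
            if lead.predicate is None:
                continue
            char_id, state = lead.predicate
            wanted = derived_taxon_set(matrix, char_id)
            unknown = missing_taxon_set(matrix, char_id)
            for taxon in taxa_below(lead.target):
                if taxon in unknown:
                    continue
                if (taxon in wanted) != (state == "1"):
                    violations.append(
                        KeyViolation(cid, "predicate-mismatch",
                                     f"{taxon} contradicts char {char_id}={state}")
                    )
    return violations


# --- serialization ---------------------------------------------------------


def _key_to_obj(key: DichotomousKey) -> dict:
    return {
        "start": key.start,
        "couplets": {
            str(cid): [
                {
                    "text": lead.text,
                    "target": lead.target,
                    **(
                        {"predicate": {"char": lead.predicate[0],
                                       "state": lead.predicate[1]}}
                        if lead.predicate else {}
                    ),
                }
                for lead in leads
            ]
            for cid, leads in key.couplets.items()
        },
    }


def _key_from_obj(obj: Mapping) -> DichotomousKey:
    couplets = {}
    for cid, leads in obj["couplets"].items():
        parsed = []
        for lead in leads:
            predicate = None
            if "predicate" in lead:
                predicate = (int(lead["predicate"]["char"]),
                             str(lead["predicate"]["state"]))
            parsed.append(Lead(lead["text"], lead["target"], predicate))
        if len(parsed) != 2:
            raise ValueError(f"couplet {cid}: needs exactly two leads")
        couplets[int(cid)] = (parsed[0], parsed[1])
    return DichotomousKey(couplets=couplets, start=int(obj.get("start", 1)))


def save_key(key: DichotomousKey, path: str | Path) -> None:
    """Write a key as YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    obj = _key_to_obj(key)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=True))
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_key(path: str | Path) -> DichotomousKey:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return _key_from_obj(yaml.safe_load(text))
    return _key_from_obj(json.loads(text))


def render_key(key: DichotomousKey, names: Mapping[str, str] | None = None) -> str:
    """Plain-text rendering in the conventional two-lead layout."""
    names = names or {}
    lines = []
    for cid in sorted(key.couplets):
        lead_a, lead_b = key.couplets[cid]
        for prefix, lead in ((str(cid), lead_a), ("-", lead_b)):
            target = (
                names.get(lead.target, lead.target)
                if lead.is_terminal
                else str(lead.target)
            )
            lines.append(f"{prefix}\t{lead.text}\t{target}")
    return "\n".join(lines) + "\n"
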