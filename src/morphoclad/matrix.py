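"""Polarity-coded character matrices: data model, polarity policies, and I/O.

A :class:`CharacterMatrix` holds binary morphological characters scored for a
set of taxa, in the character-rows x taxon-columns layout of a published
character table.  Uncertainty codes (``?``, ``1?``, ``0?``, ``0*``) are kept
verbatim; :func:`apply_polarity_policy` reduces them deterministically to
{0, 1, missing} before any parsimony computation.

File formats: CSV/TSV (first column = character id, second = description,
remaining columns = taxa) and NEXUS (``DATATYPE=STANDARD SYMBOLS="01"
MISSING=?``) with a private ``MORPHOCLAD`` block preserving descriptions and
uncertainty codes so the round trip is lossless.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .states import RESOLVED, StateCode

__all__ = [
    "CharacterDefinition",
    "CharacterMatrix",
    "ResolvedMatrix",
    "MatrixFormatError",
    "load_matrix",
    "write_matrix",
    "write_nexus",
    "apply_polarity_policy",
    "derived_taxon_set",
    "POLARITY_POLICIES",
]


class MatrixFormatError(ValueError):
    """Malformed matrix file (bad header, ragged row, or unknown token)."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One binary character: the derived condition and its ancestral state."""

    id: int
    description: str
    plesiomorphic_description: str = ""
    source_anchor: str = ""

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError(f"character {self.id}: empty description")


class CharacterMatrix:
    """Taxa x characters grid of :class:`StateCode` cells.

    Parameters
    ----------
    taxa:
        Ordered taxon labels (unique).
    characters:
        Ordered :class:`CharacterDefinition` (ids unique).
    cells:
        ``cells[i][j]`` is the state of character ``i`` in taxon ``j``.
    convergence_annotations:
        ``(char_id, taxon)`` pairs flagged in the source as convergent
        occurrences of the derived state (bold cells of a published table).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDefinition],
        cells: Sequence[Sequence[StateCode]],
        convergence_annotations: Iterable[tuple[int, str]] = (),
    ) -> None:
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.convergence_annotations = set(convergence_annotations)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if not self.taxa:
            raise ValueError("matrix has no taxa")
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character ids")
        if len(self.cells) != len(self.characters):
            raise ValueError(
                f"{len(self.cells)} cell rows for {len(self.characters)} characters"
            )
        for i, row in enumerate(self.cells):
            if len(row) != len(self.taxa):
                raise ValueError(
                    f"character row {i} has {len(row)} cells for {len(self.taxa)} taxa"
                )
        index = self._index = {c.id: i for i, c in enumerate(self.characters)}
        taxon_index = self._taxon_index = {t: j for j, t in enumerate(self.taxa)}
        for char_id, taxon in self.convergence_annotations:
            if char_id not in index or taxon not in taxon_index:
                raise ValueError(f"annotation ({char_id}, {taxon}) off the grid")
            if self.cells[index[char_id]][taxon_index[taxon]] is not StateCode.APOMORPHIC:
                raise ValueError(
                    f"annotation ({char_id}, {taxon}) does not mark an apomorphic cell"
                )

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def cell(self, char_id: int, taxon: str) -> StateCode:
        return self.cells[self._index[char_id]][self._taxon_index[taxon]]

    def character(self, char_id: int) -> CharacterDefinition:
        return self.characters[self._index[char_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
            and self.convergence_annotations == other.convergence_annotations
        )


class ResolvedMatrix(CharacterMatrix):
    """A matrix whose cells are restricted to {0, 1, missing}."""

    def __init__(self, *args, policy_name: str = "as-argued", **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.policy_name = policy_name
        for i, row in enumerate(self.cells):
            for j, state in enumerate(row):
                if state not in RESOLVED:
                    raise ValueError(
                        f"unresolved code {state.value!r} at character row {i}, "
                        f"taxon {self.taxa[j]!r}"
                    )


# --- polarity policies -----------------------------------------------------

#: as-argued: take every qualified code at its argued polarity (1? -> 1,
#: 0? -> 0, 0* -> 0: an intraspecific deviation does not regroup the taxon).
#: conservative: discard all qualified codes as missing.
POLARITY_POLICIES = {
    "as-argued": {
        StateCode.APOMORPHIC_UNCERTAIN: StateCode.APOMORPHIC,
        StateCode.PLESIOMORPHIC_UNCERTAIN: StateCode.PLESIOMORPHIC,
        StateCode.PLESIOMORPHIC_VARIABLE: StateCode.PLESIOMORPHIC,
        StateCode.MISSING: StateCode.MISSING,
    },
    "conservative": {
        StateCode.APOMORPHIC_UNCERTAIN: StateCode.MISSING,
        StateCode.PLESIOMORPHIC_UNCERTAIN: StateCode.MISSING,
        StateCode.PLESIOMORPHIC_VARIABLE: StateCode.MISSING,
        StateCode.MISSING: StateCode.MISSING,
    },
}


def apply_polarity_policy(
    matrix: CharacterMatrix, policy: str = "as-argued"
) -> ResolvedMatrix:
    """Reduce uncertainty codes to {0, 1, missing} under a named policy."""
    try:
        mapping = POLARITY_POLICIES[policy]
    except KeyError:
        raise ValueError(
            f"unknown polarity policy {policy!r}; "
            f"choose from {sorted(POLARITY_POLICIES)}"
        ) from None
    cells = [
        [mapping.get(state, state) for state in row] for row in matrix.cells
    ]
    return ResolvedMatrix(
        matrix.taxa,
        matrix.characters,
        cells,
        policy_name=policy,
    )


def derived_taxon_set(matrix: CharacterMatrix, char_id: int) -> set[str]:
    """Taxa scored apomorphic (1) for a character; missing cells excluded."""
    if char_id not in matrix._index:
        raise KeyError(f"unknown character id {char_id}")
    row = matrix.cells[matrix._index[char_id]]
    return {
        taxon
        for taxon, state in zip(matrix.taxa, row)
        if state is StateCode.APOMORPHIC
    }


def missing_taxon_set(matrix: CharacterMatrix, char_id: int) -> set[str]:
    """Taxa with no information (?) for a character."""
    if char_id not in matrix._index:
        raise KeyError(f"unknown character id {char_id}")
    row = matrix.cells[matrix._index[char_id]]
    return {
        taxon
        for taxon, state in zip(matrix.taxa, row)
        if state is StateCode.MISSING
    }


# --- delimited I/O ---------------------------------------------------------


def _parse_delimited(
    text: str, delimiter: str, path: str, taxa_as_rows: bool = False
) -> CharacterMatrix:
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = rows[0]
    if len(header) < 3:
        raise MatrixFormatError(
            f"{path}, line 1: header needs id, description and >=1 taxon column"
        )
    taxa = [h.strip() for h in header[2:]]
    characters: list[CharacterDefinition] = []
    cells: list[list[StateCode]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise MatrixFormatError(
                f"{path}, line {lineno}: {len(row)} fields, expected {len(header)}"
            )
        try:
            char_id = int(row[0])
        except ValueError:
            raise MatrixFormatError(
                f"{path}, line {lineno}: character id {row[0]!r} is not an integer"
            ) from None
        characters.append(CharacterDefinition(char_id, row[1].strip()))
        states = []
        for col, token in enumerate(row[2:]):
            try:
                states.append(StateCode.parse(token))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}, line {lineno}, column {col + 3}: "
                    f"unknown state token {token!r}"
                ) from None
        cells.append(states)
    matrix = CharacterMatrix(taxa, characters, cells)
    if taxa_as_rows:
        raise MatrixFormatError(
            f"{path}: taxa-as-rows layout requires transpose before construction"
        )
    return matrix


def _parse_delimited_transposed(text: str, delimiter: str, path: str) -> CharacterMatrix:
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = rows[0]
    # header: blank/label column then character ids
    try:
        char_ids = [int(tok) for tok in header[1:]]
    except ValueError:
        raise MatrixFormatError(
            f"{path}, line 1: taxa-as-rows header must list character ids"
        ) from None
    taxa, grid = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise MatrixFormatError(
                f"{path}, line {lineno}: {len(row)} fields, expected {len(header)}"
            )
        taxa.append(row[0].strip())
        states = []
        for col, token in enumerate(row[1:]):
            try:
                states.append(StateCode.parse(token))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}, line {lineno}, column {col + 2}: "
                    f"unknown state token {token!r}"
                ) from None
        grid.append(states)
    characters = [CharacterDefinition(cid, f"character {cid}") for cid in char_ids]
    cells = [[grid[j][i] for j in range(len(taxa))] for i in range(len(char_ids))]
    return CharacterMatrix(taxa, characters, cells)


# --- NEXUS I/O -------------------------------------------------------------

_NEXUS_SIDECAR = "MORPHOCLAD"


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write NEXUS (STANDARD datatype, symbols ``01``, missing ``?``).

    Qualified codes are written at their as-argued symbol in the CHARACTERS
    block; the original codes and the character descriptions go into a
    private ``MORPHOCLAD`` block so that :func:`load_matrix` round-trips the
    matrix cell-for-cell.
    """
    resolved = POLARITY_POLICIES["as-argued"]
    lines = ["#NEXUS", "", "BEGIN TAXA;"]
    lines.append(f"    DIMENSIONS NTAX={matrix.n_taxa};")
    lines.append("    TAXLABELS " + " ".join(matrix.taxa) + ";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN CHARACTERS;")
    lines.append(f"    DIMENSIONS NCHAR={matrix.n_characters};")
    lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;')
    lines.append("    MATRIX")
    width = max(len(t) for t in matrix.taxa) + 2
    for j, taxon in enumerate(matrix.taxa):
        symbols = "".join(
            resolved.get(row[j], row[j]).value for row in matrix.cells
        )
        lines.append(f"        {taxon.ljust(width)}{symbols}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append(f"BEGIN {_NEXUS_SIDECAR};")
    for c in matrix.characters:
        desc = c.description.replace("'", "''")
        plesio = c.plesiomorphic_description.replace("'", "''")
        lines.append(f"    CHAR {c.id} '{desc}' '{plesio}';")
    for i, row in enumerate(matrix.cells):
        for j, state in enumerate(row):
            if state.is_uncertain and state is not StateCode.MISSING:
                lines.append(
                    f"    CODE {matrix.characters[i].id} {matrix.taxa[j]} {state.value};"
                )
    for char_id, taxon in sorted(matrix.convergence_annotations):
        lines.append(f"    CONVERGENT {char_id} {taxon};")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_nexus(path: str | Path) -> CharacterMatrix:
    text = Path(path).read_text()
    try:
        data = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise MatrixFormatError(f"{path}: NEXUS parse failed: {exc}") from exc
    taxa = [t.label.replace(" ", "_") for t in data.taxon_namespace]
    n_chars = max(len(data[t]) for t in data.taxon_namespace)
    grid: dict[str, list[StateCode]] = {}
    for taxon, label in zip(data.taxon_namespace, taxa):
        seq = data[taxon]
        states = []
        for cell in seq:
            sym = str(cell.symbol) if cell.symbol is not None else "?"
            if sym not in ("0", "1", "?"):
                raise MatrixFormatError(
                    f"{path}: unknown NEXUS symbol {sym!r} for taxon {label}"
                )
            states.append(StateCode.parse(sym))
        grid[label] = states

    descriptions: dict[int, tuple[str, str]] = {}
    codes: list[tuple[int, str, StateCode]] = []
    annotations: list[tuple[int, str]] = []
    block = re.search(
        rf"BEGIN\s+{_NEXUS_SIDECAR}\s*;(.*?)END\s*;", text, re.S | re.I
    )
    if block:
        for stmt in block.group(1).split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            m = re.match(r"CHAR\s+(\d+)\s+'((?:[^']|'')*)'\s+'((?:[^']|'')*)'", stmt)
            if m:
                descriptions[int(m.group(1))] = (
                    m.group(2).replace("''", "'"),
                    m.group(3).replace("''", "'"),
                )
                continue
            m = re.match(r"CODE\s+(\d+)\s+(\S+)\s+(\S+)", stmt)
            if m:
                codes.append((int(m.group(1)), m.group(2), StateCode.parse(m.group(3))))
                continue
            m = re.match(r"CONVERGENT\s+(\d+)\s+(\S+)", stmt)
            if m:
                annotations.append((int(m.group(1)), m.group(2)))

    char_ids = sorted(descriptions) if len(descriptions) == n_chars else list(
        range(1, n_chars + 1)
    )
    characters = [
        CharacterDefinition(
            cid,
            descriptions.get(cid, ("character %d" % cid, ""))[0],
            descriptions.get(cid, ("", ""))[1],
        )
        for cid in char_ids
    ]
    cells = [[grid[t][i] for t in taxa] for i in range(n_chars)]
    matrix = CharacterMatrix(taxa, characters, cells)
    for char_id, taxon, state in codes:
        matrix.cells[matrix._index[char_id]][matrix._taxon_index[taxon]] = state
    matrix.convergence_annotations = set(annotations)
    matrix._validate()
    return matrix


def load_matrix(
    path: str | Path, dialect: str | None = None, taxa_as_rows: bool = False
) -> CharacterMatrix:
    """Load a character matrix from CSV, TSV or NEXUS.

    ``dialect`` is inferred from the file suffix when omitted.  The default
    layout is character rows x taxon columns; pass ``taxa_as_rows=True`` for
    the transposed delimited layout.
    """
    path = Path(path)
    if dialect is None:
        dialect = {
            ".csv": "csv",
            ".tsv": "tsv",
            ".nex": "nexus",
            ".nexus": "nexus",
        }.get(path.suffix.lower())
        if dialect is None:
            raise MatrixFormatError(f"{path}: cannot infer dialect from suffix")
    if dialect == "nexus":
        return _parse_nexus(path)
    if dialect not in ("csv", "tsv"):
        raise MatrixFormatError(f"unknown dialect {dialect!r}")
    delimiter = "," if dialect == "csv" else "\t"
    text = path.read_text()
    if taxa_as_rows:
        return _parse_delimited_transposed(text, delimiter, str(path))
    return _parse_delimited(text, delimiter, str(path))


def write_matrix(matrix: CharacterMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Write a matrix as CSV/TSV (character rows) or NEXUS."""
    if dialect == "nexus":
        write_nexus(matrix, path)
        return
    if dialect not in ("csv", "tsv"):
        raise MatrixFormatError(f"unknown dialect {dialect!r}")
    delimiter = "," if dialect == "csv" else "\t"
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(["id", "description", *matrix.taxa])
        for c, row in zip(matrix.characters, matrix.cells):
            writer.writerow([c.id, c.description, *[s.value for s in row]])
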