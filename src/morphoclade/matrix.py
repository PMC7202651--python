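"""Character-matrix containers for discrete morphological data.

The central object is :class:`CharacterMatrix`, a taxa × characters grid of
:class:`StateSet` cells. Cells may be scored (one or more integer state
codes), missing (``?``) or inapplicable (``-``). Missing and inapplicable
cells behave as full wildcards during parsimony optimization and are
"unscored" for pairwise-distance comparability.

Character identifiers are 1-based and stable under any taxon or character
subsetting, so downstream reports (synapomorphy lists, character subsets)
always cite the numbering of the source file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "StateSet",
    "CharacterMatrix",
    "GroupMap",
    "MatrixError",
    "MISSING",
    "INAPPLICABLE",
]


class MatrixError(ValueError):
    """Raised for malformed matrices or invalid subsetting requests."""


@dataclass(frozen=True)
class StateSet:
    """One cell of the matrix: a set of state codes or a wildcard flag.

    A scored monomorphic cell has exactly one state; a polymorphic cell
    (e.g. an ontogenetically variable character scored as a multi-state)
    has two or more, and is treated as "any member state" ambiguity during
    optimization. Missing and inapplicable cells carry no states of their
    own; scoring code resolves them to the observed state universe of their
    character column.
    """

    states: frozenset[int] = frozenset()
    is_missing: bool = False
    is_inapplicable: bool = False

    def __post_init__(self) -> None:
        if self.is_missing and self.is_inapplicable:
            raise MatrixError("cell cannot be both missing and inapplicable")
        if self.is_scored and not self.states:
            raise MatrixError("scored cell must have at least one state")
        if not self.is_scored and self.states:
            raise MatrixError("wildcard cell carries no explicit states")
        if any(s < 0 for s in self.states):
            raise MatrixError("state codes must be non-negative integers")

    @property
    def is_scored(self) -> bool:
        return not (self.is_missing or self.is_inapplicable)

    @property
    def is_polymorphic(self) -> bool:
        return self.is_scored and len(self.states) >= 2

    @classmethod
    def of(cls, *states: int) -> "StateSet":
        return cls(states=frozenset(states))

    def __repr__(self) -> str:  # compact, e.g. {0,1} or '?'
        if self.is_missing:
            return "?"
        if self.is_inapplicable:
            return "-"
        inner = ",".join(str(s) for s in sorted(self.states))
        return "{%s}" % inner if len(self.states) > 1 else inner


MISSING = StateSet(is_missing=True)
INAPPLICABLE = StateSet(is_inapplicable=True)


@dataclass
class CharacterMatrix:
    """Taxa × characters grid of :class:`StateSet` cells.

    ``char_ids`` are 1-based identifiers in original file order; they are
    preserved verbatim by :meth:`select_taxa` and :meth:`select_characters`
    so that subsetted analyses still cite the source numbering.
    """

    taxon_labels: list[str]
    char_ids: list[int]
    cells: list[list[StateSet]]  # cells[taxon_index][char_index]
    weights: list[float] = field(default_factory=list)
    ordering: list[str] = field(default_factory=list)  # all "unordered" here

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = [1.0] * len(self.char_ids)
        if not self.ordering:
            self.ordering = ["unordered"] * len(self.char_ids)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dupes = {t for t in self.taxon_labels if self.taxon_labels.count(t) > 1}
            raise MatrixError(f"duplicate taxon labels: {sorted(dupes)}")
        if len(self.cells) != len(self.taxon_labels):
            raise MatrixError(
                f"{len(self.cells)} cell rows for {len(self.taxon_labels)} taxa"
            )
        for label, row in zip(self.taxon_labels, self.cells):
            if len(row) != len(self.char_ids):
                raise MatrixError(
                    f"taxon {label!r}: {len(row)} cells, expected {len(self.char_ids)}"
                )
        if len(self.weights) != len(self.char_ids):
            raise MatrixError("one weight per character required")
        if any(w <= 0 for w in self.weights):
            raise MatrixError("weights must be positive")

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_chars(self) -> int:
        return len(self.char_ids)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxon_labels.index(label)
        except ValueError:
            raise MatrixError(f"unknown taxon label: {label!r}") from None

    def char_index(self, char_id: int) -> int:
        try:
            return self.char_ids.index(char_id)
        except ValueError:
            raise MatrixError(f"unknown character id: {char_id}") from None

    def cell(self, taxon: str, char_id: int) -> StateSet:
        return self.cells[self.taxon_index(taxon)][self.char_index(char_id)]

    def column(self, char_id: int) -> dict[str, StateSet]:
        j = self.char_index(char_id)
        return {t: self.cells[i][j] for i, t in enumerate(self.taxon_labels)}

    def observed_states(self, char_id: int) -> frozenset[int]:
        """Union of states over the scored cells of a character column."""
        j = self.char_index(char_id)
        out: set[int] = set()
        for row in self.cells:
            if row[j].is_scored:
                out |= row[j].states
        return frozenset(out)

    # ------------------------------------------------------------------
    def select_taxa(
        self,
        keep: Sequence[str] | None = None,
        drop: Sequence[str] | None = None,
    ) -> "CharacterMatrix":
        """Sub-matrix on taxa; character ids are untouched."""
        if (keep is None) == (drop is None):
            raise MatrixError("give exactly one of keep= or drop=")
        names = list(keep if keep is not None else drop)
        unknown = [n for n in names if n not in self.taxon_labels]
        if unknown:
            raise MatrixError(f"unknown taxon labels: {unknown}")
        if keep is not None:
            kept = [t for t in self.taxon_labels if t in set(names)]
        else:
            kept = [t for t in self.taxon_labels if t not in set(names)]
        idx = [self.taxon_labels.index(t) for t in kept]
        return CharacterMatrix(
            taxon_labels=kept,
            char_ids=list(self.char_ids),
            cells=[list(self.cells[i]) for i in idx],
            weights=list(self.weights),
            ordering=list(self.ordering),
        )

    def select_characters(self, char_ids: Sequence[int]) -> "CharacterMatrix":
        """Sub-matrix on characters, preserving the original 1-based ids."""
        unknown = [c for c in char_ids if c not in self.char_ids]
        if unknown:
            raise MatrixError(f"unknown character ids: {unknown}")
        idx = [self.char_ids.index(c) for c in char_ids]
        return CharacterMatrix(
            taxon_labels=list(self.taxon_labels),
            char_ids=[self.char_ids[j] for j in idx],
            cells=[[row[j] for j in idx] for row in self.cells],
            weights=[self.weights[j] for j in idx],
            ordering=[self.ordering[j] for j in idx],
        )

    def resample_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Matrix with columns taken (possibly repeatedly) by position.

        Used by bootstrap resampling; repeated columns keep their source
        char_id so per-character reports remain interpretable.
        """
        for j in indices:
            if not 0 <= j < self.n_chars:
                raise MatrixError(f"column position out of range: {j}")
        return CharacterMatrix(
            taxon_labels=list(self.taxon_labels),
            char_ids=[self.char_ids[j] for j in indices],
            cells=[[row[j] for j in indices] for row in self.cells],
            weights=[self.weights[j] for j in indices],
            ordering=[self.ordering[j] for j in indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxon_labels == other.taxon_labels
            and self.char_ids == other.char_ids
            and self.cells == other.cells
            and self.weights == other.weights
            and self.ordering == other.ordering
        )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GroupMap:
    """OTU → (genus, tribe) assignment used by the disparity analysis."""

    genus: Mapping[str, str]
    tribe: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.genus) != set(self.tribe):
            raise MatrixError("genus and tribe maps must cover the same OTUs")

    @property
    def otus(self) -> list[str]:
        return sorted(self.genus)

    def genera(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for otu in self.otus:
            out.setdefault(self.genus[otu], []).append(otu)
        return out

    @classmethod
    def from_tsv(cls, text: str) -> "GroupMap":
        """Parse a TSV with columns: otu, genus, tribe (header optional)."""
        genus: dict[str, str] = {}
        tribe: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixError(f"expected 3 tab-separated columns: {line!r}")
            if parts == ["otu", "genus", "tribe"]:
                continue
            otu, g, t = parts
            if otu in genus:
                raise MatrixError(f"duplicate OTU in group map: {otu!r}")
            genus[otu] = g
            tribe[otu] = t
        return cls(genus=genus, tribe=tribe)

    def to_tsv(self) -> str:
        lines = ["otu\tgenus\ttribe"]
        for otu in self.otus:
            lines.append(f"{otu}\t{self.genus[otu]}\t{self.tribe[otu]}")
        return "\n".join(lines) + "\n"


def read_character_ids(text: str) -> list[int]:
    """Plain-text character-subset list: one 1-based id per line."""
    ids = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(int(line))
    return ids
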