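"""Taxonomic lineages in the pipe-delimited ``k__|p__|...`` encoding.

MetaPhlAn-style merged abundance tables identify each row by a lineage
string such as ``k__Bacteria|p__Firmicutes|...|s__Ruminococcus_lactaris``.
A lineage names a contiguous prefix of the seven canonical ranks; the
deepest named rank is its *terminal rank* and determines at which
taxonomic resolution the row contributes counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_PREFIXES: dict[str, str] = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

_PREFIX_TO_RANK = {v: k for k, v in RANK_PREFIXES.items()}
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class LineageError(ValueError):
    """Raised for malformed or rank-inconsistent lineage strings."""


def rank_index(rank: str) -> int:
    """Position of ``rank`` in the kingdom→species hierarchy (0-based)."""
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise LineageError(f"unknown taxonomic rank {rank!r}; expected one of {RANKS}")


@total_ordering
@dataclass(frozen=True)
class TaxonLineage:
    """An ordered assignment of names to a contiguous prefix of ranks.

    Invariants enforced at construction: at least the kingdom is named, a
    named rank implies all higher ranks are named (no gaps), and names are
    non-empty.  The string form round-trips through ``from_string``.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise LineageError("lineage must name at least the kingdom")
        if len(self.names) > len(RANKS):
            raise LineageError(f"lineage has {len(self.names)} levels; max is {len(RANKS)}")
        for rank, name in zip(RANKS, self.names):
            if not name:
                raise LineageError(f"empty name at rank {rank!r}")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonLineage":
        """Parse a pipe-delimited lineage like ``k__Bacteria|p__Firmicutes``.

        Raises :class:`LineageError` if a segment carries an unknown prefix,
        ranks appear out of order, or an intermediate rank is skipped.
        """
        segments = lineage.strip().split("|")
        names: list[str] = []
        for pos, seg in enumerate(segments):
            prefix = seg[:3]
            rank = _PREFIX_TO_RANK.get(prefix)
            if rank is None:
                raise LineageError(f"segment {seg!r} in {lineage!r} has no recognized rank prefix")
            if _RANK_INDEX[rank] != pos:
                raise LineageError(
                    f"rank {rank!r} out of order in {lineage!r}: "
                    f"expected {RANKS[pos]!r} at position {pos}"
                )
            names.append(seg[3:])
        return cls(tuple(names))

    # -- views -----------------------------------------------------------

    @property
    def terminal_rank(self) -> str:
        """The deepest named rank."""
        return RANKS[len(self.names) - 1]

    def name_at(self, rank: str) -> str | None:
        """Name at ``rank``, or None if the lineage stops above it."""
        i = rank_index(rank)
        return self.names[i] if i < len(self.names) else None

    @property
    def terminal_name(self) -> str:
        return self.names[-1]

    @property
    def genus(self) -> str | None:
        return self.name_at("genus")

    def truncate(self, rank: str) -> "TaxonLineage":
        """Lineage cut at ``rank`` (which must be at or above terminal)."""
        i = rank_index(rank)
        if i >= len(self.names):
            raise LineageError(
                f"cannot truncate {self} at {rank!r}: lineage ends at {self.terminal_rank!r}"
            )
        return TaxonLineage(self.names[: i + 1])

    def __str__(self) -> str:
        return "|".join(RANK_PREFIXES[RANKS[i]] + n for i, n in enumerate(self.names))

    def __lt__(self, other: "TaxonLineage") -> bool:
        return self.names < other.names
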