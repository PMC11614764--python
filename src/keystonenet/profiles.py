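"""Reading, validating and filtering taxonomic abundance tables.

The substrate of all correlation work is an :class:`AbundanceTable`: a
samples x taxa matrix of estimated mapped read counts, with every taxon at
one shared taxonomic rank.  This module parses MetaPhlAn-style merged TSV
tables, de-duplicates samples to one per participant, aggregates counts up
the taxonomy, applies the prevalence filter and computes presence/absence
site similarity between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lineage import RANKS, LineageError, TaxonLineage, rank_index

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "ProfileParseError",
    "read_taxonomic_profile",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_sample_metadata",
    "select_one_sample_per_participant",
    "aggregate_to_rank",
    "filter_prevalence",
    "site_similarity",
]


class ProfileParseError(ValueError):
    """Raised when an input table cannot be parsed into an AbundanceTable."""


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of estimated mapped read counts.

    All taxa share the same terminal rank.  Counts are nonnegative
    integers (units: estimated mapped reads), never relative abundances.
    """

    sample_ids: list[str]
    taxa: list[TaxonLineage]
    counts: np.ndarray  # (n_samples, n_taxa) int64
    rank: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(map(str, self.taxa))) != len(self.taxa):
            raise ValueError("duplicate taxa")
        rank_index(self.rank)
        for t in self.taxa:
            if t.terminal_rank != self.rank:
                raise ValueError(f"taxon {t} has terminal rank {t.terminal_rank!r}, expected {self.rank!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def taxon_labels(self) -> list[str]:
        return [str(t) for t in self.taxa]

    def to_frame(self) -> pd.DataFrame:
        """Taxa-rows, sample-columns DataFrame (the canonical TSV layout)."""
        return pd.DataFrame(self.counts.T, index=self.taxon_labels, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(list(sample_ids), list(self.taxa), self.counts[idx], self.rank)


@dataclass
class SampleMetadata:
    """Maps sample_id -> (participant_id, dataset_label)."""

    participant: dict[str, str]
    dataset: dict[str, str] = field(default_factory=dict)

    def require(self, sample_ids: list[str]) -> None:
        orphans = [s for s in sample_ids if s not in self.participant]
        if orphans:
            raise KeyError(f"samples without metadata: {orphans}")


def _round_half_up(values: np.ndarray) -> np.ndarray:
    # upstream "estimated reads" may be fractional; half-up keeps .5 deterministic
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(np.int64)


def read_taxonomic_profile(path: str | Path, rank: str) -> AbundanceTable:
    """Read a MetaPhlAn-style merged TSV, keeping rows terminal at ``rank``.

    The first column holds pipe-delimited lineage strings; the remaining
    columns are per-sample estimated read counts (fractional values are
    rounded half-up).  Rows whose lineage terminates at a different rank
    are dropped, which avoids double counting across ranks.
    """
    rank_index(rank)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    if df.shape[1] < 2:
        raise ProfileParseError(f"{path}: expected a lineage column plus >=1 sample column")
    sample_ids = [str(c) for c in df.columns[1:]]
    taxa: list[TaxonLineage] = []
    rows: list[np.ndarray] = []
    for _, row in df.iterrows():
        lineage_str = str(row.iloc[0])
        if lineage_str.startswith("#"):
            continue
        try:
            lin = TaxonLineage.from_string(lineage_str)
        except LineageError as e:
            raise ProfileParseError(f"{path}: malformed lineage in row {lineage_str!r}: {e}") from e
        if lin.terminal_rank != rank:
            continue
        vals = np.empty(len(sample_ids))
        for j, s in enumerate(sample_ids):
            cell = row.iloc[j + 1]
            try:
                vals[j] = float(cell)
            except (TypeError, ValueError):
                raise ProfileParseError(
                    f"{path}: non-numeric value {cell!r} for sample {s!r} in row {lineage_str!r}"
                ) from None
        taxa.append(lin)
        rows.append(_round_half_up(vals))
    counts = np.array(rows, dtype=np.int64).T if rows else np.zeros((len(sample_ids), 0), np.int64)
    return AbundanceTable(sample_ids, taxa, counts, rank)


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write the canonical taxa-rows / sample-columns integer TSV."""
    df = table.to_frame()
    df.index.name = "lineage"
    df.to_csv(path, sep="\t")


def read_abundance_tsv(path: str | Path, rank: str) -> AbundanceTable:
    """Read back a canonical TSV written by :func:`write_abundance_tsv`."""
    return read_taxonomic_profile(path, rank)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a 3-column TSV: sample_id, participant_id, dataset_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ProfileParseError(f"{path}: expected 3 columns (sample, participant, dataset)")
    cols = df.columns[:3]
    participant = dict(zip(df[cols[0]], df[cols[1]]))
    dataset = dict(zip(df[cols[0]], df[cols[2]]))
    return SampleMetadata(participant=participant, dataset=dataset)


def select_one_sample_per_participant(
    table: AbundanceTable, meta: SampleMetadata, seed: int
) -> AbundanceTable:
    """Keep exactly one sample per participant, chosen uniformly at random.

    Repeated samples from one participant are not statistically
    independent, so correlation estimation uses a single random sample
    each.  Selection iterates participants in sorted order under one
    seeded generator, making the draw reproducible.
    """
    meta.require(table.sample_ids)
    rng = np.random.default_rng(seed)
    by_participant: dict[str, list[str]] = {}
    for s in table.sample_ids:
        by_participant.setdefault(meta.participant[s], []).append(s)
    chosen: set[str] = set()
    for pid in sorted(by_participant):
        samples = sorted(by_participant[pid])
        chosen.add(samples[rng.integers(len(samples))])
    kept = [s for s in table.sample_ids if s in chosen]
    return table.select_samples(kept)


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts of taxa sharing the same lineage prefix at ``rank``.

    ``rank`` must be at or above the table's rank; aggregating a table to
    its own rank is the identity.  Per-sample totals are conserved.
    """
    if rank_index(rank) > rank_index(table.rank):
        raise ValueError(f"cannot aggregate {table.rank}-level table down to {rank}")
    if rank == table.rank:
        return AbundanceTable(list(table.sample_ids), list(table.taxa), table.counts.copy(), rank)
    groups: dict[str, tuple[TaxonLineage, list[int]]] = {}
    for j, t in enumerate(table.taxa):
        trunc = t.truncate(rank)
        key = str(trunc)
        groups.setdefault(key, (trunc, []))[1].append(j)
    taxa = [groups[k][0] for k in groups]  # first-seen order
    counts = np.stack([table.counts[:, groups[k][1]].sum(axis=1) for k in groups], axis=1)
    return AbundanceTable(list(table.sample_ids), taxa, counts, rank)


def filter_prevalence(table: AbundanceTable, min_prevalence: float = 0.20) -> AbundanceTable:
    """Keep taxa with nonzero counts in >= ceil(min_prevalence * n) samples.

    The boundary is inclusive: with 10 samples and the default threshold
    of 0.20, presence in exactly 2 samples suffices.  Idempotent.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    need = int(np.ceil(min_prevalence * table.n_samples))
    present = (table.counts > 0).sum(axis=0)
    keep = np.flatnonzero(present >= need)
    if keep.size == 0:
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    taxa = [table.taxa[j] for j in keep]
    return AbundanceTable(list(table.sample_ids), taxa, table.counts[:, keep], table.rank)


def site_similarity(table: AbundanceTable) -> tuple[float, np.ndarray]:
    """Mean pairwise Jaccard similarity of presence/absence profiles.

    Returns ``(mean, matrix)`` where ``matrix[i, j]`` is |intersection| /
    |union| of the taxa detected in samples i and j; a pair of samples
    with no detected taxa at all has similarity 0 by convention.  Used to
    judge whether communities are similar enough to share one correlation
    network.
    """
    n = table.n_samples
    if n < 2:
        raise ValueError("site similarity needs at least 2 samples")
    presence = table.counts > 0
    inter = (presence[:, None, :] & presence[None, :, :]).sum(axis=2).astype(float)
    union = (presence[:, None, :] | presence[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    iu = np.triu_indices(n, k=1)
    return float(sim[iu].mean()), sim
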