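"""Per-taxon transcriptional states from metatranscriptome functional profiles.

Given per-sample transcription attributed to one taxon (HUMAnN-style
stratified gene-family or Enzyme Commission tables), this module
normalizes each sample to copies per million of the taxon's total
transcription, summarizes transcriptional repertoire stability with
pairwise Sorensen similarity, discovers transcriptional states by
silhouette-selected k-means (iteratively excluding samples stranded in
clusters of fewer than three), and ranks features by random-forest
permutation importance (mean decrease in out-of-bag accuracy) with a
label-permutation null for per-feature p-values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "TranscriptProfile",
    "StateModel",
    "FeatureImportance",
    "read_functional_profile",
    "normalize_cpm",
    "sorensen_similarity",
    "choose_k",
    "fit_states",
    "permutation_importance",
]

CPM_TOTAL = 1e6
_EXCLUDED_FEATURES = {"UNMAPPED", "UNGROUPED", "UNINTEGRATED"}
_STRATIFIED = re.compile(r"^(?P<feature>[^|]+)\|(?P<taxon>.+)$")


@dataclass
class TranscriptProfile:
    """Per-taxon samples x features transcription matrix."""

    taxon: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n_samples, n_features), nonnegative
    normalized: bool = False
    zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match sample/feature ids")
        if (self.values < 0).any():
            raise ValueError("transcription values must be nonnegative")


@dataclass
class StateModel:
    """Fitted transcriptional states for one taxon."""

    taxon: str
    k: int
    assignments: dict[str, int]  # retained sample -> state
    centroids: np.ndarray  # (k, n_features)
    mean_silhouette: float
    excluded_samples: list[str]
    silhouette_curve: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class FeatureImportance:
    """Mean decrease in OOB accuracy and permutation p-value per feature."""

    feature_ids: list[str]
    importance: np.ndarray
    p_value: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "importance": self.importance,
                "p_value": self.p_value,
            }
        )


def read_functional_profile(path: str | Path) -> dict[str, TranscriptProfile]:
    """Parse a HUMAnN-style stratified TSV into per-taxon profiles.

    Rows look like ``FEATURE|g__Genus.s__Genus_species``; unstratified
    rows (no pipe) are community totals and are ignored, as are the
    special UNMAPPED/UNGROUPED/UNINTEGRATED feature ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(c) for c in df.columns]
    per_taxon: dict[str, tuple[list[str], list[np.ndarray]]] = {}
    for row_id, row in df.iterrows():
        m = _STRATIFIED.match(str(row_id))
        if m is None:
            continue
        feature, taxon = m.group("feature"), m.group("taxon")
        if feature.upper() in _EXCLUDED_FEATURES or taxon.lower() == "unclassified":
            continue
        feats, vals = per_taxon.setdefault(taxon, ([], []))
        feats.append(feature)
        vals.append(row.to_numpy(dtype=float))
    if not per_taxon:
        raise ValueError(f"{path}: no parseable stratified rows")
    return {
        taxon: TranscriptProfile(
            taxon=taxon,
            sample_ids=list(sample_ids),
            feature_ids=feats,
            values=np.stack(vals, axis=1),
        )
        for taxon, (feats, vals) in per_taxon.items()
    }


def normalize_cpm(profile: TranscriptProfile) -> TranscriptProfile:
    """Scale each sample to copies per million of the taxon's transcription.

    Samples with no transcription attributed to the taxon cannot be
    normalized; they are flagged in ``zero_samples`` and excluded
    downstream.  Idempotent.
    """
    totals = profile.values.sum(axis=1)
    zero = totals == 0
    scaled = np.zeros_like(profile.values)
    nz = ~zero
    scaled[nz] = profile.values[nz] / totals[nz, None] * CPM_TOTAL
    return TranscriptProfile(
        taxon=profile.taxon,
        sample_ids=list(profile.sample_ids),
        feature_ids=list(profile.feature_ids),
        values=scaled,
        normalized=True,
        zero_samples=[s for s, z in zip(profile.sample_ids, zero) if z],
    )


def sorensen_similarity(profile: TranscriptProfile) -> tuple[float, np.ndarray]:
    """Mean pairwise Sorensen similarity 2a / (2a + b + c) on presence/absence.

    a = features present in both samples, b and c = features unique to
    each.  Pairs of samples with no present features at all score 0.
    Returns (mean over pairs, full pairwise matrix).
    """
    presence = profile.values > 0
    n = presence.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    a = (presence[:, None, :] & presence[None, :, :]).sum(axis=2).astype(float)
    totals = presence.sum(axis=1).astype(float)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * a / np.maximum(denom, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    iu = np.triu_indices(n, k=1)
    return float(sim[iu].mean()), sim


def _usable_matrix(profile: TranscriptProfile) -> tuple[np.ndarray, list[str]]:
    prof = profile if profile.normalized else normalize_cpm(profile)
    keep = [s for s in prof.sample_ids if s not in set(prof.zero_samples)]
    idx = [prof.sample_ids.index(s) for s in keep]
    return prof.values[idx], keep


def choose_k(
    profile: TranscriptProfile | np.ndarray,
    k_max: int = 10,
    seed: int | None = None,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick k maximizing the mean silhouette width over k = 2..k_max.

    k-means (Euclidean, 25 restarts per k, seeded) on the CPM-normalized
    matrix; silhouette is undefined at k = 1, so the search starts at 2.
    Ties resolve to the smallest k.
    """
    if isinstance(profile, TranscriptProfile):
        x, _ = _usable_matrix(profile)
    else:
        x = np.asarray(profile, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to choose k")
    ss = np.random.SeedSequence(seed)
    curve: list[tuple[int, float]] = []
    best_k, best_sil = 2, -np.inf
    for k, child in zip(range(2, min(k_max, n - 1) + 1), ss.spawn(k_max)):
        km = KMeans(
            n_clusters=k, n_init=25, random_state=int(child.generate_state(1)[0] % 2**31)
        ).fit(x)
        if len(set(km.labels_)) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(x, km.labels_, metric="euclidean"))
        curve.append((k, sil))
        if sil > best_sil:
            best_k, best_sil = k, sil
    return best_k, curve


def fit_states(
    profile: TranscriptProfile,
    k_max: int = 10,
    min_cluster_size: int = 3,
    seed: int | None = None,
) -> StateModel | None:
    """Silhouette-selected k-means with small-cluster sample exclusion.

    Repeatedly: choose k by silhouette, fit k-means; if any cluster has
    fewer than ``min_cluster_size`` members, drop those samples (recorded
    in ``excluded_samples``) and start over.  Returns None ("no stable
    state model") when too few samples remain.
    """
    x, sample_ids = _usable_matrix(profile)
    excluded = list(profile.zero_samples)
    ss = np.random.SeedSequence(seed)
    for round_seed in ss.spawn(len(sample_ids) + 1):
        if len(sample_ids) < 2 * min_cluster_size:
            return None
        sub_choose, sub_fit = round_seed.spawn(2)
        k, curve = choose_k(x, k_max=k_max, seed=int(sub_choose.generate_state(1)[0] % 2**31))
        km = KMeans(
            n_clusters=k,
            n_init=25,
            random_state=int(sub_fit.generate_state(1)[0] % 2**31),
        ).fit(x)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=k)
        small = np.flatnonzero(sizes < min_cluster_size)
        if small.size == 0:
            sil = float(silhouette_score(x, labels, metric="euclidean"))
            return StateModel(
                taxon=profile.taxon,
                k=k,
                assignments=dict(zip(sample_ids, labels.tolist())),
                centroids=km.cluster_centers_,
                mean_silhouette=sil,
                excluded_samples=excluded,
                silhouette_curve=curve,
            )
        drop = np.isin(labels, small)
        excluded.extend(s for s, d in zip(sample_ids, drop) if d)
        sample_ids = [s for s, d in zip(sample_ids, drop) if not d]
        x = x[~drop]
    return None


# ---------------------------------------------------------------------------
# random-forest permutation importance (mean decrease in OOB accuracy)
# ---------------------------------------------------------------------------


def _forest_mda(
    x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Breiman-style mean decrease in accuracy over out-of-bag samples.

    Trees are bagged manually so out-of-bag membership is explicit: for
    each tree, accuracy on its OOB samples is compared with accuracy
    after permuting one feature's OOB values; the decrease is averaged
    over trees (trees with no OOB samples are skipped for that term).
    """
    n, d = x.shape
    decreases = np.zeros(d)
    counts = np.zeros(d)
    max_features = max(1, int(math.sqrt(d)))
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31))
        ).fit(x[boot], y[boot])
        x_oob = x[oob]
        base_acc = float(np.mean(tree.predict(x_oob) == y[oob]))
        # one stacked predict per tree: all features' permuted copies at once
        perm_rows = np.repeat(x_oob[None, :, :], d, axis=0)  # (d, n_oob, d)
        for j in range(d):
            perm_rows[j, :, j] = x_oob[rng.permutation(oob.size), j]
        preds = tree.predict(perm_rows.reshape(d * oob.size, d)).reshape(d, oob.size)
        perm_acc = (preds == y[oob][None, :]).mean(axis=1)
        decreases += base_acc - perm_acc
        counts += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, decreases / np.maximum(counts, 1), 0.0)


def permutation_importance(
    profile: TranscriptProfile | np.ndarray,
    labels: dict[str, int] | np.ndarray,
    n_trees: int = 500,
    n_perm: int = 100,
    seed: int | None = None,
    feature_ids: list[str] | None = None,
) -> FeatureImportance:
    """Feature importance with a permuted-label null distribution.

    Observed importance is the mean decrease in out-of-bag accuracy of a
    bagged random forest classifying transcriptional states.  The null
    refits the forest ``n_perm`` times with shuffled state labels;
    per-feature p-values use the add-one estimator
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if isinstance(profile, TranscriptProfile):
        x, sample_ids = _usable_matrix(profile)
        feats = list(profile.feature_ids)
        if isinstance(labels, dict):
            keep = [i for i, s in enumerate(sample_ids) if s in labels]
            x = x[keep]
            y = np.array([labels[sample_ids[i]] for i in keep])
        else:
            y = np.asarray(labels)
    else:
        x = np.asarray(profile, dtype=float)
        y = np.asarray(labels)
        feats = feature_ids or [f"feature_{j}" for j in range(x.shape[1])]
    classes, y = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 states")
    if np.bincount(y).min() < 2:
        raise ValueError("each state needs at least 2 samples")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_perm + 1)
    rng = np.random.default_rng(streams[0])
    observed = _forest_mda(x, y, n_trees, rng)
    exceed = np.zeros(x.shape[1], dtype=np.int64)
    for child in streams[1:]:
        nrng = np.random.default_rng(child)
        y_null = nrng.permutation(y)
        null_imp = _forest_mda(x, y_null, n_trees, nrng)
        exceed += null_imp >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    return FeatureImportance(
        feature_ids=feats, importance=observed, p_value=p, n_permutations=n_perm
    )
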