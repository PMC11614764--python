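"""Synthetic microbial communities with known correlation structure.

The generator follows the standard log-normal/multinomial compositional
benchmark: latent per-taxon log-abundances are drawn from a multivariate
normal whose correlation structure is specified explicitly (positively
correlated within-genus blocks, plus planted "keystone" taxa with
negative couplings to one block), exponentiated, thinned by per-taxon
dropout to emulate prevalence structure, closed to relative abundances,
and finally observed as multinomial read counts at a per-sample
sequencing depth.  Because the latent correlation matrix is known, every
stage of the inference pipeline can be validated against ground truth.

A companion generator produces per-taxon transcription profiles drawn
from k distinct transcriptional states for testing the state-discovery
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lineage import TaxonLineage
from .profiles import AbundanceTable
from .transcription import TranscriptProfile

__all__ = [
    "CommunitySpec",
    "simulate_counts",
    "default_keystone_scenario",
    "simulate_transcription",
]


@dataclass
class CommunitySpec:
    """Generative description of a synthetic community.

    ``blocks`` are (member indices, within-block latent correlation);
    ``keystone_specs`` are (keystone index, block index, coupling), the
    coupling being the latent correlation between the keystone and every
    member of the target block.  ``dropout`` gives each taxon's
    probability of being zeroed in a sample before closure, shaping
    prevalence.  ``depth_range`` bounds the log-uniform per-sample total
    count (sequencing depth).
    """

    n_taxa: int
    genus_map: dict[int, str]
    blocks: list[tuple[list[int], float]]
    keystone_specs: list[tuple[int, int, float]] = field(default_factory=list)
    log_mean: np.ndarray | None = None
    log_var: np.ndarray | None = None
    dropout: np.ndarray | None = None
    depth_range: tuple[float, float] = (5e4, 2e5)

    def latent_correlation(self) -> np.ndarray:
        """Assemble and validate the latent correlation matrix."""
        c = np.eye(self.n_taxa)
        for members, rho in self.blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("within-block correlation must be in [-1, 1]")
            for a in members:
                for b in members:
                    if a != b:
                        c[a, b] = rho
        for ks, block_idx, coupling in self.keystone_specs:
            if not -1.0 <= coupling <= 1.0:
                raise ValueError("keystone coupling must be in [-1, 1]")
            for b in self.blocks[block_idx][0]:
                c[ks, b] = c[b, ks] = coupling
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"latent correlation matrix is not PSD (min eigenvalue {eigmin:.3g}); "
                "weaken block correlations or keystone couplings, or project to the "
                "nearest PSD matrix before use"
            )
        return c

    def covariance(self) -> np.ndarray:
        c = self.latent_correlation()
        sd = np.sqrt(self.log_var if self.log_var is not None else np.ones(self.n_taxa))
        return c * np.outer(sd, sd)

    def taxa(self) -> list[TaxonLineage]:
        """Species-level lineages grouping taxa by their assigned genus."""
        genus_members: dict[str, int] = {}
        out = []
        for i in range(self.n_taxa):
            genus = self.genus_map[i]
            genus_members[genus] = genus_members.get(genus, 0) + 1
            out.append(
                TaxonLineage.from_string(
                    "k__Bacteria|p__SimPhylum|c__SimClass|o__SimOrder|"
                    f"f__Fam_{genus}|g__{genus}|s__{genus}_sp{genus_members[genus]}"
                )
            )
        return out


def simulate_counts(
    spec: CommunitySpec, n_samples: int, seed: int | None = None
) -> tuple[AbundanceTable, np.ndarray]:
    """Draw a count table from a community spec; returns (table, latent correlation).

    Latent log-abundances ~ MVN(log_mean, covariance); exponentiate,
    apply per-taxon dropout, close each sample to fractions and draw
    multinomial counts at a log-uniform depth.  Per-sample count totals
    equal the drawn depths exactly.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cov = spec.covariance()
    truth = spec.latent_correlation()
    mean = spec.log_mean if spec.log_mean is not None else np.zeros(spec.n_taxa)
    z = rng.multivariate_normal(mean, cov, size=n_samples, method="cholesky")
    abundance = np.exp(z)
    if spec.dropout is not None:
        # detection-limit censoring: a taxon with dropout rate q is zeroed in
        # the q fraction of samples where its abundance is lowest, emulating
        # prevalence structure without the signal destruction of independent
        # random zeroing (absence in real profiles is abundance-dependent)
        keep = abundance > np.array(
            [np.quantile(abundance[:, j], spec.dropout[j]) for j in range(spec.n_taxa)]
        )[None, :]
        dead = ~keep.any(axis=1)
        if dead.any():
            keep[dead, abundance[dead].argmax(axis=1)] = True
        abundance = abundance * keep
    fractions = abundance / abundance.sum(axis=1, keepdims=True)
    lo, hi = spec.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples)).astype(np.int64)
    counts = np.stack(
        [rng.multinomial(depths[i], fractions[i]) for i in range(n_samples)]
    )
    table = AbundanceTable(
        sample_ids=[f"sample_{i:04d}" for i in range(n_samples)],
        taxa=spec.taxa(),
        counts=counts,
        rank="species",
    )
    return table, truth


def default_keystone_scenario(seed: int | None = None) -> CommunitySpec:
    """Community of 40 taxa: 4 positively correlated genus blocks plus a
    single-species keystone genus negatively coupled to one block.

    Taxon 0 is the keystone (its own genus), coupled at -0.5 to all ten
    members of block A and uncoupled elsewhere, so its latent correlation
    row has exactly 10 negative entries and 29 near-zero ones.  Blocks
    have within-block latent correlation 0.6.  Depths are log-uniform in
    [5e4, 2e5]; 120 samples is the recommended size.  The seed only
    randomizes per-taxon mean log-abundances and dropout rates.
    """
    rng = np.random.default_rng(seed)
    n = 40
    block_members = [
        list(range(1, 11)),
        list(range(11, 21)),
        list(range(21, 31)),
        list(range(31, 40)),
    ]
    genus_map: dict[int, str] = {0: "Keystonea"}
    for b, members in enumerate(block_members):
        for i in members:
            genus_map[i] = f"Genus{'ABCD'[b]}"
    log_mean = rng.normal(2.0, 0.8, size=n)
    log_mean[0] = 1.5  # keystone: modest but well-detected abundance
    dropout = rng.uniform(0.0, 0.3, size=n)
    dropout[0] = 0.05
    return CommunitySpec(
        n_taxa=n,
        genus_map=genus_map,
        blocks=[(m, 0.6) for m in block_members],
        keystone_specs=[(0, 0, -0.5)],
        log_mean=log_mean,
        log_var=np.ones(n),
        dropout=dropout,
        depth_range=(5e4, 2e5),
    )


def simulate_transcription(
    k: int,
    samples_per_state: int,
    n_features: int,
    n_informative: int,
    separation: float,
    seed: int | None = None,
    taxon: str = "g__SimGenus.s__SimGenus_sp1",
) -> tuple[TranscriptProfile, np.ndarray]:
    """Transcription profiles drawn from k planted states.

    State centroids share a common baseline and differ only on the
    informative features, offset by ``separation`` times the noise scale
    in state-specific directions; values are gamma-distributed around the
    centroid so they are nonnegative and CPM-normalizable.  Returns the
    raw profile and the true state labels.
    """
    if k < 2:
        raise ValueError("need k >= 2 states")
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    baseline = 100.0
    noise_sd = 10.0
    centroids = np.full((k, n_features), baseline)
    if n_informative < k:
        raise ValueError("need n_informative >= k for distinct states")
    # orthonormal state directions, so `separation` sets every pairwise
    # centroid distance (random directions can be nearly collinear)
    directions, _ = np.linalg.qr(rng.standard_normal((n_informative, k)))
    directions = directions.T[:k]
    centroids[:, :n_informative] += separation * noise_sd * directions
    centroids = np.maximum(centroids, 1.0)
    labels = np.repeat(np.arange(k), samples_per_state)
    mu = centroids[labels]
    shape = (mu / noise_sd) ** 2
    scale = noise_sd**2 / mu
    values = rng.gamma(shape, scale)
    profile = TranscriptProfile(
        taxon=taxon,
        sample_ids=[f"sample_{i:04d}" for i in range(labels.size)],
        feature_ids=[f"EC_{j:03d}" for j in range(n_features)],
        values=values,
    )
    return profile, labels
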