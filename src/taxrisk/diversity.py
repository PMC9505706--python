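"""Alpha and beta diversity: rarefaction, richness/evenness indices,
Bray–Curtis dissimilarity, principal coordinate analysis and PERMANOVA.

Alpha diversity is computed on counts rarefied to a common depth (the
study convention is the minimum sample depth, 1099 reads) so that richness
estimates are not confounded by sequencing effort.  Beta diversity operates
on relative abundances and is summarised by classical metric scaling of the
Bray–Curtis matrix, with group separation tested by a permutational
multivariate ANOVA on the distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1

from taxrisk.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    """Per-sample alpha-diversity indices plus the rarefaction settings used."""

    values: pd.DataFrame  # columns: observed, chao1, shannon, simpson
    depth: int | None = None
    seed: int | None = None


@dataclass
class Ordination:
    """PCoA embedding: coordinates, eigenvalues, proportion explained."""

    coordinates: pd.DataFrame  # samples × axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    arr = np.asarray(counts)
    return pd.DataFrame(arr)


def rarefy(counts, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample's reads to ``depth`` without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Row sums of the result equal ``depth`` exactly; the draw is a
    multivariate hypergeometric, i.e. a uniform subsample of the reads.
    """
    if depth <= 0:
        raise ConfigError(f"rarefaction depth must be positive, got {depth}")
    df = _as_frame(counts)
    mat = df.to_numpy()
    if np.any(mat < 0):
        raise ValidationError("negative counts")
    totals = mat.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(df.index[~keep])
        logger.warning(
            "dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:5],
        )
    if not keep.any():
        raise ValidationError(f"no sample has >= {depth} reads")
    rng = np.random.default_rng(seed)
    out = np.empty((keep.sum(), mat.shape[1]), dtype=np.int64)
    for i, row in enumerate(mat[keep].astype(np.int64)):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=df.index[keep], columns=df.columns)


def alpha_diversity(
    counts, depth: int | None = None, seed: int | None = None
) -> DiversityResult:
    """Observed taxa, Chao1, Shannon (natural log) and Gini–Simpson per sample.

    Simpson is reported as ``1 - sum(p^2)``, the probability that two reads
    drawn at random belong to different taxa.  Chao1 uses singleton and
    doubleton counts: ``S_obs + F1^2 / (2*F2)``, falling back to
    ``S_obs + F1*(F1-1)/2`` when there are no doubletons.
    """
    df = _as_frame(counts)
    if depth is not None:
        df = rarefy(df, depth, seed)
    mat = df.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        bad = list(df.index[totals <= 0])
        raise ValidationError(f"all-zero samples: {bad}")
    p = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    observed = (mat > 0).sum(axis=1)
    chao = np.array([
        _skbio_chao1(row.astype(np.int64), bias_corrected=False)
        for row in mat
    ])
    values = pd.DataFrame(
        {"observed": observed, "chao1": chao, "shannon": shannon,
         "simpson": simpson},
        index=df.index,
    )
    return DiversityResult(values, depth=depth, seed=seed)


def bray_curtis(profiles) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC(x,y) = 1 - 2 Σmin(x,y)/(Σx+Σy)."""
    df = _as_frame(profiles)
    mat = df.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("negative abundances")
    zero_rows = (mat.sum(axis=1) == 0)
    if zero_rows.sum() >= 2:
        raise ValidationError(
            "Bray-Curtis undefined between all-zero samples: "
            f"{list(df.index[zero_rows])[:5]}"
        )
    d = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in df.index])


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposes the double-centred ``-D^2/2`` matrix; coordinates on
    axis j are the j-th eigenvector scaled by ``sqrt(lambda_j)``.  Negative
    eigenvalues (possible for semi-metric dissimilarities like Bray–Curtis)
    are reported but their axes are discarded.
    """
    if n_axes < 1:
        raise ConfigError("n_axes must be >= 1")
    D = np.asarray(dist.data, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    n_pos = int((eigvals > tol).sum())
    if n_axes > n_pos:
        logger.warning(
            "only %d positive-eigenvalue axes available (requested %d)",
            n_pos, n_axes,
        )
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[:n_pos].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return Ordination(frame, eigvals, prop)


def _permanova_stats(D2: np.ndarray, labels: np.ndarray,
                     perm_labels: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``perm_labels`` (n_perm × n label matrix)."""
    n = D2.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    ss_total = D2.sum() / (2 * n)
    ss_within = np.zeros(perm_labels.shape[0])
    for g in groups:
        M = (perm_labels == g).astype(float)
        n_g = M[0].sum()
        quad = ((M @ D2) * M).sum(axis=1) / 2.0
        ss_within += quad / n_g
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational MANOVA on a distance matrix; returns (pseudo-F, p).

    The pseudo-F partitions the total sum of squared distances into among-
    and within-group components.  With ``n_perm`` an integer, p is the
    standard permutation estimate ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``
    over seeded label shuffles; with ``n_perm="exact"`` every permutation of
    the labels is enumerated and p is the exact tail fraction.
    """
    labels = np.asarray(list(groups))
    n = len(labels)
    if n != dist.shape[0]:
        raise ValidationError("group labels must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs >= 2 samples")

    D2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs = float(_permanova_stats(D2, labels, labels[None, :])[0])

    if n_perm == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = _permanova_stats(D2, labels, labels[perms])
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return f_obs, p
    n_perm = int(n_perm)
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    perm_labels = np.array([rng.permutation(labels) for _ in range(n_perm)])
    f_perm = _permanova_stats(D2, labels, perm_labels)
    p = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + n_perm)
    return f_obs, float(p)
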