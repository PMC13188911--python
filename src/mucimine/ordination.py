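"""Unsupervised concordance statistics: PCA, PERMANOVA, Procrustes.

These support the question "do the enzyme-family profiles and the community
(coverage) profiles tell the same story about host status?": PCA/PCoA
ordinate samples, PERMANOVA tests group separation on a distance matrix, and
a symmetric Procrustes superposition with a permutation test measures the
concordance of the two ordinations (r = sqrt(1 - m^2)).

PERMANOVA and the Procrustes test are implemented here directly (they are
the statistics under test elsewhere in the suite, cross-checked against
independent implementations); PCoA of a distance matrix delegates to
scikit-bio and drops axes with negative eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "ProcrustesResult",
    "bray_curtis",
    "pca",
    "pcoa",
    "permanova",
    "procrustes_test",
]


@dataclass
class OrdinationResult:
    """Sample coordinates (samples x axes) plus explained-variance fractions."""

    coordinates: pd.DataFrame
    explained: np.ndarray

    def __post_init__(self) -> None:
        self.explained = np.asarray(self.explained, dtype=float)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class ProcrustesResult:
    m2: float
    r: float
    p_value: float
    n_perm: int


def bray_curtis(abundances: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    d_kl = sum |x_k - x_l| / sum (x_k + x_l); a pair of all-zero samples has
    distance 0 by convention.
    """
    X = np.asarray(abundances, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    tot = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # enforce exact symmetry against fp noise
    ids = [str(s) for s in abundances.index] if isinstance(
        abundances, pd.DataFrame) else None
    return DistanceMatrix(D, ids=ids)


def pca(X: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Column-centered SVD PCA of a samples x features matrix.

    Axis signs are fixed deterministically by making the largest-magnitude
    loading on each axis positive. ``n_axes`` beyond the matrix rank is
    truncated.
    """
    ids = [str(s) for s in X.index] if isinstance(X, pd.DataFrame) else [
        str(i) for i in range(len(X))]
    M = np.asarray(X, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    C = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    k = min(n_axes, rank)
    var = s**2
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    # deterministic sign: largest |loading| positive per axis
    for a in range(k):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U[:, :k] * s[:k]
    coords = pd.DataFrame(
        scores, index=pd.Index(ids, name="sample_id"),
        columns=[f"PC{a + 1}" for a in range(k)])
    return OrdinationResult(coords, explained)


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates of a distance matrix (negative eigenvalues dropped)."""
    with warnings.catch_warnings():
        # skbio warns when asked for all dimensions / on negative eigenvalues;
        # we need the full spectrum and drop negative axes ourselves
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(D, number_of_dimensions=0)
    eig = res.eigvals.values
    pos = eig > 0
    k = min(n_axes, int(pos.sum()))
    coords = res.samples.iloc[:, :k].copy()
    coords.index = pd.Index([str(i) for i in D.ids], name="sample_id")
    coords.columns = [f"PCo{a + 1}" for a in range(k)]
    explained = eig[:k] / eig[pos].sum()
    return OrdinationResult(coords, explained)


def _ss_within(D2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        mask = labels == g
        n_g = int(mask.sum())
        ss += D2[np.ix_(mask, mask)].sum() / (2 * n_g)
    return ss


def permanova(
    D: DistanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with a free label-permutation test.

    Partitions the total sum of squared distances (Gower) into among- and
    within-group parts: SS_T = sum_{k<l} d_kl^2 / n, SS_W summed per group,
    F = (SS_A/(a-1)) / (SS_W/(n-a)). P = (1 + #{perm F >= obs}) / (1 + n_perm).
    """
    ids = [str(i) for i in D.ids]
    if isinstance(groups, Mapping):
        labels = np.array([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("singleton group(s) not allowed in PERMANOVA")
    n = len(ids)
    a = len(uniq)
    D2 = np.asarray(D.data, dtype=float) ** 2
    ss_total = D2.sum() / (2 * n)
    ss_within = _ss_within(D2, labels)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ss_w = _ss_within(D2, perm)
        f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Procrustes residual m^2 for centered, unit-norm configurations."""
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def _prepare_config(M: np.ndarray, d: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape[1] < d:  # pad narrower configuration with zero axes
        M = np.hstack([M, np.zeros((M.shape[0], d - M.shape[1]))])
    C = M - M.mean(axis=0)
    norm = np.linalg.norm(C)
    if norm == 0:
        raise ValueError("degenerate (all-identical) configuration")
    return C / norm


def procrustes_test(
    X_coords: pd.DataFrame,
    Y_coords: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes concordance of two sample-coordinate sets.

    Both configurations are centered and scaled to unit Frobenius norm; the
    optimal rotation minimizes the residual m^2 and r = sqrt(1 - m^2). The
    permutation test re-rotates after permuting the sample rows of Y;
    P = (1 + #{perm r >= observed}) / (1 + n_perm).
    """
    if isinstance(X_coords, pd.DataFrame) and isinstance(Y_coords, pd.DataFrame):
        x_ids = [str(i) for i in X_coords.index]
        y_ids = [str(i) for i in Y_coords.index]
        if set(x_ids) != set(y_ids):
            raise ValueError("coordinate sets cover different samples")
        Y_coords = Y_coords.loc[X_coords.index]
    X = np.asarray(X_coords, dtype=float)
    Y = np.asarray(Y_coords, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations have different numbers of samples")
    d = max(X.shape[1], Y.shape[1])
    Xc = _prepare_config(X, d)
    Yc = _prepare_config(Y, d)
    m2 = _procrustes_m2(Xc, Yc)
    r_obs = float(np.sqrt(1.0 - m2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(Yc.shape[0])
        m2_p = _procrustes_m2(Xc, Yc[perm])
        if np.sqrt(1.0 - m2_p) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return ProcrustesResult(float(m2), r_obs, float(p), n_perm)
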