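"""Prevalence filtering and two-group differential screening.

The screen mirrors a three-stage funnel: (1) drop families that are rare or
sparsely distributed (total abundance and subject-coverage thresholds, both
strict); (2) a supervised PLS-DA of the retained abundance matrix with
stratified k-fold cross-validation, plus a per-feature permutation test on
VIP (variable importance in projection) scores; (3) an unpaired two-sample
t-test per family with Benjamini-Hochberg FDR control. Candidates pass both
the VIP-permutation and the FDR gate and are ranked by total abundance.

The PLS is a NIPALS PLS1 on column-centered X against a {0,1}-encoded group
label (case = 1). With a single response the NIPALS weight for each component
is the (normalized) covariance X_res' y_res, so the first weight vector is
parallel to X' (y - ybar) — a property the test-suite exploits as an oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FilterThresholds",
    "FilterResult",
    "PLSDA",
    "filter_hmms",
    "pls_fit",
    "pls_cv_accuracy",
    "pls_variable_significance",
    "differential_ttest",
    "select_candidates",
    "screen_abundance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Strict lower bounds on total abundance and prevalence (subject coverage)."""

    min_total_abundance: float = 16.0
    min_subject_coverage: int = 5

    def __post_init__(self) -> None:
        if self.min_total_abundance < 0 or self.min_subject_coverage < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterResult:
    retained: list[str]
    table: pd.DataFrame  # columns: total_abundance, subject_coverage, retained


def filter_hmms(T: pd.DataFrame, thresholds: FilterThresholds) -> FilterResult:
    """Retain HMM j iff sum_k T_jk > min_total AND #{k: T_jk > 0} > min_coverage.

    Both inequalities are strict; rows of ``T`` are HMMs, columns samples.
    """
    if (T.values < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    total = T.sum(axis=1)
    coverage = (T > 0).sum(axis=1)
    keep = (total > thresholds.min_total_abundance) & (
        coverage > thresholds.min_subject_coverage
    )
    table = pd.DataFrame(
        {
            "total_abundance": total,
            "subject_coverage": coverage.astype(int),
            "retained": keep,
        },
        index=T.index.copy(),
    )
    return FilterResult(retained=list(T.index[keep].astype(str)), table=table)


def _encode_groups(y: Sequence, positive_label=None) -> tuple[np.ndarray, dict]:
    y = np.asarray(y)
    levels = sorted(map(str, np.unique(y.astype(str))))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if positive_label is None:
        positive_label = "case" if "case" in levels else levels[1]
    if str(positive_label) not in levels:
        raise ValueError(f"positive label {positive_label!r} not in {levels}")
    encoding = {lv: (1.0 if lv == str(positive_label) else 0.0) for lv in levels}
    return np.array([encoding[str(v)] for v in y]), encoding


class PLSDA:
    """NIPALS PLS1 discriminant model for a two-level group label.

    Parameters
    ----------
    n_components : int
        Number of latent components; truncated (with a warning) if the
        centered predictor matrix runs out of rank.
    positive_label : str, optional
        Group encoded as 1 (default ``"case"`` when present, else the
        lexicographically larger level).

    Fitted attributes (sklearn convention, trailing underscore): ``x_weights_``
    (p x a, unit columns), ``x_scores_`` (n x a, mutually orthogonal),
    ``x_loadings_``, ``y_loadings_``, ``x_mean_``, ``y_mean_``, ``coef_``,
    ``vip_`` (VIP score per feature), ``encoding_``.
    """

    def __init__(self, n_components: int = 5, positive_label=None):
        self.n_components = n_components
        self.positive_label = positive_label

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components,
                "positive_label": self.positive_label}

    def set_params(self, **params) -> "PLSDA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "PLSDA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 4:
            raise ValueError("X must be 2-D with at least 4 samples")
        y01, encoding = _encode_groups(y, self.positive_label)
        if len(y01) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        n, p = X.shape
        a_max = min(self.n_components, n - 1, p)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y01.mean()
        E = X - self.x_mean_
        f = y01 - self.y_mean_

        W, Tsc, P, q = [], [], [], []
        tol = 1e-12 * max(1.0, np.abs(E).max()) ** 2
        for _ in range(a_max):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw**2 <= tol:
                break
            w /= nw
            t = E @ w
            tt = t @ t
            if tt <= tol:
                break
            pvec = E.T @ t / tt
            qa = f @ t / tt
            E = E - np.outer(t, pvec)
            f = f - qa * t
            W.append(w)
            Tsc.append(t)
            P.append(pvec)
            q.append(qa)
        if not W:
            raise ValueError("predictor matrix has no usable variance against y")
        if len(W) < self.n_components:
            warnings.warn(
                f"PLS truncated to {len(W)} of {self.n_components} components "
                "(rank deficiency)", RuntimeWarning, stacklevel=2)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(Tsc)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(q)
        self.n_components_ = len(W)
        self.encoding_ = encoding
        # regression coefficients on the original (centered) X scale
        R = self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_)
        self.coef_ = R @ self.y_loadings_
        self.vip_ = self._vip()
        return self

    def _vip(self) -> np.ndarray:
        # VIP_f = sqrt( p * sum_a ssy_a w_fa^2 / sum_a ssy_a ), weights unit-norm
        ssy = self.y_loadings_**2 * (self.x_scores_**2).sum(axis=0)
        p = self.x_weights_.shape[0]
        num = (self.x_weights_**2) @ ssy
        return np.sqrt(p * num / ssy.sum())

    def decision_function(self, X) -> np.ndarray:
        """Continuous prediction of the {0,1} group encoding."""
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Hard labels: decision >= 0.5 -> positive group."""
        score = self.decision_function(X)
        inv = {v: k for k, v in self.encoding_.items()}
        return np.array([inv[1.0] if s >= 0.5 else inv[0.0] for s in score])


def pls_fit(X, y, n_components: int = 5, positive_label=None) -> PLSDA:
    """Fit a NIPALS PLS-DA model (thin wrapper over :class:`PLSDA`)."""
    return PLSDA(n_components=n_components, positive_label=positive_label).fit(X, y)


def pls_cv_accuracy(
    X, y, n_components: int = 5, n_folds: int = 10, seed: int = 0,
    positive_label=None,
) -> float:
    """Stratified k-fold cross-validated classification accuracy of the PLS-DA.

    Prediction uses the 0.5 threshold on the continuous score; the returned
    value is the fraction of held-out samples classified correctly, pooled
    over folds. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for train, test in skf.split(X, y):
            model = PLSDA(n_components, positive_label).fit(X[train], y[train])
            pred = model.predict(X[test])
            correct += int((pred == y[test]).sum())
    return correct / len(y)


def _vip_of(X, y01, n_components: int) -> np.ndarray:
    """VIP scores for pre-encoded y; shared by observed and permuted fits."""
    model = PLSDA(n_components, positive_label="1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model.fit(X, np.where(y01 > 0.5, "1", "0"))
    return model.vip_


def pls_variable_significance(
    X, y, n_components: int = 5, n_perm: int = 999, seed: int = 0,
    positive_label=None,
) -> np.ndarray:
    """Permutation P-value per feature for its VIP score.

    The null distribution is the feature's VIP under refits with
    group labels permuted; P = (1 + #{perm VIP >= observed}) / (1 + n_perm),
    so the attainable floor is 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a usable resolution")
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_groups(y, positive_label)
    observed = _vip_of(X, y01, n_components)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(y01)
        exceed += _vip_of(X, perm, n_components) >= observed
    return (1 + exceed) / (1 + n_perm)


def differential_ttest(
    T: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_alpha: float = 1e-4,
    variant: Literal["pooled", "welch"] = "pooled",
) -> pd.DataFrame:
    """Unpaired two-sided t-test per HMM with Benjamini-Hochberg adjustment.

    ``T`` is HMM x sample; ``groups`` maps sample id -> "case"/"control".
    Returns a frame indexed like ``T`` with columns mean_case, mean_control,
    t_stat, p_raw, q_bh, differential (q < fdr_alpha), enriched_in, and
    t_degenerate for rows where both groups had zero variance (t is then set
    to 0/p to 1 when the means agree, which is the natural limit).
    """
    samples = [str(s) for s in T.columns]
    labels = np.array([groups[s] for s in samples])
    case = T.values[:, labels == "case"].astype(float)
    ctrl = T.values[:, labels == "control"].astype(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1,
                               equal_var=(variant == "pooled"))
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            same = degenerate & np.isclose(mean_case, mean_ctrl)
            t = np.where(same, 0.0, t)
            p = np.where(same, 1.0, p)
            diff_deg = degenerate & ~same  # zero variance, different means
            t = np.where(diff_deg, np.sign(mean_case - mean_ctrl) * np.inf, t)
            p = np.where(diff_deg, 0.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "t_stat": t,
            "p_raw": p,
            "q_bh": q,
            "differential": q < fdr_alpha,
            "enriched_in": np.where(mean_case >= mean_ctrl, "case", "control"),
            "t_degenerate": degenerate,
        },
        index=T.index.copy(),
    )
    return out


def select_candidates(screen: pd.DataFrame) -> pd.DataFrame:
    """Rank HMMs passing both screening gates by total abundance.

    Requires columns ``pls_significant``, ``differential`` and
    ``total_abundance``. Adds an ``outlier`` flag for candidates whose total
    abundance exceeds Q3 + 1.5 IQR of the candidate set (Tukey fence) —
    the rule that singled out the two standout enzymes.
    """
    needed = {"pls_significant", "differential", "total_abundance"}
    missing = needed - set(screen.columns)
    if missing:
        raise ValueError(f"screen table lacks columns {sorted(missing)}")
    cand = screen[screen["pls_significant"] & screen["differential"]].copy()
    if cand.empty:
        logger.info("no candidates pass both screening gates")
        return cand.assign(outlier=pd.Series(dtype=bool))
    cand = cand.sort_values("total_abundance", ascending=False, kind="mergesort")
    q1, q3 = np.percentile(cand["total_abundance"], [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    cand["outlier"] = cand["total_abundance"] > fence
    return cand


def screen_abundance(
    T: pd.DataFrame,
    groups: Mapping[str, str],
    thresholds: FilterThresholds = FilterThresholds(),
    n_components: int = 5,
    n_folds: int = 10,
    n_perm: int = 999,
    pls_alpha: float = 0.05,
    fdr_alpha: float = 1e-4,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Full screening funnel on an abundance matrix.

    Filters, runs PLS-DA (CV accuracy + VIP permutation P on the retained
    families), then the per-family t-test with BH adjustment. Returns the
    per-HMM screen table (all input HMMs; unretained rows carry NaN statistics
    and False flags) and the cross-validated accuracy.
    """
    filt = filter_hmms(T, thresholds)
    table = filt.table.copy()
    for col in ("pls_p", "t_stat", "p_raw", "q_bh", "mean_case", "mean_control"):
        table[col] = np.nan
    table["pls_significant"] = False
    table["differential"] = False
    table["enriched_in"] = ""
    if not filt.retained:
        return table, float("nan")

    Tk = T.loc[filt.retained]
    X = Tk.values.T  # samples x features
    y = np.array([groups[str(s)] for s in Tk.columns])
    accuracy = pls_cv_accuracy(X, y, n_components, n_folds, seed)
    pls_p = pls_variable_significance(X, y, n_components, n_perm, seed)
    tt = differential_ttest(Tk, groups, fdr_alpha)

    table.loc[filt.retained, "pls_p"] = pls_p
    table.loc[filt.retained, "pls_significant"] = pls_p <= pls_alpha
    for col in ("t_stat", "p_raw", "q_bh", "mean_case", "mean_control"):
        table.loc[filt.retained, col] = tt[col].values
    table.loc[filt.retained, "differential"] = tt["differential"].values
    table.loc[filt.retained, "enriched_in"] = tt["enriched_in"].values
    # candidates must clear both gates
    table["candidate"] = table["pls_significant"] & table["differential"]
    return table, accuracy
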