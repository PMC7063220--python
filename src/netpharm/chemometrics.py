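"""Pharmacodynamic-evaluation statistics for animal-cohort index matrices.

The cohort is an animals x indices matrix (whole blood viscosity at five
shear rates, plasma viscosity, and the four coagulation indices TT, PT,
APTT, FIB) with a treatment-group label per row.  The toolbox covers:

* unit-variance autoscaling (column mean 0, variance 1);
* PCA by SVD with per-component explained variance and a cross-validated Q2;
* two-class and multi-class PLS-DA fitted by NIPALS PLS2 against a one-hot
  class matrix, reporting R2X, R2Y and a venetian-blind cross-validated Q2;
* variable importance in projection (VIP), with the VIP > 1 selection rule;
* label-permutation validation of a fitted PLS-DA model;
* ranking of treatment groups by the distance of their score-space centroid
  to a reference (normality) group;
* one-way ANOVA and Welch pairwise comparisons reconstructed from group
  summary statistics (means, SDs, group sizes) alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# scaling

def autoscale(x, ddof: int = 1):
    """Center each column to mean 0 and scale to unit variance.

    Returns ``(scaled, means, sds)``; a DataFrame input yields a DataFrame
    with the same index/columns.  A constant column cannot be scaled and
    raises, naming the column.
    """
    cols = list(x.columns) if isinstance(x, pd.DataFrame) else None
    arr = np.asarray(x, dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        names = [cols[j] if cols else str(j) for j in bad]
        raise ValueError(f"constant column(s) cannot be autoscaled: {', '.join(names)}")
    scaled = (arr - means) / sds
    if cols is not None:
        scaled = pd.DataFrame(scaled, index=x.index, columns=cols)
    return scaled, means, sds


def unscale(scaled, means, sds):
    """Inverse of :func:`autoscale`."""
    arr = np.asarray(scaled, dtype=float) * np.asarray(sds) + np.asarray(means)
    if isinstance(scaled, pd.DataFrame):
        arr = pd.DataFrame(arr, index=scaled.index, columns=scaled.columns)
    return arr


# --------------------------------------------------------------------------
# PCA

@dataclass
class PcaModel:
    """Principal components of a (pre-scaled) matrix."""

    mean: np.ndarray
    scores: np.ndarray          # n x A
    loadings: np.ndarray        # p x A, orthonormal columns
    r2x_per_component: np.ndarray
    q2: float | None
    feature_names: list[str]

    @property
    def r2x(self) -> float:
        return float(self.r2x_per_component.sum())


def pca(x, n_components: int = 2, cv_folds: int | None = 7) -> PcaModel:
    """PCA by singular value decomposition with cross-validated Q2.

    The matrix is centered internally; scaling is the caller's choice
    (apply :func:`autoscale` first for unit-variance PCA).  ``r2x`` per
    component is the fraction of centered sum of squares carried by that
    component.  Q2 is estimated by venetian-blind row cross-validation:
    each held-out block is projected onto the loadings of a model fitted
    without it and Q2 = 1 - PRESS/TSS over all blocks.  Pass
    ``cv_folds=None`` to skip it.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else None
    arr = np.asarray(x, dtype=float)
    n, p = arr.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(rows-1, cols)] = [1, {min(n - 1, p)}]"
        )
    mean = arr.mean(axis=0)
    xc = arr - mean
    total_ss = float((xc**2).sum())
    if total_ss == 0:
        raise ValueError("matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = (u * s)[:, :n_components]
    loadings = vt[:n_components].T
    r2x_per = (s[:n_components] ** 2) / total_ss

    q2 = None
    if cv_folds:
        folds = max(2, min(cv_folds, n - 1))
        press = tss = 0.0
        for f in range(folds):
            test = np.arange(f, n, folds)
            train = np.setdiff1d(np.arange(n), test)
            m = arr[train].mean(axis=0)
            _, _, vt_f = np.linalg.svd(arr[train] - m, full_matrices=False)
            v = vt_f[: min(n_components, vt_f.shape[0])].T
            resid = (arr[test] - m) - (arr[test] - m) @ v @ v.T
            press += float((resid**2).sum())
            tss += float(((arr[test] - m) ** 2).sum())
        q2 = 1.0 - press / tss
    return PcaModel(
        mean, scores, loadings, r2x_per, q2,
        names or [f"x{j}" for j in range(p)],
    )


# --------------------------------------------------------------------------
# PLS-DA (NIPALS PLS2 on a one-hot class matrix)

@dataclass
class PlsdaModel:
    """Fitted PLS-DA model (NIPALS PLS2 against one-hot class dummies).

    Scores ``T`` are mutually orthogonal; ``W`` holds unit-norm X-weights,
    ``P`` X-loadings, ``C`` Y-loadings.  ``ssy_explained`` is the absolute
    Y sum of squares captured by each component (the weights of the VIP
    formula).  ``q2`` is the cumulative venetian-blind cross-validated
    predictive ability; None when cross-validation was disabled.
    """

    classes: tuple
    groups: np.ndarray
    feature_names: list[str]
    n_components: int
    scale: bool
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    T: np.ndarray
    U: np.ndarray
    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray
    ssy_explained: np.ndarray
    q2: float | None

    @property
    def r2x(self) -> float:
        return float(self.r2x_per_component.sum())

    @property
    def r2y(self) -> float:
        return float(self.r2y_per_component.sum())

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B with Yhat_centered = X_scaled @ B."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)

    def transform(self, x) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd
        return xs @ self.W @ np.linalg.inv(self.P.T @ self.W)

    def predict_scores(self, x) -> np.ndarray:
        """Predicted class-dummy matrix for new rows."""
        xs = (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd
        return xs @ self.coef + self.y_mean

    def predict(self, x) -> np.ndarray:
        """Hard class assignment (argmax of the predicted dummies)."""
        idx = np.argmax(self.predict_scores(x), axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def _one_hot(groups) -> tuple[np.ndarray, tuple]:
    groups = np.asarray(groups)
    classes = tuple(sorted(pd.unique(groups)))
    y = np.zeros((groups.size, len(classes)))
    for j, c in enumerate(classes):
        y[groups == c, j] = 1.0
    return y, classes


def _nipals_pls2(x, y, n_components, tol=1e-12, max_iter=1000):
    """NIPALS PLS2 on centered matrices; returns T, U, W, P, C and SS books."""
    x = x.copy()
    y = y.copy()
    n, p = x.shape
    ssx0 = float((x**2).sum())
    ssy0 = float((y**2).sum())
    T, U, W, P, C = [], [], [], [], []
    r2x_per, r2y_per, ssy_abs = [], [], []
    for _ in range(n_components):
        ssy_before = float((y**2).sum())
        if ssy_before <= max(ssy0, 1.0) * 1e-14:
            break  # Y residual exhausted; further components are noise
        u = y[:, int(np.argmax(y.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _it in range(max_iter):
            w = x.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise ValueError("X residual has no covariance with Y; cannot extract component")
            w /= norm_w
            t = x @ w
            c = y.T @ t / (t @ t)
            u = y @ c / (c @ c)
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        pl = x.T @ t / (t @ t)
        x -= np.outer(t, pl)
        y -= np.outer(t, c)
        ssy_after = float((y**2).sum())
        T.append(t)
        U.append(u)
        W.append(w)
        P.append(pl)
        C.append(c)
        r2x_per.append(float(np.outer(t, pl).__pow__(2).sum()) / ssx0)
        r2y_per.append((ssy_before - ssy_after) / ssy0)
        ssy_abs.append(ssy_before - ssy_after)
    stack = lambda v: np.column_stack(v) if v else np.zeros((0, 0))
    return (
        stack(T), stack(U), stack(W), stack(P), stack(C),
        np.asarray(r2x_per), np.asarray(r2y_per), np.asarray(ssy_abs),
    )


def plsda(
    x,
    groups,
    n_components: int = 2,
    cv_folds: int | None = 7,
    scale: bool = True,
) -> PlsdaModel:
    """Fit a PLS-DA model of group membership on an index matrix.

    X is autoscaled (unit variance; ``scale=False`` centers only) and the
    group labels are one-hot encoded and column-centered; a PLS2 model is
    then extracted by NIPALS.  Q2 uses venetian-blind row folds (every
    ``cv_folds``-th row held out in turn), refitting the scaling and the
    model on each training split.  Every group needs >= 2 members.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else None
    arr = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if arr.shape[0] != groups.size:
        raise ValueError("x and groups disagree on the number of rows")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("PLS-DA needs at least two groups")
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"group(s) with < 2 members: {', '.join(map(str, small))}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    def _prep(xa):
        mean = xa.mean(axis=0)
        sd = xa.std(axis=0, ddof=1) if scale else np.ones(xa.shape[1])
        if np.any(sd <= 0):
            raise ValueError("constant column in X; autoscaling undefined")
        return mean, sd

    y, classes = _one_hot(groups)
    x_mean, x_sd = _prep(arr)
    y_mean = y.mean(axis=0)
    T, U, W, P, C, r2x_per, r2y_per, ssy_abs = _nipals_pls2(
        (arr - x_mean) / x_sd, y - y_mean, n_components
    )

    q2 = None
    if cv_folds:
        n = arr.shape[0]
        folds = max(2, min(cv_folds, n - 1))
        press = tss = 0.0
        for f in range(folds):
            test = np.arange(f, n, folds)
            train = np.setdiff1d(np.arange(n), test)
            if np.unique(groups[train]).size < 2:
                continue
            m, s = _prep(arr[train])
            ym = y[train].mean(axis=0)
            Tf, _, Wf, Pf, Cf, *_ = _nipals_pls2(
                (arr[train] - m) / s, y[train] - ym, n_components
            )
            b = Wf @ np.linalg.solve(Pf.T @ Wf, Cf.T)
            yhat = ((arr[test] - m) / s) @ b + ym
            press += float(((y[test] - yhat) ** 2).sum())
            tss += float(((y[test] - ym) ** 2).sum())
        q2 = 1.0 - press / tss

    return PlsdaModel(
        classes=classes,
        groups=groups,
        feature_names=names or [f"x{j}" for j in range(arr.shape[1])],
        n_components=T.shape[1],
        scale=scale,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        T=T, U=U, W=W, P=P, C=C,
        r2x_per_component=r2x_per,
        r2y_per_component=r2y_per,
        ssy_explained=ssy_abs,
        q2=q2,
    )


def vip(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection of a fitted PLS-DA model.

    ``VIP_j = sqrt(p * sum_a(SSY_a * w_ja^2) / sum_a(SSY_a))`` with p the
    variable count and SSY_a the Y sum of squares explained by component a,
    so that ``sum_j VIP_j^2 = p``.  Variables with VIP > 1 contribute more
    than average to the class separation.
    """
    ss = model.ssy_explained
    if ss.size == 0 or ss.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.W.shape[0]
    contrib = (model.W**2) @ ss
    scores = np.sqrt(p * contrib / ss.sum())
    return pd.Series(scores, index=model.feature_names, name="VIP")


# --------------------------------------------------------------------------
# permutation validation

@dataclass
class PermutationValidation:
    """Outcome of a label-permutation test of a PLS-DA model.

    The model is refitted under ``n_perm`` random permutations of the group
    labels.  ``valid`` requires every permuted R2Y and Q2 to fall below the
    unpermuted model's values.  The intercepts come from a straight-line
    regression of the permuted statistics on the permuted-vs-original label
    correlation (the model's own point enters at correlation 1), evaluated
    at correlation 0; a negative Q2 intercept is the classical sign of a
    non-overfitted model.
    """

    r2y_model: float
    q2_model: float
    r2y_perm: np.ndarray
    q2_perm: np.ndarray
    label_correlation: np.ndarray
    r2_intercept: float
    q2_intercept: float
    valid: bool


def permutation_validate(
    x,
    groups,
    n_components: int = 2,
    n_perm: int = 200,
    seed=0,
    cv_folds: int | None = 7,
    scale: bool = True,
) -> PermutationValidation:
    """Validate a PLS-DA model by refitting under permuted group labels."""
    import warnings

    if n_perm < 10:
        warnings.warn("n_perm < 10 gives a very coarse null", stacklevel=2)
    if not cv_folds:
        raise ValueError("permutation validation needs a cross-validated Q2 (cv_folds >= 2)")
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    model = plsda(x, groups, n_components=n_components, cv_folds=cv_folds, scale=scale)
    y0, _ = _one_hot(groups)
    y0c = (y0 - y0.mean(axis=0)).ravel()
    r2s, q2s, corrs = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        m = plsda(x, perm, n_components=n_components, cv_folds=cv_folds, scale=scale)
        yp, _ = _one_hot(perm)
        ypc = (yp - yp.mean(axis=0)).ravel()
        corrs.append(float(abs(ypc @ y0c) / (np.linalg.norm(ypc) * np.linalg.norm(y0c))))
        r2s.append(m.r2y)
        q2s.append(m.q2 if m.q2 is not None else np.nan)
    r2s, q2s, corrs = map(np.asarray, (r2s, q2s, corrs))
    cx = np.append(corrs, 1.0)
    r2_int = float(np.polyval(np.polyfit(cx, np.append(r2s, model.r2y), 1), 0.0))
    q2_int = float(np.polyval(np.polyfit(cx, np.append(q2s, model.q2), 1), 0.0))
    valid = bool(np.all(r2s < model.r2y) and np.all(q2s < model.q2))
    return PermutationValidation(
        model.r2y, model.q2, r2s, q2s, corrs, r2_int, q2_int, valid
    )


# --------------------------------------------------------------------------
# group centroids

def group_distance_ranking(scores, groups, reference_group) -> pd.DataFrame:
    """Rank groups by Euclidean centroid distance to a reference group.

    ``scores`` is the animals x components score matrix (e.g. ``model.T``).
    The reference is typically the control (normality) group; a smaller
    distance means the group sits closer to normality in score space.
    """
    arr = np.atleast_2d(np.asarray(scores, dtype=float))
    groups = np.asarray(groups)
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent")
    cents = {g: arr[groups == g].mean(axis=0) for g in pd.unique(groups)}
    ref = cents[reference_group]
    rows = [
        {"group": g, "distance": float(np.linalg.norm(c - ref))}
        for g, c in cents.items()
        if g != reference_group
    ]
    df = pd.DataFrame(rows).sort_values(["distance", "group"], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# summary-statistic ANOVA

@dataclass
class AnovaSummary:
    """One-way ANOVA and pairwise Welch comparisons from group summaries."""

    anova: pd.DataFrame      # per variable: F, df1, df2, p
    pairwise: pd.DataFrame   # per (variable, group, reference): t, df, p, flags


def _welch_from_summary(m1, s1, n1, m2, s2, n2):
    se2 = s1**2 / n1 + s2**2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def summary_anova(
    group_means: pd.DataFrame,
    group_sds: pd.DataFrame,
    group_ns,
    control_group: str = "control",
    model_group: str = "model",
) -> AnovaSummary:
    """One-way ANOVA per index reconstructed from means, SDs and group sizes.

    ``group_means``/``group_sds`` are groups x variables frames with a
    shared group index; ``group_ns`` maps group -> animals.  Between-group
    sums of squares come from the means and sizes, within-group from the
    SDs, reproducing the raw-data ANOVA exactly.  Pairwise Welch t-tests
    from the same summaries are reported against the control and against
    the disease-model group, flagged at p < 0.05 and p < 0.01.
    """
    ns = pd.Series(group_ns, dtype=float).reindex(group_means.index)
    if ns.isna().any():
        raise ValueError("group_ns missing for some groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (group_sds <= 0).any().any():
        raise ValueError("SDs must be positive")
    k = len(group_means.index)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    ntot = float(ns.sum())
    rows = []
    for var in group_means.columns:
        m = group_means[var].to_numpy(dtype=float)
        s = group_sds[var].to_numpy(dtype=float)
        n = ns.to_numpy()
        grand = float((n * m).sum() / ntot)
        ssb = float((n * (m - grand) ** 2).sum())
        ssw = float(((n - 1) * s**2).sum())
        df1, df2 = k - 1, int(ntot - k)
        if ssb == 0.0:
            f, p = 0.0, 1.0
        else:
            f = (ssb / df1) / (ssw / df2)
            p = float(stats.f.sf(f, df1, df2))
        rows.append({"variable": var, "F": f, "df1": df1, "df2": df2, "p": p})
    anova = pd.DataFrame(rows)

    pair_rows = []
    for ref in (control_group, model_group):
        if ref not in group_means.index:
            continue
        for g in group_means.index:
            if g == ref:
                continue
            for var in group_means.columns:
                t, df, p = _welch_from_summary(
                    group_means.loc[g, var], group_sds.loc[g, var], ns[g],
                    group_means.loc[ref, var], group_sds.loc[ref, var], ns[ref],
                )
                pair_rows.append(
                    {
                        "variable": var, "group": g, "reference": ref,
                        "t": t, "df": df, "p": p,
                        "p_lt_05": p < 0.05, "p_lt_01": p < 0.01,
                    }
                )
    pairwise = pd.DataFrame(
        pair_rows,
        columns=["variable", "group", "reference", "t", "df", "p", "p_lt_05", "p_lt_01"],
    )
    return AnovaSummary(anova, pairwise)
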