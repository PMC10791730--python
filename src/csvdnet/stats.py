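"""Group comparisons and brain-behavior correlations.

Demographics and cognitive scores are compared with one-way ANOVA
(chi-square for sex proportions); network metrics with one-way ANCOVA
controlling age, sex and education, followed by Fisher's LSD post hoc
pairwise tests (model-based t-tests on covariate-adjusted means, no
multiplicity correction).  Correlations between nodal metrics and
cognitive scores are Pearson (or partial, residualizing the covariates)
with Benjamini–Hochberg FDR control per group family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class GroupComparisonResult:
    omnibus_F: float
    omnibus_p: float
    df: tuple[float, float]
    posthoc: dict[tuple[str, str], float]
    adjusted_means: dict[str, float]
    group_order: tuple[str, ...]
    _fit: dict = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    feature: str
    test: str
    r: float
    p: float
    q: float
    n: int
    undefined: bool = False


# ---------------------------------------------------------------------------
# simple omnibus tests

def oneway_anova(values, group_labels) -> tuple[float, float]:
    """One-way between-groups ANOVA; F on (k-1, N-k) degrees of freedom."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = [y[g == lab] for lab in pd.unique(g)]
    if len(groups) < 2 or any(len(gr) < 2 for gr in groups):
        raise ParameterError("ANOVA needs >= 2 groups with >= 2 observations each")
    ssw = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    grand = y.mean()
    ssb = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    df_b, df_w = len(groups) - 1, y.size - len(groups)
    if ssw <= 0:
        if ssb <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0  # perfect separation
    F = (ssb / df_b) / (ssw / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


def oneway_anova_from_summary(ns, means, sds) -> tuple[float, float]:
    """ANOVA reconstructed from per-group (n, mean, SD) summaries.

    Useful for checking published tables where only summaries are printed.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape) or ns.size < 2:
        raise ParameterError("need matching n/mean/SD for >= 2 groups")
    N = ns.sum()
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df_b, df_w = ns.size - 1, N - ns.size
    F = (ssb / df_b) / (ssw / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ParameterError("table must be nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ParameterError("zero row/column marginal in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# ANCOVA + LSD

def _coerce_covariates(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != n:
        raise ParameterError(f"covariates have {len(cov)} rows for {n} observations")
    out = {}
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = pd.unique(s)
            if len(levels) > 2:
                raise ParameterError(
                    f"categorical covariate {col!r} has >2 levels; encode it explicitly"
                )
            out[str(col)] = (s == levels[-1]).astype(float).to_numpy()
        else:
            out[str(col)] = s.astype(float).to_numpy()
    return pd.DataFrame(out)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # identify the first column whose removal restores full rank
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
            raise ParameterError(f"design matrix is rank deficient: column {names[j]!r} is collinear")
    raise ParameterError("design matrix is rank deficient")


def ancova_f_test(values, group_labels, covariates=None) -> GroupComparisonResult:
    """Covariate-adjusted group comparison (one-way ANCOVA) with LSD post hoc.

    Fits ``y ~ group + covariates`` by OLS; the omnibus statistic is the
    partial F for the group factor (model comparison against the
    covariate-only model).  Adjusted group means are evaluated at the
    covariate means; pairwise LSD p-values use the full model's residual
    mean square and degrees of freedom.  With no covariates this reduces
    exactly to one-way ANOVA.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    order = tuple(pd.unique(g))
    if len(order) < 2:
        raise ParameterError("need >= 2 groups")
    cov = _coerce_covariates(covariates, y.size)

    dummies = np.column_stack([(g == lab).astype(float) for lab in order[1:]])
    X_full = np.column_stack([np.ones(y.size), dummies, cov.to_numpy()]) \
        if cov.shape[1] else np.column_stack([np.ones(y.size), dummies])
    names = ["intercept"] + [f"group[{lab}]" for lab in order[1:]] + list(cov.columns)
    _check_full_rank(X_full, names)
    X_red = np.column_stack([np.ones(y.size), cov.to_numpy()]) \
        if cov.shape[1] else np.ones((y.size, 1))

    beta, ssr_full = _ols(X_full, y)
    _, ssr_red = _ols(X_red, y)
    df_num = len(order) - 1
    df_resid = y.size - X_full.shape[1]
    if df_resid <= 0:
        raise ParameterError("not enough observations for the design")
    mse = ssr_full / df_resid
    if mse <= np.finfo(float).tiny:
        F, p = float("inf"), 0.0
        if ssr_red - ssr_full <= 0:
            F, p = 0.0, 1.0
    else:
        F = ((ssr_red - ssr_full) / df_num) / mse
        p = float(sps.f.sf(F, df_num, df_resid))

    cov_means = cov.to_numpy().mean(axis=0) if cov.shape[1] else np.empty(0)

    def design_row(lab):
        d = [1.0] + [1.0 if lab == o else 0.0 for o in order[1:]] + list(cov_means)
        return np.asarray(d)

    adjusted = {lab: float(design_row(lab) @ beta) for lab in order}
    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    fit = {
        "beta": beta,
        "XtX_inv": XtX_inv,
        "mse": mse,
        "df_resid": df_resid,
        "order": order,
        "design_row": design_row,
    }
    result = GroupComparisonResult(
        omnibus_F=float(F),
        omnibus_p=float(p),
        df=(float(df_num), float(df_resid)),
        posthoc={},
        adjusted_means=adjusted,
        group_order=order,
        _fit=fit,
    )
    object.__setattr__(result, "posthoc", lsd_posthoc(result))
    return result


def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def lsd_posthoc(result: GroupComparisonResult) -> dict[tuple[str, str], float]:
    """Unadjusted pairwise t-tests on the covariate-adjusted group means.

    Uses the full model's residual mean square and residual df (Fisher's
    LSD).  For two groups the pairwise p equals the omnibus p (t^2 = F).
    """
    fit = result._fit
    if fit is None:
        raise ParameterError("result carries no fit internals")
    out = {}
    for g1, g2 in combinations(fit["order"], 2):
        c = fit["design_row"](g1) - fit["design_row"](g2)
        se = float(np.sqrt(fit["mse"] * (c @ fit["XtX_inv"] @ c)))
        diff = float(c @ fit["beta"])
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / se
            p = float(2 * sps.t.sf(abs(t), fit["df_resid"]))
        out[(g1, g2)] = p
    return out


# ---------------------------------------------------------------------------
# correlations + FDR

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _partial_corr(x, y, cov: np.ndarray):
    import pingouin as pg

    df = pd.DataFrame({"x": x, "y": y})
    covnames = []
    for j in range(cov.shape[1]):
        df[f"c{j}"] = cov[:, j]
        covnames.append(f"c{j}")
    res = pg.partial_corr(data=df, x="x", y="y", covar=covnames)
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    return float(res["r"].iloc[0]), float(res[pcol].iloc[0])


def pearson_correlations(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    groups,
    *,
    mode: str = "pearson",
    covariates: pd.DataFrame | None = None,
    fdr_scope: str = "group",
) -> list[CorrelationResult]:
    """Correlate every (feature, cognitive test) pair within each group.

    ``mode='pearson'`` uses plain Pearson r; ``mode='partial'`` controls
    the supplied covariates.  q-values are BH-FDR within each group's
    family by default (``fdr_scope='global'`` pools all groups into one
    family).  Zero-variance features or scores yield results flagged
    ``undefined`` and are excluded from the FDR family.
    """
    if mode not in ("pearson", "partial"):
        raise ParameterError(f"unknown correlation mode {mode!r}")
    if mode == "partial" and covariates is None:
        raise ParameterError("partial mode requires covariates")
    g = np.asarray(groups)
    feats = pd.DataFrame(features).reset_index(drop=True)
    scor = pd.DataFrame(scores).reset_index(drop=True)
    cov = _coerce_covariates(covariates, len(feats)) if covariates is not None else None

    results: list[CorrelationResult] = []
    for lab in pd.unique(g):
        sel = g == lab
        n = int(sel.sum())
        block: list[CorrelationResult] = []
        for fcol in feats.columns:
            x = feats.loc[sel, fcol].to_numpy(dtype=float)
            for tcol in scor.columns:
                y = scor.loc[sel, tcol].to_numpy(dtype=float)
                if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                    block.append(CorrelationResult(
                        group=str(lab), feature=str(fcol), test=str(tcol),
                        r=np.nan, p=np.nan, q=np.nan, n=n, undefined=True,
                    ))
                    continue
                if mode == "partial":
                    r, p = _partial_corr(x, y, cov.loc[sel].to_numpy())
                else:
                    r, p = sps.pearsonr(x, y)
                block.append(CorrelationResult(
                    group=str(lab), feature=str(fcol), test=str(tcol),
                    r=float(r), p=float(p), q=np.nan, n=n,
                ))
        if fdr_scope == "group":
            block = _attach_q(block)
        results.extend(block)
    if fdr_scope == "global":
        results = _attach_q(results)
    elif fdr_scope != "group":
        raise ParameterError(f"unknown fdr_scope {fdr_scope!r}")
    return results


def _attach_q(block: list[CorrelationResult]) -> list[CorrelationResult]:
    defined = [i for i, r in enumerate(block) if not r.undefined]
    if not defined:
        return block
    q = bh_fdr([block[i].p for i in defined])
    out = list(block)
    for qi, i in zip(q, defined):
        r = block[i]
        out[i] = CorrelationResult(
            group=r.group, feature=r.feature, test=r.test,
            r=r.r, p=r.p, q=float(qi), n=r.n,
        )
    return out
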