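"""Moderated differential expression under a non-intercept group model.

The model has one coefficient per season-by-condition group (no intercept);
season, condition, and interaction effects are estimated as contrasts of
group means.  Per-feature weighted least squares is combined with
empirical-Bayes variance moderation: the residual variances are shrunk
toward a common prior estimated by matching moments of log s^2 to a scaled
F distribution, and the resulting moderated t-statistics gain the prior
degrees of freedom.  Observation-level precision weights come from the
mean-variance trend (locally weighted regression of sqrt(residual sd) on
average log abundance), so counts enter downstream linear models on the
log-CPM scale with appropriate precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("earlyControl", "earlyPoor", "lateControl", "latePoor")


# ---------------------------------------------------------------------------
# design and contrasts
# ---------------------------------------------------------------------------


def build_design(meta: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Samples x groups indicator matrix (~0 + group, no intercept)."""
    groups = meta[group_col]
    levels = [g for g in GROUP_LEVELS if g in set(groups)]
    if not levels:
        levels = sorted(groups.unique())
    design = pd.DataFrame(0.0, index=meta.index, columns=levels)
    for s, g in groups.items():
        design.loc[s, g] = 1.0
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is not full rank (empty group?)")
    return design


def default_contrasts(columns) -> dict[str, np.ndarray]:
    """Season, condition, and interaction contrasts over the 4 group means."""
    cols = list(columns)
    if set(cols) != set(GROUP_LEVELS):
        raise ValueError(f"expected the 4 groups {GROUP_LEVELS}, got {cols}")
    c = {g: np.zeros(len(cols)) for g in GROUP_LEVELS}
    for g in GROUP_LEVELS:
        v = np.zeros(len(cols))
        v[cols.index(g)] = 1.0
        c[g] = v
    return {
        "condition": (c["earlyPoor"] + c["latePoor"]) / 2
        - (c["earlyControl"] + c["lateControl"]) / 2,
        "season": (c["lateControl"] + c["latePoor"]) / 2
        - (c["earlyControl"] + c["earlyPoor"]) / 2,
        "interaction": (c["latePoor"] - c["lateControl"])
        - (c["earlyPoor"] - c["earlyControl"]),
    }


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)
# ---------------------------------------------------------------------------


def precision_weights(
    logcpm: pd.DataFrame, design: pd.DataFrame, span: float = 0.5
) -> pd.DataFrame:
    """Per-observation weights from the fitted mean-variance trend.

    Fits each feature by ordinary least squares, regresses sqrt(residual
    standard deviation) on mean log abundance with a locally weighted
    smoother, and evaluates the trend at each observation's fitted value;
    the weight is the predicted fourth inverse power.  With fewer than 10
    features the trend is unreliable and equal weights are returned.
    """
    y = logcpm.to_numpy(float)
    x = design.to_numpy(float)
    n, p = x.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    if y.shape[0] < 10:
        logger.warning("fewer than 10 features: falling back to equal weights")
        return pd.DataFrame(1.0, index=logcpm.index, columns=logcpm.columns)

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # features x p
    fitted = beta @ x.T
    resid = y - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    mean_abund = y.mean(axis=1)

    sy = np.sqrt(sd)
    trend = lowess(sy, mean_abund, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # collapse duplicate abscissae so interpolation is well defined
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    if tx.size < 2 or np.ptp(ty) < 1e-12:
        w = np.full_like(y, float(np.mean(sy) ** -4) if np.mean(sy) > 0 else 1.0)
        return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)

    pred = np.interp(fitted, tx, ty)
    pred = np.clip(pred, max(1e-6, float(ty[ty > 0].min(initial=1e-6)) * 1e-3), None)
    w = pred ** -4
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModerationParams:
    """Prior df d0 and prior variance s0^2 of the moderation prior."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s_sq: np.ndarray, df: float) -> ModerationParams:
    """Moment-match log s^2 to a scaled F / log-chi-square prior.

    Returns (d0, s0^2); d0 = inf (full shrinkage to a common variance) when
    the observed spread of log s^2 is no larger than its sampling noise.
    """
    ok = s_sq > 0
    if ok.sum() < 2:
        return ModerationParams(np.inf, float(np.mean(s_sq[ok])) if ok.any() else 1.0)
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return ModerationParams(np.inf, float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0, s0_sq)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-contrast moderated test tables plus the moderation prior."""

    tables: dict[str, pd.DataFrame]
    moderation: ModerationParams
    residual_df: float


def fit_moderated(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: dict[str, np.ndarray] | None = None,
    weights: pd.DataFrame | None = None,
    moderation: ModerationParams | None = None,
) -> DEResult:
    """Per-feature weighted least squares with moderated t contrasts.

    The posterior variance is (d0*s0^2 + d*s^2) / (d0 + d) and the
    moderated t carries d0 + d degrees of freedom.  Passing ``moderation``
    overrides the moment estimator (d0 = 0 reproduces the ordinary t).
    """
    x = design.to_numpy(float)
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("singular design matrix")
    if contrasts is None:
        contrasts = default_contrasts(design.columns)
    y = logcpm.to_numpy(float)
    g = y.shape[0]
    w = np.ones_like(y) if weights is None else weights.to_numpy(float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    cnames = list(contrasts)
    cmat = np.stack([np.asarray(contrasts[c], float) for c in cnames])  # c x p
    est = np.empty((g, len(cnames)))
    se_unscaled = np.empty((g, len(cnames)))
    s_sq = np.empty(g)
    for i in range(g):
        wi = w[i]
        xtw = x.T * wi
        xtwx = xtw @ x
        xtwx_inv = np.linalg.inv(xtwx)
        beta = xtwx_inv @ (xtw @ y[i])
        resid = y[i] - x @ beta
        s_sq[i] = float(np.sum(wi * resid ** 2) / df)
        est[i] = cmat @ beta
        se_unscaled[i] = np.sqrt(np.einsum("cp,pq,cq->c", cmat, xtwx_inv, cmat))

    mod = moderation if moderation is not None else estimate_moderation(s_sq, df)
    if np.isinf(mod.d0):
        post_var = np.full(g, mod.s0_sq)
        total_df = np.inf
    else:
        post_var = (mod.d0 * mod.s0_sq + df * s_sq) / (mod.d0 + df)
        total_df = mod.d0 + df
    post_var = np.maximum(post_var, 1e-300)

    ave_expr = y.mean(axis=1)
    tables = {}
    for j, cname in enumerate(cnames):
        t = est[:, j] / (np.sqrt(post_var) * se_unscaled[:, j])
        pval = 2.0 * stats.t.sf(np.abs(t), total_df)
        tables[cname] = pd.DataFrame(
            {
                "logFC": est[:, j],
                "t": t,
                "p": pval,
                "padj": bh_adjust(pval),
                "ave_expr": ave_expr,
            },
            index=logcpm.index,
        )
    return DEResult(tables=tables, moderation=mod, residual_df=df)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_summary(result: DEResult, alphas=(0.05, 0.1)) -> pd.DataFrame:
    """Counts of up/down features per contrast at each adjusted-p threshold."""
    rows = []
    for cname, tab in result.tables.items():
        row = {"contrast": cname}
        for a in alphas:
            sig = tab["padj"] < a
            row[f"up_{a}"] = int((sig & (tab["logFC"] > 0)).sum())
            row[f"down_{a}"] = int((sig & (tab["logFC"] < 0)).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("contrast")
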