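"""Subject-level feature table and the two-stage statistics.

Stage 1 screens the candidate EEG features (ROI band powers and network-AUC
metrics, six bands each) with an L1-penalised linear model (LASSO) whose
penalty λ is tuned by K-fold cross-validation at the minimum-CV-error
criterion (the ``lambda.min`` convention).  Stage 2 correlates every
selected feature with the motor threshold, routing each pair to Pearson's r
when both variables pass the Shapiro–Wilk normality test at α and to
Spearman's ρ otherwise.  Significance is two-sided at p < 0.05 per test; a
Benjamini–Hochberg adjustment is available but off by default, matching the
per-test convention of the analysis this mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .spectral import DEFAULT_BANDS

TARGETS = ("RMT", "AMT")
NETWORK_METRICS = ("cc_global", "eff_global", "cc_nodal_roi", "eff_nodal_roi")


class AssociationError(ValueError):
    pass


# --------------------------------------------------------------------------
# feature table
# --------------------------------------------------------------------------

def feature_columns(band_names=None) -> list[str]:
    """Deterministic predictor column order: powers first, then the four
    network AUC metrics, band-major within each block."""
    bands = list(band_names) if band_names is not None else [
        b.name for b in DEFAULT_BANDS
    ]
    cols = [f"power_{b}" for b in bands]
    for metric in NETWORK_METRICS:
        cols += [f"{metric}_auc_{b}" for b in bands]
    return cols


def assemble_features(
    roi_power: pd.DataFrame,
    network_auc: pd.DataFrame,
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-subject ROI powers, network AUCs and motor thresholds.

    Parameters
    ----------
    roi_power
        Indexed by subject id, columns ``power_<band>``.
    network_auc
        Indexed by subject id, columns ``<metric>_auc_<band>``.
    targets
        Indexed by subject id, columns ``RMT`` and ``AMT`` (%MSO).

    Returns a table with stable column order; raises on duplicated or
    mismatched subject ids and on missing values.
    """
    for frame, name in ((roi_power, "roi_power"), (network_auc, "network_auc"),
                        (targets, "targets")):
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise AssociationError(f"duplicated subject ids in {name}: {dupes}")
    ids = roi_power.index
    for frame, name in ((network_auc, "network_auc"), (targets, "targets")):
        missing = ids.difference(frame.index).tolist()
        extra = frame.index.difference(ids).tolist()
        if missing or extra:
            raise AssociationError(
                f"subject mismatch in {name}: missing={missing} extra={extra}"
            )
    bands = [c.removeprefix("power_") for c in roi_power.columns]
    cols = feature_columns(bands)
    table = pd.concat(
        [roi_power, network_auc.loc[ids], targets.loc[ids][list(TARGETS)]], axis=1
    )
    try:
        table = table[cols + list(TARGETS)]
    except KeyError as err:
        raise AssociationError(f"missing feature columns: {err}") from err
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise AssociationError(f"missing values for subjects {bad}")
    if (table[list(TARGETS)] <= 0).any().any():
        raise AssociationError("motor thresholds must be positive %MSO")
    return table


# --------------------------------------------------------------------------
# LASSO screening
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LassoFit:
    """CV-tuned LASSO fit at λ-min."""

    target: str
    lambdas: np.ndarray          # descending λ grid
    cv_mse: np.ndarray           # mean CV MSE per λ
    lambda_min: float
    coef_standardized: dict[str, float]
    coef_original: dict[str, float]
    intercept: float
    selected: tuple[str, ...]
    cv_seed: int
    dropped_constant: tuple[str, ...] = field(default=())


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                eps: float = 1e-4) -> np.ndarray:
    """Log-spaced λ grid from λ_max (smallest λ that zeroes every
    coefficient, max_j |x_jᵀy| / n for standardised X and centred y) down to
    eps·λ_max."""
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:
        raise AssociationError("target is orthogonal to every predictor")
    return np.geomspace(lam_max, eps * lam_max, n_lambdas)


def fit_lasso_at(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coordinate-descent LASSO coefficients at a fixed penalty λ for the
    objective (1/2n)‖y − Xβ‖² + λ‖β‖₁ (no intercept; X, y pre-processed)."""
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def lasso_select(
    table: pd.DataFrame,
    target: str,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    eps: float = 1e-4,
) -> LassoFit:
    """LASSO screening of the EEG features for one motor threshold.

    Predictors are z-scored internally and the target centred; λ is chosen
    as the grid value minimising the mean K-fold CV MSE, with ties broken
    toward the larger (sparser) λ.  Features with a non-zero coefficient at
    λ-min form the selected set.
    """
    if target not in TARGETS:
        raise AssociationError(f"target must be one of {TARGETS}")
    predictors = [c for c in table.columns if c not in TARGETS]
    n = len(table)
    if n <= folds:
        raise AssociationError(f"n={n} subjects cannot support {folds}-fold CV")
    X_raw = table[predictors].to_numpy(dtype=float)
    y_raw = table[target].to_numpy(dtype=float)

    sd = X_raw.std(axis=0, ddof=0)
    constant = sd == 0
    dropped = tuple(np.array(predictors)[constant])
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}", stacklevel=2)
        predictors = [p for p, c in zip(predictors, ~constant) if c]
        X_raw = X_raw[:, ~constant]
        sd = sd[~constant]
    mu = X_raw.mean(axis=0)
    X = (X_raw - mu) / sd
    y_mean = y_raw.mean()
    y = y_raw - y_mean

    lambdas = lambda_grid(X, y, n_lambdas, eps)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(cv.split(X)):
        _, coefs, _ = lasso_path(X[tr], y[tr], alphas=lambdas, max_iter=50_000)
        # lasso_path returns coefs for alphas in descending order = our grid
        pred = X[te] @ coefs
        resid = pred - y[te][:, None]
        sq_err[f] = np.mean(resid**2, axis=0)
    cv_mse = sq_err.mean(axis=0)
    # grid is descending; argmin returns the first (largest-λ) minimiser
    best = int(np.argmin(cv_mse))
    lam_min = float(lambdas[best])
    coef = fit_lasso_at(X, y, lam_min)
    coef_std = dict(zip(predictors, coef))
    coef_orig = dict(zip(predictors, coef / sd))
    selected = tuple(p for p, c in coef_std.items() if c != 0.0)
    intercept = float(y_mean - np.sum((coef / sd) * mu))
    return LassoFit(
        target, lambdas, cv_mse, lam_min, coef_std, coef_orig,
        intercept, selected, seed, dropped,
    )


# --------------------------------------------------------------------------
# normality-routed correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    target: str
    method: str           # "pearson" | "spearman"
    coefficient: float
    p_value: float
    x_normal: bool
    y_normal: bool

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise AssociationError("correlation coefficient outside [-1, 1]")


def normality_route(x, y, alpha: float = 0.05) -> tuple[str, bool, bool]:
    """Pick the correlation method: Pearson iff both samples pass the
    Shapiro–Wilk test (p > α), else Spearman.  A constant sample routes to
    Spearman with a warning (the test is undefined there)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise AssociationError("need at least 3 observations per sample")
    flags = []
    for sample in (x, y):
        if np.ptp(sample) == 0:
            warnings.warn("constant sample: Shapiro-Wilk undefined, "
                          "routing to Spearman", stacklevel=2)
            flags.append(False)
        else:
            flags.append(bool(stats.shapiro(sample).pvalue > alpha))
    method = "pearson" if all(flags) else "spearman"
    return method, flags[0], flags[1]


def correlate(
    x, y, method: str | None = None,
    feature: str = "x", target: str = "y", alpha: float = 0.05,
) -> CorrelationResult:
    """Two-sided Pearson or Spearman correlation; ``method=None`` routes via
    the normality test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AssociationError("samples must have equal length")
    if len(x) < 3:
        raise AssociationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("zero-variance sample has no correlation")
    if method is None:
        method, xn, yn = normality_route(x, y, alpha)
    else:
        _, xn, yn = normality_route(x, y, alpha)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise AssociationError(f"unknown method {method!r}")
    return CorrelationResult(
        feature, target, method, float(res.statistic), float(res.pvalue), xn, yn
    )


def correlate_selected(
    table: pd.DataFrame, fit: LassoFit, alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Routed correlations of every LASSO-selected feature against the fit's
    target, as a tidy frame.  ``fdr=True`` appends Benjamini–Hochberg
    adjusted p-values (off by default)."""
    rows = []
    for feat in fit.selected:
        r = correlate(table[feat], table[fit.target],
                      feature=feat, target=fit.target, alpha=alpha)
        rows.append({
            "feature": r.feature, "target": r.target, "method": r.method,
            "coefficient": r.coefficient, "p_value": r.p_value,
            "significant": r.p_value < alpha,
        })
    out = pd.DataFrame(
        rows, columns=["feature", "target", "method", "coefficient",
                       "p_value", "significant"],
    )
    if fdr and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, out["p_value"].iloc[idx] * m / rank)
            adj[idx] = prev
        out["p_adjusted"] = adj
    return out


# --------------------------------------------------------------------------
# descriptive summary
# --------------------------------------------------------------------------

def summarize_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± SD of every EEG metric per band, plus motor-threshold
    descriptives (min, max, mean, SD).  Layout: rows are the metric families
    (power, global CC/efficiency, nodal CC/efficiency over the ROI), columns
    band × {mean, sd}."""
    if len(table) < 2:
        raise AssociationError("need at least 2 subjects to summarise")
    bands = [c.removeprefix("power_") for c in table.columns
             if c.startswith("power_")]
    families = {
        "power": "power_{b}",
        "cc_global": "cc_global_auc_{b}",
        "eff_global": "eff_global_auc_{b}",
        "cc_nodal_roi": "cc_nodal_roi_auc_{b}",
        "eff_nodal_roi": "eff_nodal_roi_auc_{b}",
    }
    cols = pd.MultiIndex.from_product([bands, ["mean", "sd"]],
                                      names=["band", "stat"])
    metrics = pd.DataFrame(index=list(families), columns=cols, dtype=float)
    for fam, pattern in families.items():
        for b in bands:
            col = pattern.format(b=b)
            if col in table.columns:
                metrics.loc[fam, (b, "mean")] = table[col].mean()
                metrics.loc[fam, (b, "sd")] = table[col].std(ddof=1)
    rows = []
    for t in TARGETS:
        if t in table.columns:
            s = table[t]
            rows.append({"target": t, "min": s.min(), "max": s.max(),
                         "mean": s.mean(), "sd": s.std(ddof=1)})
    return metrics, pd.DataFrame(rows).set_index("target")
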