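"""Logistic models of high-severity fire with spatially robust uncertainty.

The modeling surface mirrors the analysis design the package implements:

* a pixel table (one row per retained 30 m pixel) with a binary
  high-severity outcome, continuous covariates standardized to mean 0 /
  sd 1, and categorical ownership and fire-identity terms;
* maximum-likelihood binomial GLMs fit by iteratively reweighted least
  squares, with interactions between the hot-dry-windy index and four of
  the five structure metrics (never homogeneity, which is collinear with
  density);
* percentile confidence intervals from a spatial block bootstrap —
  square blocks tile the landscape and whole blocks are resampled with
  replacement, so that within-block spatial autocorrelation does not
  deflate the uncertainty the way an i.i.d. bootstrap would;
* spatially blocked k-fold assignment and log-loss/AUC evaluation for a
  pluggable classifier;
* equal-sample kernel-density differences for comparing covariate
  distributions between ownership classes.

Fire severity is a contagious spatial process; all uncertainty here is
therefore block-based by default. Setting the block side to one pixel
recovers the ordinary (naive) bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "BlockSpec",
    "standardize",
    "subsample",
    "build_design",
    "fit_logistic",
    "assign_blocks",
    "block_bootstrap_ci",
    "odds_ratio",
    "predict_probability",
    "spatial_kfold",
    "evaluate_classifier",
    "density_difference",
]


# ---------------------------------------------------------------------------
# Table preparation
# ---------------------------------------------------------------------------


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None, *, keep_raw: bool = True
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale continuous columns to mean 0, sd 1 (population sd).

    Returns the transformed table and a ``{column: (mean, sd)}`` map for
    back-transformation. Raw values are kept as ``<col>_raw`` columns.
    A constant column is an error.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if pd.api.types.is_float_dtype(table[c]) and not c.endswith("_raw")
        ]
    out = table.copy()
    stats: dict[str, tuple[float, float]] = {}
    for col in columns:
        v = out[col].to_numpy(float)
        mu = float(np.mean(v))
        sd = float(np.std(v))  # population sd
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        if keep_raw:
            out[col + "_raw"] = v
        out[col] = (v - mu) / sd
        stats[col] = (mu, sd)
    return out, stats


def subsample(table: pd.DataFrame, fraction: float = 0.25, *, seed=None) -> pd.DataFrame:
    """Uniform random subsample without replacement of floor(n*fraction) rows."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(np.floor(len(table) * fraction))
    if n == 0:
        raise ValueError("subsample would be empty")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    return table.iloc[np.sort(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model specification and design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one logistic model.

    ``interactions`` are pairs of standardized main-effect columns whose
    product enters the design (named ``"a:b"``). ``categoricals`` maps a
    column to its reference level (``None`` = first level in sorted
    order); non-reference levels enter as dummies named ``"col=level"``.
    """

    outcome: str = "high_severity"
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    categoricals: tuple[tuple[str, str | None], ...] = ()
    scale: str = "stand"

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if "homogeneity" in (a, b) and "hdw" in (a, b):
                raise ValueError(
                    "homogeneity does not interact with the hot-dry-windy index"
                )

    def term_names(self, table: pd.DataFrame) -> list[str]:
        names = ["intercept"]
        names += list(self.covariates)
        names += [f"{a}:{b}" for a, b in self.interactions]
        for col, ref in self.categoricals:
            levels = sorted(table[col].astype(str).unique())
            ref = levels[0] if ref is None else ref
            names += [f"{col}={lv}" for lv in levels if lv != ref]
        return names


def structure_model_spec(
    scale: str = "stand",
    *,
    include_fire_id: bool = True,
    include_cwd: bool = True,
) -> ModelSpec:
    """The structure GLM: five structure metrics, weather, topography,
    incoming severity, and the four HDW-by-structure interactions."""
    covs = [
        "stem_density",
        "mean_height",
        "mean_gap_area",
        "homogeneity",
        "ladder_index",
        "hdw",
        "fuel_moisture",
        "slope",
        "tpi",
        "heat_load",
        "incoming_severity",
    ]
    if include_cwd:
        covs.append("cwd")
    inter = (
        ("hdw", "stem_density"),
        ("hdw", "mean_height"),
        ("hdw", "mean_gap_area"),
        ("hdw", "ladder_index"),
    )
    cats: list[tuple[str, str | None]] = []
    if include_fire_id:
        cats.append(("fire_id", None))
    return ModelSpec(
        covariates=tuple(covs), interactions=inter, categoricals=tuple(cats), scale=scale
    )


def ownership_model_spec(*, include_fire_id: bool = True, include_cwd: bool = True) -> ModelSpec:
    """The ownership GLM: ownership contrasts plus weather/topography controls."""
    covs = ["hdw", "fuel_moisture", "slope", "tpi", "heat_load", "incoming_severity"]
    if include_cwd:
        covs.append("cwd")
    cats: list[tuple[str, str | None]] = [("ownership", "public")]
    if include_fire_id:
        cats.append(("fire_id", None))
    return ModelSpec(covariates=tuple(covs), categoricals=tuple(cats), scale="stand")


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix X, outcome y, and term names for a model spec."""
    n = len(table)
    cols = [np.ones(n)]
    for c in spec.covariates:
        cols.append(table[c].to_numpy(float))
    for a, b in spec.interactions:
        cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
    for col, ref in spec.categoricals:
        vals = table[col].astype(str).to_numpy()
        levels = sorted(np.unique(vals))
        ref = levels[0] if ref is None else ref
        for lv in levels:
            if lv != ref:
                cols.append((vals == lv).astype(float))
    X = np.column_stack(cols)
    y = table[spec.outcome].to_numpy(float)
    return X, y, spec.term_names(table)


# ---------------------------------------------------------------------------
# IRLS logistic fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Point estimates (standardized log-odds) with optional bootstrap CIs."""

    params: pd.Series
    converged: bool
    n: int
    deviance: float
    n_iter: int
    separation: bool = False
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None
    replicates: pd.DataFrame | None = None
    n_replicates_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.params})
        out["odds_ratio"] = np.exp(self.params)
        if self.ci_lower is not None:
            out["ci_lower"] = self.ci_lower
            out["ci_upper"] = self.ci_upper
        return out

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
            "n": int(self.n),
            "deviance": float(self.deviance),
            "n_iter": int(self.n_iter),
            "n_replicates_dropped": int(self.n_replicates_dropped),
            "meta": self.meta,
        }
        if self.ci_lower is not None:
            d["ci_lower"] = self.ci_lower.to_dict()
            d["ci_upper"] = self.ci_upper.to_dict()
        return d


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    beta = np.zeros(X.shape[1]) if start is None else start.copy()
    deviance = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError("design matrix is rank deficient") from exc
        mu_new = expit(np.clip(X @ beta, -30.0, 30.0))
        mu_new = np.clip(mu_new, 1e-12, 1.0 - 1e-12)
        new_dev = -2.0 * float(y @ np.log(mu_new) + (1.0 - y) @ np.log(1.0 - mu_new))
        if abs(new_dev - deviance) <= tol * (abs(new_dev) + 0.1):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    return beta, deviance, it, converged


def fit_logistic(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood logit fit by IRLS (deviance tolerance 1e-8).

    Raises on a single-class outcome or a rank-deficient design;
    quasi-separation (runaway coefficients) is flagged, not raised.
    """
    X, y, names = build_design(table, spec)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    beta, deviance, n_iter, converged = _irls(X, y, tol=tol, max_iter=max_iter, start=start)
    # quasi-separation: runaway coefficients or an essentially perfect fit
    separation = bool(np.max(np.abs(beta)) > 25.0 or deviance < 1e-6 * len(y))
    if separation or not converged:
        logger.warning(
            "logistic fit flagged: converged=%s separation=%s", converged, separation
        )
    return FitResult(
        params=pd.Series(beta, index=names),
        converged=converged,
        n=len(y),
        deviance=deviance,
        n_iter=n_iter,
        separation=separation,
    )


def odds_ratio(coefficient: float) -> float:
    """exp(beta): multiplicative change in odds per 1-sd covariate change."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coefficient))


def predict_probability(fit: FitResult, covariates: dict | pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor at standardized values.

    ``covariates`` maps term names (as in ``fit.params``, e.g. ``"hdw"``,
    ``"hdw:stem_density"``, ``"ownership=private_industrial"``) to
    values; missing terms default to 0 (their standardized mean /
    reference level), unknown terms are an error.
    """
    if isinstance(covariates, dict):
        if not covariates:
            covariates = pd.DataFrame(index=[0])
        else:
            covariates = pd.DataFrame(
                {k: np.atleast_1d(v) for k, v in covariates.items()}
            )
    lp = np.zeros(len(covariates))
    for name in covariates.columns:
        if name not in fit.params.index:
            raise KeyError(f"unknown covariate {name!r}")
        lp += fit.params[name] * covariates[name].to_numpy(float)
    lp += fit.params["intercept"]
    return expit(lp)


# ---------------------------------------------------------------------------
# Spatial blocks and the block bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """Square spatial tiling; every pixel belongs to exactly one block."""

    block_side: float
    x0: float
    y0: float

    def block_of(self, x, y) -> np.ndarray:
        """Packed (row, col) block index; half-open tiling, so a point on
        a boundary belongs to the higher-index block."""
        bx = np.floor((np.asarray(x, float) - self.x0) / self.block_side).astype(np.int64)
        by = np.floor((np.asarray(y, float) - self.y0) / self.block_side).astype(np.int64)
        return by * (1 << 20) + bx


def assign_blocks(
    table: pd.DataFrame,
    block_side: float = 990.0,
    *,
    origin: tuple[float, float] | None = None,
    x_col: str = "x",
    y_col: str = "y",
) -> tuple[BlockSpec, np.ndarray]:
    """Tile the extent with square blocks and label every row.

    Half-open tiling by ``floor((x - x0) / side)``: a point exactly on a
    block boundary belongs to the higher-index block. The default side
    of 990 m (33 pixels) comfortably exceeds the stand-scale window.
    Returns the spec and a dense integer block id per row.
    """
    if block_side <= 0:
        raise ValueError("block_side must be positive")
    x = table[x_col].to_numpy(float)
    y = table[y_col].to_numpy(float)
    x0, y0 = (float(x.min()), float(y.min())) if origin is None else origin
    spec = BlockSpec(block_side=block_side, x0=x0, y0=y0)
    raw = spec.block_of(x, y)
    _, dense = np.unique(raw, return_inverse=True)
    return spec, dense


def block_bootstrap_ci(
    table: pd.DataFrame,
    spec: ModelSpec,
    block_ids: np.ndarray,
    *,
    B: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> FitResult:
    """Percentile CIs from a spatial block bootstrap of the logistic fit.

    Blocks are resampled with replacement (as many as exist), their
    member rows concatenated, and the model refit; the 2.5/97.5
    percentiles of each coefficient across replicates form the 95% CI.
    Replicates whose outcome collapses to a single class are dropped and
    counted. Block ids of one-pixel blocks give the ordinary bootstrap.
    """
    if B < 200:
        raise ValueError("at least 200 replicates are required for percentile CIs")
    if B < 1000:
        warnings.warn(f"B={B} is small for stable percentile CIs", stacklevel=2)
    rng = np.random.default_rng(seed)
    block_ids = np.asarray(block_ids)
    if len(block_ids) != len(table):
        raise ValueError("block_ids must label every row of the table")

    full = fit_logistic(table, spec)
    X, y, names = build_design(table, spec)
    n_blocks = block_ids.max() + 1
    members = [np.flatnonzero(block_ids == b) for b in range(n_blocks)]

    start = full.params.to_numpy()
    reps = np.full((B, len(names)), np.nan)
    dropped = 0
    for b in range(B):
        draw = rng.integers(0, n_blocks, n_blocks)
        idx = np.concatenate([members[j] for j in draw])
        yb = y[idx]
        if yb.min() == yb.max():
            dropped += 1
            continue
        try:
            beta, _, _, _ = _irls(X[idx], yb, start=start)
        except ValueError:
            # e.g. a categorical level absent from the replicate
            dropped += 1
            continue
        reps[b] = beta
    if dropped > 0.10 * B:
        warnings.warn(
            f"{dropped}/{B} bootstrap replicates dropped (single-class outcome)",
            stacklevel=2,
        )
    good = reps[~np.isnan(reps[:, 0])]
    if len(good) == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo = np.percentile(good, 100 * alpha / 2, axis=0)
    hi = np.percentile(good, 100 * (1 - alpha / 2), axis=0)
    full.ci_lower = pd.Series(lo, index=names)
    full.ci_upper = pd.Series(hi, index=names)
    full.replicates = pd.DataFrame(good, columns=names)
    full.n_replicates_dropped = dropped
    full.meta.update({"B": B, "alpha": alpha, "n_blocks": int(n_blocks)})
    return full


# ---------------------------------------------------------------------------
# Spatial folds and classifier evaluation
# ---------------------------------------------------------------------------


def spatial_kfold(block_ids: np.ndarray, k: int, *, seed=None) -> np.ndarray:
    """Partition blocks (not rows) into k folds; rows inherit their block's fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    block_ids = np.asarray(block_ids)
    blocks = np.unique(block_ids)
    if k > len(blocks):
        raise ValueError(f"k={k} exceeds the number of blocks ({len(blocks)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(blocks)
    fold_of_block = np.empty(blocks.max() + 1, dtype=np.int64)
    for i, b in enumerate(perm):
        fold_of_block[b] = i % k
    return fold_of_block[block_ids]


def evaluate_classifier(probabilities: np.ndarray, outcomes: np.ndarray) -> dict[str, float]:
    """Log-loss and AUC of predicted probabilities against 0/1 outcomes."""
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if y.min() == y.max():
        raise ValueError("AUC undefined for single-class outcomes")
    log_loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    auc = float(roc_auc_score(y, p))
    return {"log_loss": log_loss, "auc": auc}


# ---------------------------------------------------------------------------
# Density differences across ownerships
# ---------------------------------------------------------------------------


def density_difference(
    values_a: np.ndarray,
    values_b: np.ndarray,
    *,
    grid: np.ndarray | None = None,
    n_grid: int = 256,
    bw_method="scott",
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference of kernel densities after equalizing sample sizes.

    The larger sample is subsampled (without replacement, seeded) to the
    size of the smaller; Gaussian KDEs are evaluated on a shared grid and
    differenced (A minus B). Positive regions are overrepresented in A.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    rng = np.random.default_rng(seed)
    m = min(len(a), len(b))
    if len(a) > m:
        a = rng.choice(a, size=m, replace=False)
    if len(b) > m:
        b = rng.choice(b, size=m, replace=False)
    if grid is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        span = hi - lo if hi > lo else 1.0
        grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, n_grid)
    da = gaussian_kde(a, bw_method=bw_method)(grid)
    db = gaussian_kde(b, bw_method=bw_method)(grid)
    return grid, da - db
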