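"""Imputation and covariate screening/adjustment ahead of network fitting.

Missing phenotype entries are filled by chained-equations multiple
imputation (scikit-learn's iterative imputer) with an ensemble regressor
per column, collapsed to one completed table.  Ordinal items are rounded
and clipped back into their level range.  A diagnostics table compares
per-column descriptive statistics before and after imputation.

Covariate handling mirrors the usual two-step recipe: an ANOVA-style
screen flags every (variable, covariate) pair with p below alpha, then
flagged variables are replaced by their least-squares residuals on the
flagged covariates.  Categorical network variables cannot be
residualized; they are skipped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from metabridge.dataset import MixedDataset


@dataclass
class ImputationConfig:
    """``estimator``: "random_forest" (default) or "bayesian_ridge"
    (linear, much faster; useful for large tables and smoke tests)."""

    n_rounds: int = 10
    estimator: str = "random_forest"
    n_estimators: int = 20
    seed: int = 0
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.estimator not in ("random_forest", "bayesian_ridge"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def _descriptives(frame: pd.DataFrame) -> pd.DataFrame:
    stats_ = frame.describe().T[["mean", "std", "25%", "50%", "75%"]]
    stats_.columns = ["mean", "sd", "q25", "q50", "q75"]
    return stats_


def impute(data: MixedDataset, cfg: ImputationConfig | None = None) -> tuple[MixedDataset, pd.DataFrame]:
    """Fill missing entries; returns (completed dataset, diagnostics).

    Observed cells are never altered; ordinal columns are rounded and
    clipped into their declared level range.  Diagnostics list mean, SD
    and quartiles of each column under complete-case vs imputed data.
    """
    cfg = cfg or ImputationConfig()
    frame = data.frame.copy()
    fully_missing = frame.columns[frame.isna().all()].tolist()
    if fully_missing:
        raise ValueError(f"fully missing columns cannot be imputed: {fully_missing}")
    observed = frame.to_numpy(dtype=float)
    if np.any(~np.isfinite(observed) & ~np.isnan(observed)):
        bad = frame.columns[(~np.isfinite(frame) & ~frame.isna()).any()].tolist()
        raise ValueError(f"non-finite observed values in: {bad}")

    before = _descriptives(frame)
    if data.n_missing == 0:
        diag = _diagnostics_table(before, before)
        return data.copy_with(frame), diag

    if cfg.estimator == "random_forest":
        base = RandomForestRegressor(
            n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1
        )
    else:
        base = BayesianRidge()
    imputer = IterativeImputer(
        estimator=base,
        max_iter=cfg.n_rounds,
        tol=cfg.convergence_tol,
        random_state=cfg.seed,
        sample_posterior=False,
        keep_empty_features=False,
    )
    completed = imputer.fit_transform(frame.to_numpy(dtype=float))
    out = pd.DataFrame(completed, columns=frame.columns, index=frame.index)

    # restore observed cells bit-exactly and respect ordinal level ranges
    out = out.where(frame.isna(), frame)
    for var in data.roster.variables:
        if data.roster.type_of(var) in ("ordinal", "categorical"):
            levels = data.roster.levels_of(var)
            filled = out[var].round().clip(0, levels - 1)
            out[var] = filled.where(frame[var].isna(), frame[var])

    diag = _diagnostics_table(before, _descriptives(out))
    return data.copy_with(out), diag


def _diagnostics_table(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var in before.index:
        for stat in before.columns:
            rows.append(
                {
                    "variable": var,
                    "statistic": stat,
                    "complete_value": before.loc[var, stat],
                    "imputed_value": after.loc[var, stat],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- screening


@dataclass
class CovariateScreenResult:
    table: pd.DataFrame  # variable, covariate, statistic, p, flagged
    alpha: float

    def flagged_covariates(self, variable: str) -> list[str]:
        sub = self.table[(self.table["variable"] == variable) & self.table["flagged"]]
        return list(sub["covariate"])

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())


def screen_covariates(
    data: MixedDataset, covariates: list[str] | None = None, alpha: float = 0.05
) -> CovariateScreenResult:
    """F-test each network variable against each covariate.

    Categorical covariates (sex) use a one-way ANOVA across groups;
    continuous covariates (age) use the equivalent single-regressor
    F-test.  A pair is flagged when p < alpha.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    covariates = covariates if covariates is not None else data.variables("covariate")
    for cov in covariates:
        if cov not in data.frame.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        if data.frame[cov].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {cov!r} has a single unique value")

    targets = [v for v in data.roster.variables if v not in covariates]
    rows = []
    for var in targets:
        for cov in covariates:
            sub = data.frame[[var, cov]].dropna()
            y = sub[var].to_numpy(dtype=float)
            c = sub[cov].to_numpy(dtype=float)
            if data.roster.type_of(cov) == "categorical":
                groups = [y[c == level] for level in np.unique(c)]
                stat, p = stats.f_oneway(*groups)
            else:
                # single-regressor F == squared t of the slope
                slope_r, p = stats.pearsonr(y, c)
                dfree = len(y) - 2
                stat = slope_r**2 * dfree / max(1.0 - slope_r**2, 1e-300)
            rows.append(
                {
                    "variable": var,
                    "covariate": cov,
                    "statistic": float(stat),
                    "p": float(p),
                    "flagged": bool(p < alpha),
                }
            )
    return CovariateScreenResult(table=pd.DataFrame(rows), alpha=alpha)


def adjust(
    data: MixedDataset, screen: CovariateScreenResult
) -> tuple[MixedDataset, list[str]]:
    """Residualize each flagged variable on its flagged covariates.

    Categorical covariates are dummy-coded; ordinal variables are
    residualized on their integer coding (their adjusted values are no
    longer integers).  Variables typed categorical are skipped — a
    residual of a nominal variable is undefined — and returned in the
    skip log.  Returns (adjusted dataset, skipped variables).
    """
    frame = data.frame.copy()
    skipped: list[str] = []
    for var in screen.table["variable"].unique():
        covs = screen.flagged_covariates(var)
        if not covs:
            continue
        if data.roster.type_of(var) == "categorical":
            skipped.append(var)
            continue
        cols = [var, *covs]
        sub = frame[cols].dropna()
        design = [np.ones(len(sub))]
        for cov in covs:
            c = sub[cov].to_numpy(dtype=float)
            if data.roster.type_of(cov) == "categorical":
                levels = np.unique(c)
                design.extend((c == lv).astype(float) for lv in levels[1:])
            else:
                design.append(c)
        Z = np.column_stack(design)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError(f"rank-deficient covariate design for {var!r}: {covs}")
        y = sub[var].to_numpy(dtype=float)
        coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        frame.loc[sub.index, var] = y - Z @ coef
    return data.copy_with(frame), skipped
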