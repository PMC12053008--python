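"""Replication regressions under an expanding ladder of covariate sets.

Each metabolite-phenotype association surviving the network stage is
re-tested in a (possibly external) dataset by ordinary least squares,
metabolite ~ phenotype + covariates, once per covariate set in the
ladder.  The default ladder mirrors the usual epidemiological recipe:
nothing, age, sex, age+sex, then adding smoking status and physical
activity.  Binary phenotypes are fit by the same linear contract
(linear probability model).  A pair's robustness score is the number of
covariate sets under which the association stays significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from metabridge.dataset import MixedDataset

DEFAULT_LADDER = (
    (),
    ("age",),
    ("sex",),
    ("age", "sex"),
    ("age", "sex", "smoking"),
    ("age", "sex", "smoking", "physical_activity"),
)


@dataclass
class CovariateLadder:
    sets: tuple[tuple[str, ...], ...] = DEFAULT_LADDER

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class LadderResult:
    table: pd.DataFrame  # dependent, independent, covariates, beta, se, p, n
    alpha: float = 0.05

    def verdict_counts(self) -> pd.DataFrame:
        """Per pair: number of covariate sets with p < alpha."""
        sig = self.table.assign(significant=self.table["p"] < self.alpha)
        return (
            sig.groupby(["dependent", "independent"], sort=True)["significant"]
            .sum()
            .astype(int)
            .reset_index(name="n_significant_sets")
        )


def ols_ladder(
    data: MixedDataset | pd.DataFrame,
    pairs: list[tuple[str, str]],
    ladder: CovariateLadder | None = None,
    alpha: float = 0.05,
) -> LadderResult:
    """Fit dependent ~ independent + covariates for every pair and rung.

    Classical (homoskedastic) standard errors; categorical covariates
    are dummy-coded.  Raises when a covariate set is collinear, naming
    the set.
    """
    ladder = ladder or CovariateLadder()
    frame = data.frame if isinstance(data, MixedDataset) else data
    roster = data.roster if isinstance(data, MixedDataset) else None
    rows = []
    for dependent, independent in pairs:
        for var in (dependent, independent):
            if var not in frame.columns:
                raise ValueError(f"variable {var!r} not in table")
        for covariates in ladder.sets:
            cols = [dependent, independent, *covariates]
            absent = [c for c in covariates if c not in frame.columns]
            if absent:
                raise ValueError(f"covariates {absent} not in table")
            sub = frame[cols].dropna()
            design_cols = [sub[independent].to_numpy(dtype=float)]
            col_names = [independent]
            for cov in covariates:
                c = sub[cov].to_numpy(dtype=float)
                if roster is not None and roster.type_of(cov) == "categorical":
                    for lv in np.unique(c)[1:]:
                        design_cols.append((c == lv).astype(float))
                        col_names.append(f"{cov}={lv:g}")
                else:
                    design_cols.append(c)
                    col_names.append(cov)
            X = sm.add_constant(np.column_stack(design_cols))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"collinear covariate set {covariates} for pair ({dependent}, {independent})")
            fit = sm.OLS(sub[dependent].to_numpy(dtype=float), X).fit()
            rows.append(
                {
                    "dependent": dependent,
                    "independent": independent,
                    "covariates": "+".join(covariates) if covariates else "-",
                    "beta": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p": float(fit.pvalues[1]),
                    "n": int(fit.nobs),
                }
            )
    return LadderResult(table=pd.DataFrame(rows), alpha=alpha)
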