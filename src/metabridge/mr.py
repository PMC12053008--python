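"""Two-sample Mendelian randomization from GWAS summary statistics.

Implements the standard summary-data MR toolchain: genome-wide-significance
instrument selection, allele harmonization between exposure and outcome
files (order swaps, strand flips, palindromic-SNP resolution by allele
frequency), the inverse-variance-weighted (IVW) estimator with
multiplicative random-effects inflation, the weighted-median estimator
with parametric-bootstrap standard errors, MR-Egger regression with its
directional-pleiotropy intercept, Cochran's Q heterogeneity test, and
per-instrument F statistics.

Conventions: Wald-ratio weights are first-order (outcome variance only,
scaled by the squared exposure effect); causal estimates are reported as
log odds ratios / per-unit effects with OR = exp(beta) and 95% CI =
exp(beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GWAS_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


@dataclass
class GwasSummary:
    """Per-SNP association records for one trait.

    Wraps a DataFrame with columns rsid, effect_allele, other_allele,
    eaf, beta, se, pval, n.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(GWAS_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
        alleles = set(self.table["effect_allele"]) | set(self.table["other_allele"])
        bad = alleles - VALID_ALLELES
        if bad:
            raise ValueError(f"non-ACGT allele codes: {sorted(bad)}")
        if (self.table["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.table["rsid"].duplicated().any():
            raise ValueError("duplicate rsids in GWAS table")

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "GwasSummary":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to the exposure effect allele."""

    table: pd.DataFrame  # rsid, beta_x, se_x, beta_y, se_y, eaf
    exclusions: pd.DataFrame  # rsid, reason

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy()

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy()

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy()

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    odds_ratio: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        self.odds_ratio = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - 1.96 * self.se))
        self.ci_high = float(np.exp(self.beta + 1.96 * self.se))

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snps": self.n_snps,
        }
        for key in ("q", "q_df", "q_p", "egger_intercept", "egger_intercept_se", "egger_intercept_p"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


# ------------------------------------------------------------- instruments


def select_instruments(
    exposure: GwasSummary,
    p_threshold: float = 5e-8,
    min_distance: int | None = None,
    position_columns: tuple[str, str] = ("chrom", "pos"),
) -> GwasSummary:
    """Retain genome-wide-significant SNPs, optionally distance-thinned.

    When ``min_distance`` is given and the table carries position columns,
    a greedy pass keeps the most significant SNP per window (a stand-in
    for LD clumping, which needs a reference panel).
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    kept = exposure.table[exposure.table["pval"] < p_threshold].copy()
    if min_distance is not None:
        chrom_col, pos_col = position_columns
        if chrom_col not in kept.columns or pos_col not in kept.columns:
            raise ValueError("distance thinning requires position columns")
        kept = kept.sort_values("pval", kind="mergesort")
        chosen: list[int] = []
        taken: dict[object, list[int]] = {}
        for idx, row in kept.iterrows():
            positions = taken.setdefault(row[chrom_col], [])
            if all(abs(row[pos_col] - p) >= min_distance for p in positions):
                chosen.append(idx)
                positions.append(row[pos_col])
        kept = kept.loc[chosen]
    if kept.empty:
        raise ValueError(f"no instruments pass p < {p_threshold:g}")
    kept = kept.sort_values("rsid", kind="mergesort").reset_index(drop=True)
    return GwasSummary(kept)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele.

    Handles allele order swaps (sign/eaf flip), strand flips (complement
    alleles), and palindromic SNPs, which are kept only when both allele
    frequencies sit clearly on a resolvable side of 0.5 (at least
    ``palindrome_eaf_window`` away).
    """
    out_by_rsid = outcome.table.set_index("rsid")
    rows = []
    exclusions = []
    for _, exp in exposure.table.iterrows():
        rsid = exp["rsid"]
        if rsid not in out_by_rsid.index:
            exclusions.append((rsid, "missing_in_outcome"))
            continue
        out = out_by_rsid.loc[rsid]
        e1, e2 = exp["effect_allele"], exp["other_allele"]
        o1, o2 = out["effect_allele"], out["other_allele"]
        beta_y, eaf_y = float(out["beta"]), float(out["eaf"])

        if _is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                exclusions.append((rsid, "allele_mismatch"))
                continue
            eaf_x = float(exp["eaf"])
            if abs(eaf_x - 0.5) < palindrome_eaf_window or abs(eaf_y - 0.5) < palindrome_eaf_window:
                exclusions.append((rsid, "palindromic_ambiguous"))
                continue
            # strand is unresolvable from alleles; align by frequency side.
            # treat outcome record as if coded on (o1, o2); after an apparent
            # order swap re-express, then check frequency concordance
            if o1 != e1:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            if (o1, o2) == (e1, e2):
                pass
            elif (o1, o2) == (e2, e1):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            elif (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e1, e2):
                pass
            elif (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e2, e1):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            else:
                exclusions.append((rsid, "allele_mismatch"))
                continue

        rows.append(
            {
                "rsid": rsid,
                "effect_allele": e1,
                "other_allele": e2,
                "eaf": float(exp["eaf"]),
                "beta_x": float(exp["beta"]),
                "se_x": float(exp["se"]),
                "beta_y": beta_y,
                "se_y": float(out["se"]),
            }
        )

    table = pd.DataFrame(rows, columns=["rsid", "effect_allele", "other_allele", "eaf", "beta_x", "se_x", "beta_y", "se_y"])
    excl = pd.DataFrame(exclusions, columns=["rsid", "reason"])
    return HarmonizedSet(table=table, exclusions=excl)


# --------------------------------------------------------------- estimators


def _usable(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Drop zero-exposure-effect SNPs (undefined Wald ratio)."""
    keep = h.beta_x != 0.0
    return h.beta_x[keep], h.se_x[keep], h.beta_y[keep], h.se_y[keep]


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-SNP causal estimate with first-order standard error."""
    if beta_x == 0:
        raise ValueError("Wald ratio undefined for zero exposure effect")
    return beta_y / beta_x, se_y / abs(beta_x)


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate over per-SNP Wald ratios.

    First-order weights w_i = beta_x_i^2 / se_y_i^2.  The standard error
    is inflated multiplicatively by sqrt(Q/df) when Cochran's Q exceeds
    its degrees of freedom (multiplicative random-effects model).
    """
    bx, sx, by, sy = _usable(h)
    k = len(bx)
    if k < 2:
        raise ValueError(f"IVW needs >= 2 usable SNPs, got {k}")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))
    q = float(np.sum(weights * (ratios - beta) ** 2))
    df = k - 1
    if q / df > 1.0:
        se *= np.sqrt(q / df)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="IVW", beta=beta, se=se, p=p, n_snps=k,
        q=q, q_df=df, q_p=float(stats.chi2.sf(q, df)),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # weighted percentile of each ratio
    below = np.flatnonzero(cum < 0.5)
    if below.size == 0:
        return float(r[0])
    j = below[-1]
    if j == len(r) - 1:
        return float(r[-1])
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j]))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator; consistent while <50% of the weight
    comes from invalid instruments.  SE by parametric bootstrap of the
    per-SNP effects."""
    bx, sx, by, sy = _usable(h)
    k = len(bx)
    if k < 3:
        raise ValueError(f"weighted median needs >= 3 usable SNPs, got {k}")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(k)
        by_b = by + sy * rng.standard_normal(k)
        ok = bx_b != 0
        boot[b] = _weighted_median(by_b[ok] / bx_b[ok], bx_b[ok] ** 2 / sy[ok] ** 2)
    se = float(boot.std(ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MREstimate(method="weighted_median", beta=beta, se=se, p=p, n_snps=k)


def mr_egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept estimating directional pleiotropy.

    All exposure effects are oriented positive first (the estimator is
    invariant to allele recoding only after this orientation).  Standard
    errors are inflated by max(1, sqrt(Q_egger/df)).
    """
    import statsmodels.api as sm

    bx, sx, by, sy = _usable(h)
    k = len(bx)
    if k < 3:
        raise ValueError(f"MR-Egger needs >= 3 usable SNPs, got {k}")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("MR-Egger slope unidentified: no spread in exposure effects")
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    resid = by - fit.predict(X)
    q = float(np.sum(w * resid**2))
    df = k - 2
    inflate = max(1.0, np.sqrt(q / df))
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    slope_se = float(fit.bse[1]) * inflate
    int_se = float(fit.bse[0]) * inflate
    return MREstimate(
        method="MR_Egger",
        beta=slope,
        se=slope_se,
        p=float(2.0 * stats.t.sf(abs(slope / slope_se), df)),
        n_snps=k,
        q=q,
        q_df=df,
        q_p=float(stats.chi2.sf(q, df)),
        egger_intercept=intercept,
        egger_intercept_se=int_se,
        egger_intercept_p=float(2.0 * stats.t.sf(abs(intercept / int_se), df)),
    )


def cochran_q(h: HarmonizedSet, estimate: MREstimate) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratios around a pooled estimate.

    df = k-1 against an IVW-style pooled value, k-2 for Egger (one extra
    parameter).
    """
    bx, sx, by, sy = _usable(h)
    k = len(bx)
    df = k - 2 if estimate.method == "MR_Egger" else k - 1
    if df <= 0:
        raise ValueError("Cochran's Q undefined: df <= 0")
    w = bx**2 / sy**2
    if estimate.method == "MR_Egger":
        flip = np.sign(bx)
        resid = by * flip - (estimate.egger_intercept + estimate.beta * bx * flip)
        q = float(np.sum((resid / sy) ** 2))
    else:
        ratios = by / bx
        q = float(np.sum(w * (ratios - estimate.beta) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def instrument_strength(exposure: GwasSummary) -> pd.DataFrame:
    """Per-SNP F statistic (squared z-score) plus a weak-instrument flag.

    The conventional adequacy bound is F > 10 for every instrument.
    """
    f = (exposure.table["beta"] / exposure.table["se"]) ** 2
    out = pd.DataFrame({"rsid": exposure.table["rsid"], "F": f})
    out.attrs["mean_F"] = float(f.mean())
    out.attrs["min_F"] = float(f.min())
    out.attrs["weak_instruments"] = bool(f.min() <= 10.0)
    return out


# ----------------------------------------------------------------- driver


def run_direction(
    exposure: GwasSummary,
    outcome: GwasSummary,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: float = 0.08,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Selection -> harmonization -> IVW / weighted median / Egger -> diagnostics."""
    instruments = select_instruments(exposure, p_threshold=p_threshold)
    strength = instrument_strength(instruments)
    h = harmonize(instruments, outcome, palindrome_eaf_window=palindrome_eaf_window)
    report: dict = {
        "n_instruments": len(instruments),
        "n_harmonized": len(h),
        "exclusions": h.exclusions.to_dict(orient="records"),
        "mean_F": strength.attrs["mean_F"],
        "min_F": strength.attrs["min_F"],
        "weak_instruments": strength.attrs["weak_instruments"],
        "estimates": {},
    }
    report["estimates"]["IVW"] = ivw(h).to_dict()
    if len(h) >= 3:
        report["estimates"]["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed).to_dict()
        report["estimates"]["MR_Egger"] = mr_egger(h).to_dict()
    return report


def run_bidirectional(
    trait_a: GwasSummary,
    trait_b: GwasSummary,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: float = 0.08,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Forward (A->B) and reverse (B->A) MR, each with its own instruments."""
    if trait_a.table[["rsid", "beta", "se"]].equals(trait_b.table[["rsid", "beta", "se"]]):
        raise ValueError("exposure and outcome files are identical; self-MR rejected")
    kwargs = dict(
        p_threshold=p_threshold,
        palindrome_eaf_window=palindrome_eaf_window,
        n_boot=n_boot,
    )
    return {
        "forward": run_direction(trait_a, trait_b, seed=seed, **kwargs),
        "reverse": run_direction(trait_b, trait_a, seed=seed + 1, **kwargs),
    }
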