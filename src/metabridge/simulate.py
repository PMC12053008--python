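"""Synthetic cohorts and GWAS summary statistics with known ground truth.

The cohort generator emulates the structure of a population cohort with
NMR metabolomics and symptom questionnaires: ~1,600 subjects; 21 ordinal
depression-symptom items scored 0-3 with strong right skew; 52
approximately Gaussian metabolite concentrations; 3 continuous
cardiovascular risk factors; sex/age covariate effects; ~21% missingness
on symptom items versus <1% on risk factors.  The conditional-dependence
structure is specified directly as a set of target partial correlations,
assembled into a precision matrix, so the generating graph is known
exactly and can include planted bridge metabolites (a metabolite tied to
both a risk factor and a symptom).

Ordinal items are produced by Gaussian-copula thresholding: each symptom
has a latent Gaussian living in the graphical model, cut at empirical
quantiles so the realized category frequencies match the requested skew.

The GWAS generator produces paired exposure/outcome summary-statistic
tables with a known causal effect, an optional invalid (pleiotropic)
instrument fraction, and deliberate allele-coding mischief (order swaps,
strand flips, palindromic SNPs) to exercise harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metabridge.dataset import MixedDataset, Roster
from metabridge.mr import GwasSummary

# Default symptom-item category probabilities (scores 0..3).  Questionnaire
# items of this kind put most mass at 0 in population samples.
DEFAULT_SYMPTOM_SKEW = (0.60, 0.25, 0.10, 0.05)

DEFAULT_MISSING_RATES = {
    "symptom": 0.21,
    "metabolite": 0.0,
    "risk_factor": 0.005,
    "covariate": 0.0,
}


@dataclass
class PlantedBridge:
    """A metabolite tied to one risk factor and one symptom.

    ``rf_strength`` / ``symptom_strength`` are target partial correlations
    of the two bridge edges on the latent scale.
    """

    risk_factor: str
    metabolite: str
    symptom: str
    rf_strength: float = 0.3
    symptom_strength: float = 0.3

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (self.metabolite, self.risk_factor, self.rf_strength),
            (self.metabolite, self.symptom, self.symptom_strength),
        ]


@dataclass
class CohortSpec:
    """Ground-truth description of a synthetic mixed-type cohort.

    ``graph`` lists (node_i, node_j, target partial correlation) on the
    latent Gaussian scale; ``planted_bridges`` are merged into it.
    ``covariate_effects`` maps a variable name to (sex_effect, age_effect)
    added on the latent scale before discretization (age effect is per SD
    of age).
    """

    n_subjects: int = 1599
    n_symptoms: int = 21
    n_metabolites: int = 52
    n_riskfactors: int = 3
    symptom_levels: int = 4
    symptom_skew: tuple[float, ...] = DEFAULT_SYMPTOM_SKEW
    graph: list[tuple[str, str, float]] = field(default_factory=list)
    planted_bridges: list[PlantedBridge] = field(default_factory=list)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    lifestyle_covariates: bool = True  # inert smoking / physical-activity columns for ladder runs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.symptom_levels < 2:
            raise ValueError("symptom_levels must be >= 2")
        if len(self.symptom_skew) != self.symptom_levels:
            raise ValueError("symptom_skew length must equal symptom_levels")
        if not np.isclose(sum(self.symptom_skew), 1.0):
            raise ValueError("symptom_skew must sum to 1")
        for role, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {role!r} must be in [0, 1)")

    # ------------------------------------------------------------- naming

    @property
    def symptom_names(self) -> list[str]:
        return [f"symptom_{i + 1}" for i in range(self.n_symptoms)]

    @property
    def metabolite_names(self) -> list[str]:
        return [f"metabolite_{i + 1}" for i in range(self.n_metabolites)]

    @property
    def riskfactor_names(self) -> list[str]:
        return [f"riskfactor_{i + 1}" for i in range(self.n_riskfactors)]

    @property
    def node_names(self) -> list[str]:
        return self.symptom_names + self.metabolite_names + self.riskfactor_names

    def all_edges(self) -> list[tuple[str, str, float]]:
        edges = list(self.graph)
        seen = {frozenset((a, b)) for a, b, _ in edges}
        for bridge in self.planted_bridges:
            for a, b, r in bridge.edges():
                if frozenset((a, b)) not in seen:
                    edges.append((a, b, r))
                    seen.add(frozenset((a, b)))
        return edges

    def roster(self) -> Roster:
        records = (
            [(s, "symptom", "ordinal", self.symptom_levels) for s in self.symptom_names]
            + [(m, "metabolite", "gaussian", 0) for m in self.metabolite_names]
            + [(r, "risk_factor", "gaussian", 0) for r in self.riskfactor_names]
            + [("sex", "covariate", "categorical", 2), ("age", "covariate", "gaussian", 0)]
        )
        if self.lifestyle_covariates:
            records += [
                ("smoking", "covariate", "categorical", 2),
                ("physical_activity", "covariate", "gaussian", 0),
            ]
        return Roster.from_records(records)


def _assemble_precision(spec: CohortSpec) -> np.ndarray:
    """Unit-diagonal precision matrix with off-diagonals -rho per edge.

    With a unit diagonal the partial correlation of an edge equals its
    target rho exactly, and partial correlations are invariant under the
    subsequent rescaling of the covariance to unit variances.
    """
    names = spec.node_names
    index = {name: i for i, name in enumerate(names)}
    p = len(names)
    omega = np.eye(p)
    for a, b, rho in spec.all_edges():
        if a not in index or b not in index:
            raise ValueError(f"graph edge ({a}, {b}) references unknown node")
        if a == b:
            raise ValueError(f"self-edge on {a}")
        i, j = index[a], index[b]
        omega[i, j] = omega[j, i] = -rho
    # PD check; on failure name the edges most likely responsible
    eigmin = np.linalg.eigvalsh(omega)[0]
    if eigmin <= 1e-10:
        offdiag_mass = np.abs(omega).sum(axis=1) - 1.0
        heavy = {names[i] for i in np.flatnonzero(offdiag_mass >= 1.0)}
        offending = [
            (a, b, rho) for a, b, rho in spec.all_edges() if a in heavy or b in heavy
        ] or spec.all_edges()
        raise ValueError(
            "assembled precision matrix is not positive-definite "
            f"(min eigenvalue {eigmin:.3g}); offending edges: {offending}"
        )
    return omega


def _latent_covariance(omega: np.ndarray) -> np.ndarray:
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def generate_cohort(spec: CohortSpec) -> tuple[MixedDataset, pd.DataFrame]:
    """Draw a cohort from the graphical model implied by ``spec``.

    Returns the dataset and the ground-truth edge list
    (columns node_i, node_j, partial_r).
    """
    omega = _assemble_precision(spec)
    sigma = _latent_covariance(omega)
    names = spec.node_names
    n = spec.n_subjects

    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    rng_latent = np.random.default_rng(seeds[0])
    rng_cov = np.random.default_rng(seeds[1])
    rng_miss = np.random.default_rng(seeds[2])

    chol = np.linalg.cholesky(sigma)
    latent = rng_latent.standard_normal((n, len(names))) @ chol.T

    # covariates: sex (0 male / 1 female) and age in years
    sex = (rng_cov.random(n) < 0.54).astype(float)
    age = rng_cov.normal(37.8, 5.0, size=n)
    age_std = (age - age.mean()) / age.std()

    for var, (beta_sex, beta_age) in spec.covariate_effects.items():
        if var not in names:
            raise ValueError(f"covariate effect on unknown variable {var!r}")
        j = names.index(var)
        latent[:, j] = latent[:, j] + beta_sex * (sex - sex.mean()) + beta_age * age_std

    frame = pd.DataFrame(latent, columns=names)

    # ordinal symptoms: cut each latent at its empirical quantiles so the
    # realized category frequencies match the requested skew exactly
    cum = np.cumsum(spec.symptom_skew)[:-1]
    for s in spec.symptom_names:
        cuts = np.quantile(frame[s].to_numpy(), cum)
        frame[s] = np.searchsorted(cuts, frame[s].to_numpy(), side="left").astype(float)

    frame["sex"] = sex
    frame["age"] = age
    if spec.lifestyle_covariates:
        # marginals loosely matching a middle-aged European cohort: ~19%
        # smokers, right-skewed weekly activity score; no effect on nodes
        frame["smoking"] = (rng_cov.random(n) < 0.19).astype(float)
        frame["physical_activity"] = np.clip(rng_cov.normal(19.2, 21.45, size=n), 0.0, None)

    roster = spec.roster()
    for var in roster.variables:
        rate = spec.missing_rates.get(roster.role_of(var), 0.0)
        if rate > 0:
            mask = rng_miss.random(n) < rate
            frame.loc[mask, var] = np.nan

    truth = pd.DataFrame(spec.all_edges(), columns=["node_i", "node_j", "partial_r"])
    return MixedDataset(frame=frame, roster=roster), truth


# --------------------------------------------------------------------- GWAS

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GwasPairSpec:
    """Ground truth for a paired exposure/outcome GWAS simulation.

    ``true_beta`` is the causal effect of the exposure on the outcome.
    Invalid instruments receive a direct (pleiotropic) effect on the
    outcome drawn as N(pleiotropy_mean, pleiotropy_sd).  Per-SNP true
    exposure effects are positive (effect allele = trait-increasing
    allele) and uniform on ``beta_range``; standard errors follow the
    usual 1/sqrt(2 * maf * (1-maf) * n) form for a unit-variance trait.
    """

    n_snps: int = 50
    true_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    invalid_fraction: float = 0.0
    n_exposure: int = 200_000
    n_outcome: int = 200_000
    maf_range: tuple[float, float] = (0.1, 0.4)
    beta_range: tuple[float, float] = (0.05, 0.15)
    swap_fraction: float = 0.2
    flip_fraction: float = 0.2
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError("invalid_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


def generate_gwas_pair(spec: GwasPairSpec) -> tuple[GwasSummary, GwasSummary]:
    """Simulate exposure and outcome summary statistics for one SNP set."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    k = spec.n_snps

    maf = rng.uniform(*spec.maf_range, size=k)
    beta_true = rng.uniform(*spec.beta_range, size=k)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * spec.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * spec.n_outcome)

    n_invalid = int(round(spec.invalid_fraction * k))
    alpha = np.zeros(k)
    if n_invalid:
        invalid = rng.choice(k, size=n_invalid, replace=False)
        alpha[invalid] = rng.normal(spec.pleiotropy_mean, spec.pleiotropy_sd, size=n_invalid)

    beta_x = beta_true + rng.normal(0.0, se_x)
    beta_y = spec.true_beta * beta_true + alpha + rng.normal(0.0, se_y)

    n_palin = int(round(spec.palindromic_fraction * k))
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    alleles = np.array([_NONPALINDROMIC_PAIRS[i] for i in pair_idx], dtype=object)
    if n_palin:
        which = rng.choice(k, size=n_palin, replace=False)
        for i in which:
            alleles[i] = _PALINDROMIC_PAIRS[rng.integers(0, 2)]

    rsids = [f"rs{i + 1:06d}" for i in range(k)]

    def table(beta: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
        z = beta / se
        return pd.DataFrame(
            {
                "rsid": rsids,
                "effect_allele": [a for a, _ in alleles],
                "other_allele": [b for _, b in alleles],
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pval": 2.0 * stats.norm.sf(np.abs(z)),
                "n": n,
            }
        )

    exposure = table(beta_x, se_x, spec.n_exposure)
    outcome = table(beta_y, se_y, spec.n_outcome)

    # allele-coding mischief in the outcome file: order swaps (beta and eaf
    # re-expressed for the other allele) and strand flips (complements,
    # numerics unchanged); palindromic SNPs are never strand-flipped here
    # since their flip is indistinguishable from a no-op
    swap = rng.random(k) < spec.swap_fraction
    flip = rng.random(k) < spec.flip_fraction
    palin = np.array([a == _COMPLEMENT[b] for a, b in alleles])
    ea = outcome["effect_allele"].to_numpy(dtype=object).copy()
    oa = outcome["other_allele"].to_numpy(dtype=object).copy()
    beta_col = outcome["beta"].to_numpy().copy()
    eaf_col = outcome["eaf"].to_numpy().copy()
    for i in range(k):
        if swap[i]:
            ea[i], oa[i] = oa[i], ea[i]
            beta_col[i] = -beta_col[i]
            eaf_col[i] = 1.0 - eaf_col[i]
        if flip[i] and not palin[i]:
            ea[i] = _COMPLEMENT[ea[i]]
            oa[i] = _COMPLEMENT[oa[i]]
    outcome["effect_allele"] = ea
    outcome["other_allele"] = oa
    outcome["beta"] = beta_col
    outcome["eaf"] = eaf_col

    return GwasSummary(exposure), GwasSummary(outcome)
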