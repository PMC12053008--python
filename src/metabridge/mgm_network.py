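"""Pairwise mixed graphical model via nodewise L1-penalized regression.

Each node is regressed on all others: linear lasso for Gaussian nodes,
L1 multinomial logistic for categorical ones.  The per-node penalty is
chosen on a log-spaced path by the extended BIC, scored on an OLS refit
of each candidate support (default gamma = 0.5), with ties broken toward
the sparser model.  An edge exists when the
cross-parameters are nonzero in both nodewise fits (AND rule, default)
or in either (OR rule); its weight is the mean absolute cross-parameter
across the two fits, and a sign is attached only when both endpoints are
continuous and the two coefficient signs agree.

Ordinal symptom items are modeled as Gaussian nodes by default
(integer-coded, standardized); ``ordinal_as="categorical"`` switches
them to multinomial treatment, which leaves their edge signs undefined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, lasso_path

from metabridge.dataset import MixedDataset, check_complete

NETWORK_ROLES = ("symptom", "metabolite", "risk_factor")


@dataclass
class NetworkModel:
    """Signed weighted undirected network over typed nodes.

    ``adjacency`` holds signed weights (0 = no edge); the sign is only
    meaningful where ``signs`` is +/-1 — entries with sign 0 involve a
    categorical node or disagreeing nodewise coefficients and their
    weight is reported unsigned.
    """

    nodes: pd.DataFrame  # name, role, type
    adjacency: np.ndarray
    signs: np.ndarray
    lambdas: dict[str, float]
    combine_rule: str
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.nodes)
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency shape does not match node roster")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def node_names(self) -> list[str]:
        return list(self.nodes["name"])

    def index_of(self, name: str) -> int:
        return self.node_names.index(name)

    def role_of(self, name: str) -> str:
        return self.nodes.set_index("name").loc[name, "role"]

    def nodes_by_role(self, role: str) -> list[str]:
        return list(self.nodes.loc[self.nodes["role"] == role, "name"])

    def weight(self, a: str, b: str) -> float:
        return float(self.adjacency[self.index_of(a), self.index_of(b)])

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(len(self.nodes), k=1)
        return int(np.count_nonzero(self.adjacency[iu]))

    def edges(self) -> pd.DataFrame:
        names = self.node_names
        rows = []
        for i, j in zip(*np.triu_indices(len(names), k=1)):
            w = self.adjacency[i, j]
            if w != 0:
                rows.append((names[i], names[j], float(w), int(self.signs[i, j])))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign"])

    @classmethod
    def from_edges(
        cls,
        nodes: list[tuple[str, str]] | pd.DataFrame,
        edges: list[tuple[str, str, float]],
        combine_rule: str = "AND",
    ) -> "NetworkModel":
        """Build a network directly from (name, role) nodes and weighted
        edges — for toy graphs, worked examples and external imports."""
        if not isinstance(nodes, pd.DataFrame):
            nodes = pd.DataFrame(
                {"name": [n for n, _ in nodes], "role": [r for _, r in nodes],
                 "type": ["gaussian"] * len(nodes)}
            )
        p = len(nodes)
        idx = {n: i for i, n in enumerate(nodes["name"])}
        adjacency = np.zeros((p, p))
        signs = np.zeros((p, p), dtype=int)
        for a, b, w in edges:
            i, j = idx[a], idx[b]
            adjacency[i, j] = adjacency[j, i] = w
            signs[i, j] = signs[j, i] = int(np.sign(w))
        return cls(nodes=nodes, adjacency=adjacency, signs=signs,
                   lambdas={}, combine_rule=combine_rule)

    # ------------------------------------------------------------------ I/O

    def write(self, edges_path: str | Path, meta_path: str | Path) -> None:
        self.edges().to_csv(edges_path, sep="\t", index=False)
        meta = {
            "nodes": self.nodes.to_dict(orient="records"),
            "lambdas": self.lambdas,
            "combine_rule": self.combine_rule,
            "selection": self.selection,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def read(cls, edges_path: str | Path, meta_path: str | Path) -> "NetworkModel":
        meta = json.loads(Path(meta_path).read_text())
        nodes = pd.DataFrame(meta["nodes"])
        p = len(nodes)
        idx = {n: i for i, n in enumerate(nodes["name"])}
        adjacency = np.zeros((p, p))
        signs = np.zeros((p, p), dtype=int)
        edges = pd.read_csv(edges_path, sep="\t")
        for _, row in edges.iterrows():
            i, j = idx[row["node_i"]], idx[row["node_j"]]
            adjacency[i, j] = adjacency[j, i] = row["weight"]
            signs[i, j] = signs[j, i] = row["sign"]
        return cls(
            nodes=nodes,
            adjacency=adjacency,
            signs=signs,
            lambdas=meta["lambdas"],
            combine_rule=meta["combine_rule"],
            selection=meta["selection"],
        )


# ------------------------------------------------------------------ fitting


def _node_types(data: MixedDataset, names: list[str], ordinal_as: str) -> dict[str, str]:
    types = {}
    for name in names:
        t = data.roster.type_of(name)
        if t == "ordinal":
            t = "gaussian" if ordinal_as == "gaussian" else "categorical"
        types[name] = t
    return types


def _design_blocks(
    frame: pd.DataFrame, names: list[str], types: dict[str, str]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Standardized predictor block and raw response per node.

    Categorical nodes become one-hot blocks over observed levels (all
    levels kept; the lasso handles the overparameterization).
    """
    blocks: dict[str, np.ndarray] = {}
    responses: dict[str, np.ndarray] = {}
    for name in names:
        col = frame[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            raise ValueError(f"constant column {name!r}; cannot enter the network")
        if types[name] == "gaussian":
            blocks[name] = ((col - col.mean()) / col.std())[:, None]
            responses[name] = blocks[name][:, 0]
        else:
            levels = np.unique(col)
            if len(levels) < 2:
                raise ValueError(f"categorical node {name!r} has a single observed level")
            onehot = (col[:, None] == levels[None, :]).astype(float)
            occupancy = onehot.sum(axis=0)
            if np.any(occupancy == 0):
                raise ValueError(f"categorical node {name!r} has empty levels")
            std = onehot.std(axis=0)
            blocks[name] = (onehot - onehot.mean(axis=0)) / std
            responses[name] = col
    return blocks, responses


def _ebic_gaussian(rss: np.ndarray, df: np.ndarray, n: int, n_params: int, gamma: float) -> np.ndarray:
    rss = np.maximum(rss, 1e-12)
    return n * np.log(rss / n) + df * np.log(n) + 2.0 * gamma * df * np.log(max(n_params, 1))

def _lambda_grid(lambda_max: float, n_lambda: int, ratio: float = 1e-3) -> np.ndarray:
    lambda_max = max(lambda_max, 1e-8)
    return np.geomspace(lambda_max, lambda_max * ratio, n_lambda)


def _fit_gaussian_node(
    y: np.ndarray, X: np.ndarray, n_lambda: int, gamma: float,
    lambda_value: float | None, lambda_scale: float,
) -> tuple[np.ndarray, float]:
    n = len(y)
    if lambda_value is not None:
        grid = np.array([max(lambda_value * lambda_scale, 1e-10)])
    else:
        lam_max = np.max(np.abs(X.T @ y)) / n
        grid = _lambda_grid(lam_max * 1.05, n_lambda) * lambda_scale
    _, coefs, _ = lasso_path(X, y, alphas=grid)
    if lambda_value is not None:
        return coefs[:, 0], float(grid[0])
    # EBIC on the OLS refit of each support along the path ("relaxed"
    # scoring): the penalized RSS rewards small lambda merely for undoing
    # shrinkage on strong edges, which drags noise edges in with them
    best: tuple[np.ndarray, float] | None = None
    best_ebic, best_df = np.inf, -1
    seen: set[bytes] = set()
    for k in range(coefs.shape[1]):
        support = coefs[:, k] != 0
        key = support.tobytes()
        if key in seen:
            continue
        seen.add(key)
        df = int(support.sum())
        refit = np.zeros(X.shape[1])
        if df == 0:
            rss = float(y @ y)
        else:
            beta, _, _, _ = np.linalg.lstsq(X[:, support], y, rcond=None)
            r = y - X[:, support] @ beta
            rss = float(r @ r)
            refit[support] = beta
        ebic = float(_ebic_gaussian(np.array([rss]), np.array([df]), n, X.shape[1], gamma)[0])
        # ties toward the sparser support, then the larger lambda
        if ebic < best_ebic - 1e-9 or (abs(ebic - best_ebic) <= 1e-9 and df < best_df):
            best, best_ebic, best_df = (refit, float(grid[k])), ebic, df
    # the chosen support's coefficients are the OLS refit (relaxed lasso):
    # at the support's entry lambda the penalized values are near zero and
    # would misstate edge strength downstream
    return best


def _fit_categorical_node(
    y: np.ndarray, X: np.ndarray, n_lambda: int, gamma: float,
    lambda_value: float | None, lambda_scale: float,
) -> tuple[np.ndarray, float]:
    """L1 multinomial fit over a lambda path, EBIC-selected.

    Returns the coefficient matrix (classes x predictors) and lambda.
    """
    n = len(y)
    classes = np.unique(y)
    onehot = (y[:, None] == classes[None, :]).astype(float)
    if lambda_value is not None:
        grid = np.array([max(lambda_value * lambda_scale, 1e-10)])
    else:
        resid = onehot - onehot.mean(axis=0)
        lam_max = np.max(np.abs(X.T @ resid)) / n
        grid = _lambda_grid(lam_max * 1.05, max(n_lambda // 2, 5)) * lambda_scale

    best_coef, best_lambda, best_ebic = None, None, np.inf
    for lam in grid:
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="saga", max_iter=3000,
            tol=1e-6, random_state=0,
        )
        model.fit(X, y)
        proba = np.clip(model.predict_proba(X), 1e-12, 1.0)
        ll = float(np.sum(onehot * np.log(proba)))
        dfree = int(np.count_nonzero(model.coef_))
        ebic = -2.0 * ll + dfree * np.log(n) + 2.0 * gamma * dfree * np.log(max(X.shape[1], 1))
        if ebic < best_ebic - 1e-9:
            best_coef, best_lambda, best_ebic = model.coef_.copy(), float(lam), ebic
    return best_coef, best_lambda


def fit_mgm(
    data: MixedDataset,
    selection: str = "ebic",
    combine_rule: str = "AND",
    gamma: float = 0.5,
    n_lambda: int = 50,
    lambda_value: float | None = None,
    lambda_scale: float = 1.0,
    ordinal_as: str = "gaussian",
    include_roles: tuple[str, ...] = NETWORK_ROLES,
) -> NetworkModel:
    """Estimate the mixed graphical model over all non-covariate nodes.

    ``selection="ebic"`` picks each node's lambda on a log-spaced path;
    ``selection="fixed"`` uses ``lambda_value`` (times ``lambda_scale``)
    for every node, which is how near-unpenalized (lambda -> 0) fits and
    penalty-monotonicity checks are run.
    """
    check_complete(data, "fit_mgm")
    if combine_rule not in ("AND", "OR"):
        raise ValueError("combine_rule must be AND or OR")
    if selection == "fixed" and lambda_value is None:
        raise ValueError("selection='fixed' requires lambda_value")
    names = [v for v in data.roster.variables if data.roster.role_of(v) in include_roles]
    if len(names) < 2:
        raise ValueError("need at least 2 network nodes")
    n = data.n_subjects
    if n <= 10:
        raise ValueError("need more than 10 subjects")

    types = _node_types(data, names, ordinal_as)
    blocks, responses = _design_blocks(data.frame, names, types)

    # per-node fits
    lam_fixed = lambda_value if selection == "fixed" else None
    cross: dict[str, dict[str, np.ndarray]] = {}
    lambdas: dict[str, float] = {}
    for name in names:
        others = [m for m in names if m != name]
        X = np.hstack([blocks[m] for m in others])
        col_of = {}
        start = 0
        for m in others:
            width = blocks[m].shape[1]
            col_of[m] = slice(start, start + width)
            start += width
        if types[name] == "gaussian":
            coef, lam = _fit_gaussian_node(
                responses[name], X, n_lambda, gamma, lam_fixed, lambda_scale
            )
            cross[name] = {m: np.atleast_1d(coef[col_of[m]]) for m in others}
        else:
            coef, lam = _fit_categorical_node(
                responses[name], X, n_lambda, gamma, lam_fixed, lambda_scale
            )
            cross[name] = {m: coef[:, col_of[m]].ravel() for m in others}
        lambdas[name] = lam

    # combine nodewise fits into edges
    p = len(names)
    adjacency = np.zeros((p, p))
    sign_mat = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            block_ab = cross[a][b]
            block_ba = cross[b][a]
            nz_ab = bool(np.any(block_ab != 0))
            nz_ba = bool(np.any(block_ba != 0))
            present = (nz_ab and nz_ba) if combine_rule == "AND" else (nz_ab or nz_ba)
            if not present:
                continue
            weight = 0.5 * (np.mean(np.abs(block_ab)) + np.mean(np.abs(block_ba)))
            sign = 0
            if types[a] == "gaussian" and types[b] == "gaussian":
                s_ab = np.sign(block_ab[0])
                s_ba = np.sign(block_ba[0])
                if s_ab != 0 and s_ab == s_ba:
                    sign = int(s_ab)
                elif s_ab != 0 and s_ba == 0:
                    sign = int(s_ab) if combine_rule == "OR" else 0
                elif s_ba != 0 and s_ab == 0:
                    sign = int(s_ba) if combine_rule == "OR" else 0
            adjacency[i, j] = adjacency[j, i] = weight * (sign if sign != 0 else 1)
            sign_mat[i, j] = sign_mat[j, i] = sign

    nodes = pd.DataFrame(
        {"name": names, "role": [data.roster.role_of(v) for v in names],
         "type": [types[v] for v in names]}
    )
    return NetworkModel(
        nodes=nodes,
        adjacency=adjacency,
        signs=sign_mat,
        lambdas=lambdas,
        combine_rule=combine_rule,
        selection={
            "rule": selection,
            "gamma": gamma,
            "n_lambda": n_lambda,
            "lambda_value": lambda_value,
            "lambda_scale": lambda_scale,
            "ordinal_as": ordinal_as,
        },
    )


# ------------------------------------------------------- partial correlation


@dataclass(frozen=True)
class PartialCorrelationRecord:
    pair: tuple[str, str]
    conditioning: tuple[str, ...]
    r: float
    n_effective: int


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise ValueError("conditioning design is rank-deficient")
    return y - Z @ coef


def partial_correlation(
    data: MixedDataset, pair: tuple[str, str], conditioning: list[str] | None = None
) -> PartialCorrelationRecord:
    """Pearson correlation of OLS residuals after projecting out the
    conditioning variables (plus intercept)."""
    a, b = pair
    conditioning = list(conditioning or [])
    if a == b:
        raise ValueError("pair members must differ")
    overlap = set(pair) & set(conditioning)
    if overlap:
        raise ValueError(f"pair and conditioning overlap: {sorted(overlap)}")
    cols = [a, b, *conditioning]
    sub = data.frame[cols].dropna()
    n = len(sub)
    Z = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in conditioning])
    ra = _residualize(sub[a].to_numpy(dtype=float), Z)
    rb = _residualize(sub[b].to_numpy(dtype=float), Z)
    r = float(stats.pearsonr(ra, rb)[0])
    return PartialCorrelationRecord(pair=(a, b), conditioning=tuple(conditioning), r=r, n_effective=n)
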