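"""Edge stability by nonparametric bootstrap and significance by permutation.

Bootstrap: subjects are resampled with replacement B times and the mixed
graphical model refit with identical settings; every edge of the original
fit gets a mean weight, a 2.5/97.5-percentile interval, a min-max
interval, and the fraction of resamples in which it was present.  Edges
appearing only in resamples are reported too, flagged as non-original.

Permutation: the null for a pair's partial correlation is built
Freedman-Lane style — both members are residualized on the conditioning
set, then the residuals of one member (the metabolite, by convention)
are permuted, preserving the conditioning structure while breaking the
pair association.  The two-sided p-value carries the add-one correction
p = (1 + #{|r_perm| >= |r_obs|}) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from metabridge.dataset import MixedDataset, check_complete
from metabridge.mgm_network import fit_mgm


@dataclass
class EdgeStabilityRecord:
    edge: tuple[str, str]
    mean_weight: float
    ci_low: float
    ci_high: float
    w_min: float
    w_max: float
    presence_fraction: float
    n_boot: int
    in_original: bool


def bootstrap_edges(
    data: MixedDataset,
    fit_config: dict | None = None,
    B: int = 100,
    seed: int = 0,
    retry_cap: int = 10,
) -> list[EdgeStabilityRecord]:
    """Refit the network on B bootstrap resamples of subjects.

    Resamples producing a constant column are redrawn (up to
    ``retry_cap`` consecutive retries) since no node fit is defined there.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    check_complete(data, "bootstrap_edges")
    fit_config = dict(fit_config or {})
    original = fit_mgm(data, **fit_config)
    names = original.node_names
    index = {n: i for i, n in enumerate(names)}
    n = data.n_subjects

    rng = np.random.default_rng(seed)
    weights = np.zeros((B, len(names), len(names)))
    b = 0
    retries = 0
    while b < B:
        rows = rng.integers(0, n, size=n)
        resample = data.copy_with(data.frame.iloc[rows].reset_index(drop=True))
        try:
            refit = fit_mgm(resample, **fit_config)
        except ValueError:
            retries += 1
            if retries > retry_cap:
                raise ValueError(
                    f"exceeded {retry_cap} consecutive degenerate bootstrap resamples"
                )
            continue
        retries = 0
        weights[b] = refit.adjacency
        b += 1

    iu = np.triu_indices(len(names), k=1)
    orig_present = original.adjacency[iu] != 0
    ever_present = np.any(weights[:, iu[0], iu[1]] != 0, axis=0)
    records = []
    for k in range(len(iu[0])):
        if not (orig_present[k] or ever_present[k]):
            continue
        i, j = iu[0][k], iu[1][k]
        w = weights[:, i, j]
        records.append(
            EdgeStabilityRecord(
                edge=(names[i], names[j]),
                mean_weight=float(w.mean()),
                ci_low=float(np.percentile(w, 2.5)),
                ci_high=float(np.percentile(w, 97.5)),
                w_min=float(w.min()),
                w_max=float(w.max()),
                presence_fraction=float(np.mean(w != 0)),
                n_boot=B,
                in_original=bool(orig_present[k]),
            )
        )
    return records


def stability_table(records: list[EdgeStabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_i": r.edge[0],
                "node_j": r.edge[1],
                "mean_weight": r.mean_weight,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "min": r.w_min,
                "max": r.w_max,
                "presence_fraction": r.presence_fraction,
                "B": r.n_boot,
                "in_original": r.in_original,
            }
            for r in records
        ]
    )


@dataclass
class PermutationResult:
    edge: tuple[str, str]
    observed_r: float
    p: float
    n_permutations: int


def permutation_edge_test(
    data: MixedDataset,
    edge: tuple[str, str],
    conditioning: list[str] | None = None,
    N: int = 1000,
    seed: int = 0,
    permute_member: int = 0,
) -> PermutationResult:
    """Permutation test of a pair's partial correlation.

    ``permute_member`` selects which member's residuals are shuffled
    (0 = first, the metabolite by the pipeline's convention).
    """
    if N < 1:
        raise ValueError("need at least one permutation")
    a, b = edge
    if a == b:
        raise ValueError("edge members must be distinct")
    conditioning = list(conditioning or [])
    sub = data.frame[[a, b, *conditioning]].dropna()
    n = len(sub)
    Z = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in conditioning])

    def resid(col: str) -> np.ndarray:
        y = sub[col].to_numpy(dtype=float)
        coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
        if rank < Z.shape[1]:
            raise ValueError("conditioning design is rank-deficient")
        return y - Z @ coef

    ra, rb = resid(a), resid(b)
    observed = float(stats.pearsonr(ra, rb)[0])

    moving, fixed = (ra, rb) if permute_member == 0 else (rb, ra)
    moving = (moving - moving.mean()) / moving.std()
    fixed = (fixed - fixed.mean()) / fixed.std()
    rng = np.random.default_rng(seed)
    # N shuffles of the moving residuals; correlations via one matmul
    perm = rng.permuted(np.broadcast_to(moving, (N, n)), axis=1)
    r_null = perm @ fixed / n
    n_extreme = int(np.sum(np.abs(r_null) >= abs(observed) - 1e-12))
    p = (1 + n_extreme) / (N + 1)
    return PermutationResult(edge=(a, b), observed_r=observed, p=float(p), n_permutations=N)
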