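"""Bridge enumeration and metabolite scoring.

A *bridge pathway* is a triple (risk factor, metabolite, symptom) in
which the metabolite carries a nonzero network edge to both the risk
factor and the symptom; the metabolite is the bridge.  Metabolites are
scored by

* degree centrality — nonzero edges within the metabolite-metabolite
  sub-network (full-network degree reported alongside);
* jointness — how specifically a metabolite connects the two phenotype
  groups: the number of distinct (risk factor, symptom) pairs it bridges
  (default), or the sum over bridged pairs of min(|w_rf|, |w_sym|)
  (weighted variant).

Candidate selection applies a two-of-three rule across the stability,
permutation and robustness verdicts: a metabolite is selected when at
least two verdicts are semi-or-better and at least one is a full pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from metabridge.mgm_network import NetworkModel

VERDICTS = ("pass", "semi", "fail")


def _check_roles(network: NetworkModel) -> None:
    roles = set(network.nodes["role"])
    if not roles & {"symptom", "metabolite", "risk_factor"}:
        raise ValueError("network carries no role annotations")


@dataclass(frozen=True)
class BridgePathway:
    risk_factor: str
    metabolite: str
    symptom: str
    rf_weight: float
    symptom_weight: float


def find_bridge_pathways(network: NetworkModel) -> list[BridgePathway]:
    """All (risk factor, metabolite, symptom) triples with both edges
    nonzero, in lexicographic order."""
    _check_roles(network)
    risk_factors = sorted(network.nodes_by_role("risk_factor"))
    metabolites = sorted(network.nodes_by_role("metabolite"))
    symptoms = sorted(network.nodes_by_role("symptom"))
    pathways = []
    for rf in risk_factors:
        for m in metabolites:
            w_rf = network.weight(m, rf)
            if w_rf == 0:
                continue
            for s in symptoms:
                w_s = network.weight(m, s)
                if w_s != 0:
                    pathways.append(BridgePathway(rf, m, s, w_rf, w_s))
    return pathways


def degree_centrality(network: NetworkModel, scope: str = "metabolite") -> dict[str, int]:
    """Per-metabolite count of nonzero incident edges.

    ``scope="metabolite"`` (default) counts edges inside the
    metabolite-metabolite sub-network; ``scope="full"`` counts all
    incident edges.
    """
    _check_roles(network)
    metabolites = network.nodes_by_role("metabolite")
    met_set = set(metabolites)
    degrees = {}
    for m in metabolites:
        i = network.index_of(m)
        count = 0
        for other in network.node_names:
            if other == m:
                continue
            if scope == "metabolite" and other not in met_set:
                continue
            if network.adjacency[i, network.index_of(other)] != 0:
                count += 1
        degrees[m] = count
    return degrees


def jointness_score(network: NetworkModel, weighted: bool = False) -> dict[str, float]:
    """Bridged (risk factor, symptom) pairs per metabolite.

    Count variant (default): number of distinct pairs.  Weighted
    variant: sum over pairs of min(|w_m,rf|, |w_m,sym|).  Zero when the
    metabolite lacks an edge to either group.
    """
    _check_roles(network)
    scores: dict[str, float] = {m: 0.0 for m in network.nodes_by_role("metabolite")}
    for path in find_bridge_pathways(network):
        if weighted:
            scores[path.metabolite] += min(abs(path.rf_weight), abs(path.symptom_weight))
        else:
            scores[path.metabolite] += 1.0
    if not weighted:
        scores = {m: float(int(v)) for m, v in scores.items()}
    return scores


# --------------------------------------------------------------- selection


@dataclass
class SelectionThresholds:
    """Cutoffs mapping raw assessment scores to pass/semi/fail verdicts.

    Stability: minimum bootstrap presence fraction over the metabolite's
    bridge edges.  Permutation: number of its two bridge-edge types
    (risk-factor side, symptom side) significant at ``permutation_alpha``.
    Robustness: minimum, over its phenotype pairs, of the number of
    covariate sets (of ``ladder_size``) with p < 0.05.
    """

    stability_pass: float = 0.9
    stability_semi: float = 0.5
    permutation_alpha: float = 0.05
    robustness_pass: int = 4
    robustness_semi: int = 2
    ladder_size: int = 6


def stability_verdict(presence_fraction: float, thresholds: SelectionThresholds) -> str:
    if presence_fraction >= thresholds.stability_pass:
        return "pass"
    if presence_fraction >= thresholds.stability_semi:
        return "semi"
    return "fail"


def permutation_verdict(n_significant_sides: int) -> str:
    return {2: "pass", 1: "semi"}.get(n_significant_sides, "fail")


def robustness_verdict(n_significant_sets: int, thresholds: SelectionThresholds) -> str:
    if n_significant_sets >= thresholds.robustness_pass:
        return "pass"
    if n_significant_sets >= thresholds.robustness_semi:
        return "semi"
    return "fail"


def is_selected(verdicts: tuple[str, str, str]) -> bool:
    """Two-of-three rule: >= 2 verdicts semi-or-better, >= 1 full pass."""
    for v in verdicts:
        if v not in VERDICTS:
            raise ValueError(f"unknown verdict {v!r}")
    n_semi_or_better = sum(v in ("pass", "semi") for v in verdicts)
    n_pass = sum(v == "pass" for v in verdicts)
    return n_semi_or_better >= 2 and n_pass >= 1


def select_candidates(table: pd.DataFrame, thresholds: SelectionThresholds | None = None) -> list[str]:
    """Apply the two-of-three rule to a bridge table.

    ``table`` needs columns metabolite, stability_verdict,
    permutation_verdict, robustness_verdict (and typically degree /
    jointness, used only for the reported ranking: candidates are
    ordered by descending jointness, then ascending degree).
    """
    required = {"metabolite", "stability_verdict", "permutation_verdict", "robustness_verdict"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"bridge table missing columns: {sorted(missing)}")
    for col in ("stability_verdict", "permutation_verdict", "robustness_verdict"):
        if table[col].isna().any():
            raise ValueError(f"missing verdicts in {col}")
    selected = table[
        [
            is_selected((r.stability_verdict, r.permutation_verdict, r.robustness_verdict))
            for r in table.itertuples()
        ]
    ].copy()
    if "jointness" in selected.columns and "degree" in selected.columns:
        selected = selected.sort_values(
            ["jointness", "degree", "metabolite"], ascending=[False, True, True], kind="mergesort"
        )
    else:
        selected = selected.sort_values("metabolite", kind="mergesort")
    return list(selected["metabolite"])
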