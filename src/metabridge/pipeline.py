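"""End-to-end orchestration: impute -> adjust -> network -> bridges ->
stability -> permutation -> selection -> covariate ladder -> optional MR.

One :class:`RunConfig` drives the whole chain; a fixed seed makes the
report byte-identical across reruns.  Every default that fills a gap the
analysis recipe leaves open (lambda selection, AND rule, ordinal-as-
Gaussian typing, permutation scheme, verdict thresholds) is recorded in
the report's assumption log so each run is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from metabridge.dataset import MixedDataset
from metabridge import mr as mr_mod
from metabridge.bridge_analysis import (
    SelectionThresholds,
    degree_centrality,
    find_bridge_pathways,
    is_selected,
    jointness_score,
    permutation_verdict,
    robustness_verdict,
    stability_verdict,
)
from metabridge.mgm_network import fit_mgm
from metabridge.preprocess import ImputationConfig, adjust, impute, screen_covariates
from metabridge.resampling import bootstrap_edges, permutation_edge_test, stability_table
from metabridge.robustness import CovariateLadder, ols_ladder

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths, stage parameters and the mandatory seed for one full run."""

    seed: int
    cohort_path: str | None = None
    roster_path: str | None = None
    replication_cohort_path: str | None = None
    replication_roster_path: str | None = None
    gwas_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # label, exposure, outcome
    out_dir: str | None = None

    imputation: ImputationConfig | None = None
    screen_alpha: float = 0.05
    screen_covariate_names: tuple[str, ...] = ("sex", "age")
    combine_rule: str = "AND"
    ebic_gamma: float = 0.5
    n_lambda: int = 50
    ordinal_as: str = "gaussian"
    n_boot: int = 100
    n_permutations: int = 1000
    permutation_alpha: float = 0.05
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    ladder: CovariateLadder | None = None
    run_mr: bool = True
    mr_p_threshold: float = 5e-8


def _available_ladder(ladder: CovariateLadder, frame: pd.DataFrame) -> tuple[CovariateLadder, list[str]]:
    """Drop ladder covariates missing from the table, keeping rung count."""
    dropped = sorted({c for rung in ladder.sets for c in rung if c not in frame.columns})
    sets = tuple(tuple(c for c in rung if c in frame.columns) for rung in ladder.sets)
    return CovariateLadder(sets=sets), dropped


def run_full(
    config: RunConfig,
    dataset: MixedDataset | None = None,
    replication: MixedDataset | None = None,
) -> dict:
    """Execute the full discovery chain; returns the run report.

    ``dataset`` may be passed directly (e.g. from the simulator);
    otherwise it is read from the configured paths.  ``replication``
    defaults to the primary cohort.
    """
    assumptions: list[str] = []
    if dataset is None:
        if not (config.cohort_path and config.roster_path):
            raise ValueError("run_full needs a dataset or cohort/roster paths")
        dataset = MixedDataset.read(config.cohort_path, config.roster_path)
    if replication is None:
        if config.replication_cohort_path:
            replication = MixedDataset.read(
                config.replication_cohort_path, config.replication_roster_path
            )
        else:
            replication = dataset
            assumptions.append("replication ladder run on the primary cohort (no external cohort configured)")

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    # ---- imputation
    imp_cfg = config.imputation or ImputationConfig(seed=stage_seed[0])
    completed, imputation_diag = impute(dataset, imp_cfg)
    assumptions.append(
        f"imputation: {imp_cfg.n_rounds} chained-equation rounds with {imp_cfg.estimator}, collapsed to one completed table"
    )

    # ---- covariate screen + adjust
    covs = [c for c in config.screen_covariate_names if c in completed.frame.columns]
    screen = screen_covariates(completed, covs, alpha=config.screen_alpha)
    adjusted, skipped = adjust(completed, screen)
    assumptions.append(f"covariate screen at alpha={config.screen_alpha} on {covs}; flagged variables residualized")
    if skipped:
        assumptions.append(f"categorical variables not residualized: {skipped}")

    # ---- network
    network = fit_mgm(
        adjusted,
        selection="ebic",
        combine_rule=config.combine_rule,
        gamma=config.ebic_gamma,
        n_lambda=config.n_lambda,
        ordinal_as=config.ordinal_as,
    )
    assumptions.append(
        f"MGM: EBIC gamma={config.ebic_gamma}, {config.n_lambda}-point lambda path, "
        f"{config.combine_rule} rule, ordinal items treated as {config.ordinal_as}"
    )

    # ---- bridges & centrality
    pathways = find_bridge_pathways(network)
    degree_sub = degree_centrality(network, scope="metabolite")
    degree_full = degree_centrality(network, scope="full")
    jointness = jointness_score(network)
    jointness_w = jointness_score(network, weighted=True)
    bridge_metabolites = sorted({p.metabolite for p in pathways})
    bridge_edges = sorted(
        {(p.metabolite, p.risk_factor) for p in pathways}
        | {(p.metabolite, p.symptom) for p in pathways}
    )

    # ---- stability bootstrap
    fit_config = dict(
        selection="ebic",
        combine_rule=config.combine_rule,
        gamma=config.ebic_gamma,
        n_lambda=config.n_lambda,
        ordinal_as=config.ordinal_as,
    )
    stability = bootstrap_edges(adjusted, fit_config, B=config.n_boot, seed=stage_seed[1])
    stab_df = stability_table(stability)
    presence = {
        (r.edge[0], r.edge[1]): r.presence_fraction for r in stability
    }

    def edge_presence(a: str, b: str) -> float:
        return presence.get((a, b), presence.get((b, a), 0.0))

    # ---- permutation on bridge edges (metabolite member permuted,
    # conditioning on the screen covariates; Freedman-Lane residual scheme)
    perm_rows = []
    for k, (m, other) in enumerate(bridge_edges):
        res = permutation_edge_test(
            completed,
            (m, other),
            conditioning=covs,
            N=config.n_permutations,
            seed=stage_seed[2] + k,
        )
        perm_rows.append(
            {"metabolite": m, "partner": other, "r": res.observed_r, "p": res.p, "N": res.n_permutations}
        )
    perm_df = pd.DataFrame(perm_rows, columns=["metabolite", "partner", "r", "p", "N"])
    assumptions.append(
        "permutation statistic: partial correlation given the screen covariates; "
        "metabolite residuals permuted (Freedman-Lane)"
    )

    # ---- robustness ladder on the replication cohort
    ladder = config.ladder or CovariateLadder()
    ladder, dropped_covs = _available_ladder(ladder, replication.frame)
    if dropped_covs:
        assumptions.append(f"ladder covariates absent from replication table, dropped: {dropped_covs}")
    pairs = [(m, other) for m, other in bridge_edges]
    if pairs:
        ladder_res = ols_ladder(replication, pairs, ladder)
        ladder_df = ladder_res.table
        verdict_counts = ladder_res.verdict_counts()
    else:
        ladder_df = pd.DataFrame(columns=["dependent", "independent", "covariates", "beta", "se", "p", "n"])
        verdict_counts = pd.DataFrame(columns=["dependent", "independent", "n_significant_sets"])

    # ---- verdicts and selection
    thresholds = config.thresholds
    role = {name: network.role_of(name) for name in network.node_names}
    table_rows = []
    for m in bridge_metabolites:
        m_edges = [(a, b) for a, b in bridge_edges if a == m]
        stab = min(edge_presence(a, b) for a, b in m_edges)
        sub = perm_df[perm_df["metabolite"] == m]
        rf_sig = bool(
            (sub[[role[p] == "risk_factor" for p in sub["partner"]]]["p"] < config.permutation_alpha).any()
        )
        sym_sig = bool(
            (sub[[role[p] == "symptom" for p in sub["partner"]]]["p"] < config.permutation_alpha).any()
        )
        vc = verdict_counts[verdict_counts["dependent"] == m]["n_significant_sets"]
        n_sig_sets = int(vc.min()) if len(vc) else 0
        verdicts = (
            stability_verdict(stab, thresholds),
            permutation_verdict(int(rf_sig) + int(sym_sig)),
            robustness_verdict(n_sig_sets, thresholds),
        )
        table_rows.append(
            {
                "metabolite": m,
                "degree": degree_sub[m],
                "degree_full": degree_full[m],
                "jointness": jointness[m],
                "jointness_weighted": jointness_w[m],
                "min_presence_fraction": stab,
                "n_significant_permutation_sides": int(rf_sig) + int(sym_sig),
                "min_significant_ladder_sets": n_sig_sets,
                "stability_verdict": verdicts[0],
                "permutation_verdict": verdicts[1],
                "robustness_verdict": verdicts[2],
                "selected": is_selected(verdicts),
            }
        )
    bridge_table = pd.DataFrame(
        table_rows,
        columns=[
            "metabolite", "degree", "degree_full", "jointness", "jointness_weighted",
            "min_presence_fraction", "n_significant_permutation_sides",
            "min_significant_ladder_sets", "stability_verdict", "permutation_verdict",
            "robustness_verdict", "selected",
        ],
    )
    selected = sorted(bridge_table[bridge_table["selected"]]["metabolite"]) if len(bridge_table) else []

    # ---- MR on selected metabolites where GWAS files are configured
    mr_reports = {}
    if config.run_mr and config.gwas_pairs:
        for label, exp_path, out_path in config.gwas_pairs:
            exposure = mr_mod.GwasSummary.read(exp_path)
            outcome = mr_mod.GwasSummary.read(out_path)
            mr_reports[label] = mr_mod.run_bidirectional(
                exposure, outcome, p_threshold=config.mr_p_threshold, seed=stage_seed[3]
            )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_subjects": dataset.n_subjects,
        "n_nodes": len(network.node_names),
        "n_edges": network.edge_count,
        "pathways": [asdict(p) for p in pathways],
        "bridge_table": table_rows,
        "selected_metabolites": selected,
        "stability": stab_df.to_dict(orient="records"),
        "permutation": perm_rows,
        "ladder": ladder_df.to_dict(orient="records"),
        "mr": mr_reports,
        "assumption_log": assumptions,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        network.write(out / "network_edges.tsv", out / "network_meta.json")
        stab_df.to_csv(out / "stability.tsv", sep="\t", index=False)
        perm_df.to_csv(out / "permutation.tsv", sep="\t", index=False)
        ladder_df.to_csv(out / "ladder.tsv", sep="\t", index=False)
        bridge_table.to_csv(out / "bridge_table.tsv", sep="\t", index=False)
        imputation_diag.to_csv(out / "imputation_diagnostics.tsv", sep="\t", index=False)
    return report
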