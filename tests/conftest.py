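import numpy as np
import pandas as pd
import pytest

from metabridge.dataset import MixedDataset, Roster
from metabridge.mgm_network import NetworkModel
from metabridge.simulate import CohortSpec, PlantedBridge, generate_cohort


@pytest.fixture
def planted_edge_cohort():
    """n=2000 cohort with one planted metabolite--risk-factor edge (r=0.5)."""
    spec = CohortSpec(
        n_subjects=2000, n_symptoms=2, n_metabolites=3, n_riskfactors=1,
        graph=[("metabolite_1", "riskfactor_1", 0.5)], missing_rates={}, seed=3,
    )
    data, truth = generate_cohort(spec)
    return data, truth


@pytest.fixture
def gaussian_frame_dataset():
    """Helper building a MixedDataset from plain gaussian columns."""

    def build(arrays: dict[str, np.ndarray], roles: dict[str, str] | None = None) -> MixedDataset:
        roles = roles or {}
        records = [(name, roles.get(name, "metabolite"), "gaussian", 0) for name in arrays]
        return MixedDataset(frame=pd.DataFrame(arrays), roster=Roster.from_records(records))

    return build


# --- the printed worked example: 11 metabolite-phenotype adjacencies over a
# 21-symptom / 52-metabolite / 3-risk-factor roster -------------------------

NAMED_SYMPTOMS = [
    "change_in_appetite", "loss_of_interest", "change_in_sleep_pattern", "worthlessness",
]
NAMED_METABOLITES = ["omega_3_fa", "creatinine", "albumin", "glucose", "citrate"]
RISK_FACTORS = ["cIMT", "SBP", "DBP"]

WORKED_ADJACENCIES = [
    ("omega_3_fa", "cIMT", 0.0875),
    ("omega_3_fa", "change_in_appetite", -0.0517),
    ("creatinine", "cIMT", 0.05),
    ("creatinine", "loss_of_interest", 0.04),
    ("creatinine", "change_in_sleep_pattern", 0.04),
    ("albumin", "cIMT", 0.04),
    ("albumin", "change_in_sleep_pattern", -0.03),
    ("glucose", "cIMT", 0.1002),
    ("glucose", "change_in_sleep_pattern", 0.052),
    ("citrate", "DBP", 0.0861),
    ("citrate", "worthlessness", 0.0127),
]

WORKED_PATHWAYS = {
    ("cIMT", "omega_3_fa", "change_in_appetite"),
    ("cIMT", "creatinine", "loss_of_interest"),
    ("cIMT", "creatinine", "change_in_sleep_pattern"),
    ("cIMT", "albumin", "change_in_sleep_pattern"),
    ("cIMT", "glucose", "change_in_sleep_pattern"),
    ("DBP", "citrate", "worthlessness"),
}


def worked_example_network() -> NetworkModel:
    symptoms = NAMED_SYMPTOMS + [f"symptom_{i}" for i in range(len(NAMED_SYMPTOMS) + 1, 22)]
    metabolites = NAMED_METABOLITES + [f"metabolite_{i}" for i in range(len(NAMED_METABOLITES) + 1, 53)]
    nodes = (
        [(s, "symptom") for s in symptoms]
        + [(m, "metabolite") for m in metabolites]
        + [(r, "risk_factor") for r in RISK_FACTORS]
    )
    return NetworkModel.from_edges(nodes, WORKED_ADJACENCIES)


@pytest.fixture
def worked_network():
    return worked_example_network()


@pytest.fixture
def bridge_fixture_spec():
    """2 planted bridge metabolites among 20, 5 symptoms, 2 risk factors."""

    def build(seed: int, n_subjects: int = 1500) -> CohortSpec:
        return CohortSpec(
            n_subjects=n_subjects, n_symptoms=5, n_metabolites=20, n_riskfactors=2,
            planted_bridges=[
                PlantedBridge("riskfactor_1", "metabolite_1", "symptom_1", 0.3, 0.3),
                PlantedBridge("riskfactor_2", "metabolite_2", "symptom_2", 0.3, 0.3),
            ],
            seed=seed,
        )

    return build
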