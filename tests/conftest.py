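import warnings

import pandas as pd
import pytest

from ptmb.io_formats import ClinicalRecord, CohortDataset, MutationRecord
from ptmb.synthetic_data import SimulationConfig, simulate_cohorts


def make_cohort(name="toy", spec=None, survival=None):
    """Build a cohort from {sample: (response, [(gene, consequence, pc?), ...])}."""
    spec = spec or {}
    mutations, clinical = [], []
    for sample, (response, muts) in spec.items():
        os_time, os_event = (survival or {}).get(sample, (None, None))
        clinical.append(
            ClinicalRecord(sample, response, os_time=os_time, os_event=os_event)
        )
        for m in muts:
            gene, consequence, *rest = m
            mutations.append(
                MutationRecord(
                    sample, gene, consequence,
                    protein_change=rest[0] if rest else None,
                )
            )
    return CohortDataset(name, mutations, clinical)


@pytest.fixture
def toy_cohort():
    return make_cohort(
        spec={
            "s1": ("R", [("BRAF", "missense_variant", "V600E"),
                         ("TP53", "stop_gained")]),
            "s2": ("R", [("BRAF", "missense_variant", "V600E")]),
            "s3": ("R", [("TTN", "synonymous_variant")]),
            "s4": ("NR", [("KRAS", "missense_variant", "G12D")]),
            "s5": ("NR", []),
            "s6": ("NR", [("BRAF", "missense_variant", "V600K")]),
        }
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed 11)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohorts(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A fast small simulation for plumbing tests."""
    cfg = SimulationConfig(
        n_cohorts=2, n_samples=20, n_genes=300, n_pathways=10,
        planted_pp_pathways=2, genes_per_pathway=12, seed=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohorts(cfg)


@pytest.fixture
def lengths_toy():
    return pd.Series(
        {"BRAF": 2301, "TP53": 1182, "KRAS": 570, "TTN": 100000, "EGFR": 3633},
        name="coding_length_bp",
    )
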