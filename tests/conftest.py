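import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from xenotalk import CrosstalkParams, SimConfig
from xenotalk.compendium import LRCompendium, merge_sources
from xenotalk.expression import CONDITIONS, ExpressionMatrix, SampleSheet
from xenotalk.simulate import simulate_compendium, simulate_xeno_expression


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def expression_bundle(sim_config):
    """One seeded synthetic expression study (matrix, annotation, sheet, blacklist, truth)."""
    return simulate_xeno_expression(sim_config, seed=7)


@pytest.fixture(scope="session")
def sim_compendium(sim_config, expression_bundle) -> LRCompendium:
    truth = expression_bundle[4]
    return simulate_compendium(sim_config, truth, seed=7)


@pytest.fixture(scope="session")
def recovery_params() -> CrosstalkParams:
    """Benchmark configuration for exact planted-set recovery.

    BH-adjusted detection at alpha 0.01 over the full per-species gene
    family (prefilter off) keeps the chance exclusion of a truly
    combo-only ligand by monotherapy noise negligible.
    """
    return CrosstalkParams(alpha=0.01, p_mode="bh", prefilter_alpha=None)


@pytest.fixture
def toy_compendium() -> LRCompendium:
    return merge_sources(
        [
            pd.DataFrame(
                {
                    "ligand": ["CSF2", "CSF2", "VEGFA"],
                    "receptor": ["CSF2RA", "CSF2RB", "FLT1"],
                    "source": ["iuphar"] * 3,
                }
            )
        ]
    )


def make_matrix(values: np.ndarray, probes, species, genes, samples=None) -> ExpressionMatrix:
    samples = samples if samples is not None else [f"s{i}" for i in range(values.shape[1])]
    data = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    meta = pd.DataFrame({"species": species, "gene": genes}, index=data.index)
    return ExpressionMatrix(data, meta, level="probe")


def four_arm_sheet(n_replicates: int = 3) -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"{c}_{r}" for c in CONDITIONS for r in range(1, n_replicates + 1)],
                "condition": [c for c in CONDITIONS for _ in range(n_replicates)],
                "replicate": [r for _ in CONDITIONS for r in range(1, n_replicates + 1)],
            }
        )
    )
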