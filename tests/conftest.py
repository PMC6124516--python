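"""Shared fixtures: small seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from placentax.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-scale study: enough genes/samples for calling power,
    small enough that a full generate-and-call cycle is fast."""
    return SimulationConfig(
        n_autosomal=300, n_x_genes=120, n_y_genes=10,
        n_female=40, n_male=40,
        n_subjects=3000, n_metabolites=20,
    )


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate_expression(small_config, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_cpg_frame(meth, total, positions=None, gene_id="G1", sample_id="S1",
                   chromosome="chrX"):
    """Small helper to build promoter-assigned CpG records."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    if positions is None:
        positions = np.arange(len(meth)) * 10 + 100
    return pd.DataFrame({
        "chromosome": chromosome,
        "position": positions,
        "methylated_reads": meth,
        "total_reads": total,
        "sample_id": sample_id,
        "gene_id": gene_id,
    })
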