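import numpy as np
import pandas as pd
import pytest

from cssmisreg import synthetic as syn
from cssmisreg.models import donor_strain, host_strain, substitution_strain


@pytest.fixture(scope="session")
def layout():
    return syn.generate_genome(n_autosomes=5, genes_per_chromosome=40, seed=7)


@pytest.fixture(scope="session")
def strains(layout):
    return [
        host_strain("B6"),
        donor_strain(layout, "MSM"),
        substitution_strain(layout, "CSSX", "X", boundary_bp=2_000_000),
    ]


@pytest.fixture(scope="session")
def architecture(layout):
    return syn.assign_architecture(layout, seed=11)


@pytest.fixture(scope="session")
def study(layout, architecture, strains):
    cfg = syn.SimulationConfig(seed=3, age_dpp=7, cascade=True)
    return syn.generate_expression_study(layout, architecture, strains, cfg)


@pytest.fixture(scope="session")
def expr(study):
    return study[0]


@pytest.fixture(scope="session")
def truth(study):
    return study[1]


@pytest.fixture(scope="session")
def annotation(layout, strains):
    return syn.generate_probe_annotation(
        layout, strains, poly_rate_donor=0.15, poly_rate_host=0.01, seed=5
    )


@pytest.fixture()
def tiny_expr():
    """Hand-built 4-gene, 2x3-sample matrix with known group means."""
    values = pd.DataFrame(
        {
            "A_r1": [16.0, 32.0, 4.0, 100.0],
            "A_r2": [16.0, 32.0, 4.0, 100.0],
            "A_r3": [16.0, 32.0, 4.0, 100.0],
            "B_r1": [16.0, 16.0, 8.0, 100.0],
            "B_r2": [16.0, 16.0, 8.0, 100.0],
            "B_r3": [16.0, 16.0, 8.0, 100.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    samples = pd.DataFrame(
        {
            "strain": ["A"] * 3 + ["B"] * 3,
            "age_dpp": [5] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=values.columns,
    )
    from cssmisreg.models import ExpressionMatrix

    return ExpressionMatrix(values, samples)
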