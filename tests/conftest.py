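import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cistrans.simulate import SimConfig, simulate_cross
from cistrans.counts import filter_low_expression
from cistrans.pipeline import allele_matrix
from cistrans.linear_model import run_ase_linear
from cistrans.categories import assign_table


def linear_assignments(config: SimConfig, cross_id="c1", fdr=0.01, pool_treatments=False):
    """Simulate one cross and run the linear engine + category assignment."""
    bundle = simulate_cross(config, cross_id, snp_level=False)
    long = filter_low_expression(bundle.allele_counts, 50)
    mat, meta = allele_matrix(long, bundle.coldata)
    tests = run_ase_linear(mat, meta, fdr=fdr, pool_treatments=pool_treatments)
    return bundle, assign_table(tests)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete simulated cross shared across read-only tests."""
    return simulate_cross(SimConfig(n_genes=60, seed=42, cross_ids=("c1",)), "c1")


def truth_joined(bundle, assignments, context):
    truth = bundle.truth.set_index("gene_id")[
        ["true_category", "true_inheritance_mode", "c_g", "t_g"]
    ]
    sub = assignments[assignments["context"] == context].set_index("gene_id")
    return sub.join(truth)
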