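import pytest

import sepalvar as sv


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic dataset at the default study conditions (11 control
    batches, 16 mutants, 39-90 sepals, planted CV^2-vs-expression slope).

    Expression matrix kept to 60 genes: the background cloud beyond the 16
    mutant genes does not enter any screen.
    """
    cfg = sv.SimConfig(seed=11, n_expr_genes=60)
    table, matrix, gene_map, truth = sv.simulate_dataset(cfg)
    return cfg, table, matrix, gene_map, truth


@pytest.fixture(scope="session")
def screen_table(default_bundle):
    _, table, matrix, gene_map, _ = default_bundle
    em = sv.ExpressionMatrix(values=matrix, gene_map=gene_map)
    st, rejects = sv.build_screen_table(table, em)
    assert rejects == []
    return st


@pytest.fixture(scope="session")
def null_bundle():
    """Synthetic dataset with no planted effect and no planted slope."""
    cfg = sv.SimConfig(seed=7, planted_slope=0.0, effect_scale=0.0,
                       noise_sd=0.0, n_expr_genes=40)
    table, matrix, gene_map, truth = sv.simulate_dataset(cfg)
    return cfg, table, matrix, gene_map, truth
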