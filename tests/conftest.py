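import numpy as np
import pandas as pd
import pytest

from heterosim.simulate import PhenoSimConfig, TrioSimConfig, simulate_phenotypes, simulate_trio_counts


@pytest.fixture(scope="session")
def small_trio():
    """A modest trio dataset with ground truth, shared across tests."""
    cfg = TrioSimConfig(n_genes=1500, seed=42)
    counts, samples, truth = simulate_trio_counts(cfg)
    return cfg, counts, samples, truth.set_index("gene")


@pytest.fixture(scope="session")
def pheno_table():
    cfg = PhenoSimConfig(n_lines=40, seed=7)
    table, truth = simulate_phenotypes(cfg)
    return cfg, table, truth.set_index("line_id")


def make_counts(means, reps=3, dispersion=0.05, seed=0, conditions=("stress",)):
    """Hand-built trio counts from explicit (maternal, paternal, hybrid) means.

    ``means`` is an (n_genes, 3) array; returns (counts, samples) in the
    package's standard layout.
    """
    rng = np.random.default_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    rows, cols = [], []
    names = []
    for cond in conditions:
        for ridx, role in enumerate(("maternal", "paternal", "hybrid")):
            for rep in range(1, reps + 1):
                mu = means[:, ridx]
                if dispersion < 1e-12:
                    c = rng.poisson(mu)
                else:
                    size = 1.0 / dispersion
                    c = rng.negative_binomial(size, size / (size + mu))
                cols.append(c)
                names.append(f"{role}_{cond}_r{rep}")
                rows.append((f"{role}_{cond}_r{rep}", role, cond, rep))
    counts = pd.DataFrame(
        np.column_stack(cols),
        index=[f"g{i}" for i in range(means.shape[0])],
        columns=names,
    )
    samples = pd.DataFrame(rows, columns=["sample_id", "role", "condition", "replicate"])
    return counts, samples
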