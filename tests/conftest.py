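import functools

import numpy as np
import pytest
from hypothesis import settings

import somcell

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


TINY_CONFIG = somcell.SimConfig(
    n_groups=2,
    group_sizes=(90, 110),
    group_names=("A", "B"),
    n_programs=3,
    genes_per_program=(25, 40),
    n_background_genes=60,
    program_mixing=((0.6, 0.3, 0.1), (0.1, 0.3, 0.6)),
    effect_size=2.0,
    velocity_source_states=(2,),
    seed=7,
)

# two mirrored programs -> their genes anti-correlate across cells
ANTI_CONFIG = somcell.SimConfig(
    n_groups=2,
    group_sizes=(80, 80),
    group_names=("A", "B"),
    n_programs=2,
    genes_per_program=(30, 40),
    n_background_genes=20,
    program_mixing=((0.95, 0.05), (0.05, 0.95)),
    effect_size=2.5,
    noise_sd=0.1,
    velocity_source_states=(),
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    return somcell.simulate(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_logc(tiny_dataset):
    return somcell.log_centralize(tiny_dataset.to_expression_matrix())


@pytest.fixture(scope="session")
def tiny_model(tiny_logc):
    cfg = somcell.SOMConfig(grid_rows=12, grid_cols=12, epochs=30, seed=3)
    return somcell.train_som(tiny_logc, cfg)


@pytest.fixture(scope="session")
def anti_dataset():
    return somcell.simulate(ANTI_CONFIG)


@pytest.fixture(scope="session")
def anti_model(anti_dataset):
    m = somcell.log_centralize(anti_dataset.to_expression_matrix())
    cfg = somcell.SOMConfig(grid_rows=10, grid_cols=10, epochs=40, seed=5)
    return somcell.train_som(m, cfg)


def program_unit_indices(model, dataset, program):
    """Flat unit indices hosting the BMUs of a planted program's genes."""
    gene_mask = dataset.true_gene_program == program
    return np.unique(model.bmu[gene_mask])


@functools.lru_cache(maxsize=1)
def gamma_recovery_errors():
    """Median relative error of fit_gamma on default-scale synthetic kinetics."""
    cfg = somcell.SimConfig(velocity_source_states=(), noise_sd=0.05, seed=21)
    ds = somcell.simulate(cfg)
    sp, up = somcell.knn_pool(ds.spliced.astype(float), ds.unspliced.astype(float),
                              n_neighbors=30)
    gamma = somcell.fit_gamma(up, sp)
    ok = np.isfinite(gamma)
    rel = np.abs(gamma[ok] - ds.true_gamma[ok]) / ds.true_gamma[ok]
    return float(ok.mean()), float(np.median(rel))


@functools.lru_cache(maxsize=1)
def source_recovery_hits(n_seeds=5):
    """How often the planted source states show net outward embedding flow.

    A state counts as identified when every planted source has a positive
    outward-flow score and the sources' mean score exceeds the mean over
    the remaining states.
    """
    from sklearn.decomposition import PCA

    hits = 0
    for seed in range(n_seeds):
        cfg = somcell.SimConfig(seed=seed)
        ds = somcell.simulate(cfg)
        vm = somcell.estimate_velocity(ds.spliced, ds.unspliced, ds.gene_ids,
                                       smooth=True, seed=seed)
        emb = PCA(n_components=2, svd_solver="randomized",
                  random_state=seed).fit_transform(np.log1p(vm.spliced))
        field = somcell.embedding_field(vm, emb, k=30)
        scores = somcell.state_flow_scores(field, emb, ds.true_program)
        sources = list(cfg.velocity_source_states)
        others = [s for s in scores.index if s not in sources]
        outward = (scores[sources] > 0).all()
        dominant = scores[sources].mean() > scores[others].mean()
        hits += bool(outward and dominant)
    return hits, n_seeds
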