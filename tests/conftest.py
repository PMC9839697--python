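import numpy as np
import pandas as pd
import pytest

from progan import preprocess, wgan
from progan.matrix import ExpressionMatrix
from progan.synthetic import generate_expression, make_pattern_design


@pytest.fixture(scope="session")
def default_design():
    return make_pattern_design()


@pytest.fixture(scope="session")
def default_dataset(default_design):
    """The default synthetic fixture: ~250 genes, 4 groups x 5 samples."""
    return generate_expression(default_design)


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate_expression(make_pattern_design(noise_sd=0.0))


@pytest.fixture(scope="session")
def small_matrix():
    """A tiny hand-sized matrix: 3 genes, 2 samples per group."""
    rng = np.random.default_rng(42)
    samples, phenos, ages = [], [], []
    for p in ("WT", "AD"):
        for a in ("3M", "6M"):
            for k in (1, 2):
                samples.append(f"{p}{a}_s{k}")
                phenos.append(p)
                ages.append(a)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(3, 8)),
        index=pd.Index([f"g{i}" for i in range(3)], name="gene_id"),
        columns=samples,
    )
    metadata = pd.DataFrame({"phenotype": phenos, "age": ages},
                            index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(values=values, metadata=metadata)


@pytest.fixture(scope="session")
def tiny_rescaled(small_matrix):
    augset = preprocess.augment(small_matrix)
    sr, params = preprocess.standardize(augset)
    return augset, preprocess.rescale(sr, params)


@pytest.fixture(scope="session")
def tiny_gan():
    """An untrained miniature GAN for architecture/arithmetic tests."""
    cfg = wgan.GanConfig(output_dim=6, latent_dim=4, gen_hidden=8,
                         critic_hidden=5, seed=7)
    return wgan.init_model(cfg)


@pytest.fixture(scope="session")
def scaled_down_run(default_dataset):
    """One scaled-down WGAN-GP training run on the default fixture.

    Shared session-wide because training dominates the suite's runtime:
    250 genes, 380 augmented samples, 15000 generator steps at lr 1e-4.
    The step-5000 checkpoint of this run is bit-identical to a separate
    5000-step run with the same seed (the update path does not depend on
    the configured total), so shorter-schedule checks reuse it.
    """
    matrix, truth = default_dataset
    augset = preprocess.augment(matrix)
    sr, params = preprocess.standardize(augset)
    rescaled = preprocess.rescale(sr, params)
    cfg = wgan.GanConfig(output_dim=len(rescaled.values), lr=1e-4,
                         n_gen_steps=15000, checkpoint_interval=500, seed=1)
    model = wgan.init_model(cfg)
    checkpoints = wgan.train(model, rescaled.values)
    return {
        "matrix": matrix, "truth": truth, "augset": augset,
        "rescaled": rescaled, "config": cfg, "model": model,
        "checkpoints": checkpoints,
    }
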