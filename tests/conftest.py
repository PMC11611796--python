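import numpy as np
import pytest

import sdweat as sw


@pytest.fixture(scope="session")
def bundled():
    return sw.load_bundled_benchmarks()


@pytest.fixture(scope="session")
def weat7(bundled):
    return next(b for b in bundled if b.id == "WEAT-7")


@pytest.fixture
def tiny_benchmark():
    """Four 2-term sets: the smallest legal benchmark."""
    return sw.BiasBenchmark(
        id="TINY",
        description="minimal benchmark",
        target_x=sw.TermSet("tx", ("alpha", "bravo")),
        target_y=sw.TermSet("ty", ("charlie", "delta")),
        attribute_a=sw.TermSet("aa", ("echo", "foxtrot")),
        attribute_b=sw.TermSet("ab", ("golf", "hotel")),
    )


@pytest.fixture
def synth_store_factory(weat7):
    """Callable (beta, seed, n_filler=...) -> synthetic store for WEAT-7."""

    def make(beta: float, seed: int, n_filler: int = 0, **cfg_kw):
        cfg = sw.SyntheticConfig(bias_strength=beta, seed=seed, **cfg_kw)
        return sw.generate_synthetic_embeddings(cfg, weat7, n_filler=n_filler)

    return make


def random_instance(rng, n_targets: int, n_attrs: int, dim: int = 6):
    """Random Gaussian vector sets (X, Y, A, B) with |X| = |Y|."""
    return (
        rng.normal(size=(n_targets, dim)),
        rng.normal(size=(n_targets, dim)),
        rng.normal(size=(n_attrs, dim)),
        rng.normal(size=(n_attrs, dim)),
    )
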