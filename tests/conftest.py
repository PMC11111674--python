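import numpy as np
import pytest

import ldinet as L
from ldinet.feature_tokenizer import TINY_TOKENIZER
from ldinet.training import TrainConfig, train


def overfit_counts(spec: L.SyntheticSpec, total: int = 64) -> dict:
    """Balanced counts over all valid triples, padded in class order to `total`."""
    counts = L.balanced_counts(spec, total // _n_classes(spec))
    order = sorted(counts, key=lambda t: (t.plant, t.disease or "", t.severity))
    i = 0
    while sum(counts.values()) < total:
        counts[order[i % len(order)]] += 1
        i += 1
    return counts


def _n_classes(spec):
    return spec.n_plants * (2 * spec.n_diseases + 1)


@pytest.fixture(scope="session")
def tiny_spec() -> L.SyntheticSpec:
    base = L.SyntheticSpec(n_plants=3, n_diseases=2, image_size=64,
                           noise_sd=0.02, seed=7)
    return L.SyntheticSpec(n_plants=3, n_diseases=2, image_size=64,
                           noise_sd=0.02, class_counts=overfit_counts(base),
                           seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_spec):
    """64 separable synthetic images + manifest + label space."""
    root = tmp_path_factory.mktemp("tinydata")
    manifest = L.generate_dataset(tiny_spec, root)
    space = L.synthetic_label_space(tiny_spec)
    records = L.read_manifest(manifest, space)
    return {"root": root, "manifest": manifest, "space": space,
            "records": records, "spec": tiny_spec}


@pytest.fixture(scope="session")
def overfit_run(tiny_dataset):
    """Tiny model trained to memorize the 64-image set (shared across tests)."""
    space = tiny_dataset["space"]
    cfg = L.ModelConfig(tokenizer=TINY_TOKENIZER, n_labels=space.total,
                        image_size=64)
    model = L.LDINet(cfg, rng=0)
    tc = TrainConfig(epochs=100, batch_size=16, base_lr=2e-3, lr_step=40,
                     lr_gamma=0.5, seed=0, image_size=64)
    model, history = train(model, tiny_dataset["records"],
                           tiny_dataset["records"], tc,
                           tiny_dataset["root"], space, augment=False)
    return {"model": model, "history": history, **tiny_dataset}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
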