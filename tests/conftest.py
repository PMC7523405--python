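import random

import pytest

from dicomsieve import CorpusSpec, TagStore, generate_corpus


@pytest.fixture(scope="session")
def small_spec() -> CorpusSpec:
    """A compact but feature-complete corpus: multi-CHI patients, burns,
    repeated volumes, derived series and description leaks all occur."""
    return CorpusSpec(
        n_patients=10,
        studies_per_patient=(1, 2),
        slices_per_series=(2, 5),
        multi_chi_fraction=0.3,
        desc_leak_fraction=0.3,
        burn_text_fraction=0.6,
        seed=42,
    )


@pytest.fixture(scope="session")
def corpus(tmp_path_factory, small_spec):
    """(archive_root, manifest) for the shared session corpus."""
    root = tmp_path_factory.mktemp("archive")
    manifest = generate_corpus(small_spec, root)
    return root, manifest


@pytest.fixture(scope="session")
def loaded_store(tmp_path_factory, corpus):
    """(store, load_report) over the session corpus."""
    root, _ = corpus
    store = TagStore(tmp_path_factory.mktemp("store") / "tags.sqlite")
    report = store.load_directory(root)
    yield store, report
    store.close()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(2024)


@pytest.fixture(scope="session")
def mapping(corpus):
    """Reconciled CHI->EUPI table for the session corpus."""
    from dicomsieve import MappingTable

    _, manifest = corpus
    table = MappingTable("session-eupi-key")
    table.reconcile([g for g in manifest.master_persons if len(g) > 1])
    return table


@pytest.fixture(scope="session")
def inventory(tmp_path_factory, loaded_store, mapping):
    """Promoted inventory over the session corpus (default config)."""
    from dicomsieve import Inventory, PromotionConfig, promote

    store, _ = loaded_store
    path = tmp_path_factory.mktemp("inv") / "inventory.sqlite"
    report = promote(store, PromotionConfig(), mapping, path)
    inv = Inventory(path)
    yield inv, report
    inv.close()
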