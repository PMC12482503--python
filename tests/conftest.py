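import numpy as np
import pytest

from synthprice import (
    RawCatalogEntry,
    SyntheticSpec,
    featurize_dataset,
    generate_es_library,
    generate_hs_library,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_es=300, n_hs=150, noise_sd=0.2, seed=11)


@pytest.fixture(scope="session")
def small_es(small_spec):
    return generate_es_library(small_spec)


@pytest.fixture(scope="session")
def small_hs(small_spec, small_es):
    hs, _skipped = generate_hs_library(small_es, small_spec)
    return hs


@pytest.fixture(scope="session")
def small_features(small_es, small_hs):
    """Morgan features (radius 2, 512 bits) for the small libraries."""
    smiles = [s for s, _ in small_es]
    y = np.array([p for _, p in small_es])
    X = featurize_dataset(smiles, "morgan", radius=2, n_bits=512)
    Xh = featurize_dataset(small_hs, "morgan", radius=2, n_bits=512)
    return X, y, Xh


@pytest.fixture
def worked_catalog():
    """Six-entry catalog with a hand-traceable preprocessing outcome.

    1 unparsable entry; two offers for ethanol at 10 and 4 USD/mmol (the
    cheaper survives); methane at 1 USD/mmol (below the 2 USD/mmol
    cutoff); two further clean entries.  Expected survivors: ethanol at
    log(4), ethylamine at log(5), benzene at log(3).
    """
    return [
        RawCatalogEntry("C1CC", 5.0, "per-mmol"),  # unclosed ring: unparsable
        RawCatalogEntry("CCO", 10.0, "per-mmol", supplier_id="a"),
        RawCatalogEntry("OCC", 4.0, "per-mmol", supplier_id="b"),  # same molecule, cheaper
        RawCatalogEntry("C", 1.0, "per-mmol"),  # below the 2 USD/mmol cutoff
        RawCatalogEntry("CCN", 5.0, "per-mmol"),
        RawCatalogEntry("c1ccccc1", 3.0, "per-mmol"),
    ]
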