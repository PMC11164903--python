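import numpy as np
import pandas as pd
import pytest

from beanprint.dataset import META_COLUMNS, SpectralDataset
from beanprint.synthetic import SyntheticSpec, generate_dataset


def make_meta(sample_ids, replicates, countries, regions=None):
    """Metadata frame for hand-built fixtures."""
    n = len(sample_ids)
    regions = regions if regions is not None else [""] * n
    return pd.DataFrame(
        {
            "spectrum_id": [f"{s}_r{r}" for s, r in zip(sample_ids, replicates)],
            "sample_id": sample_ids,
            "replicate": replicates,
            "country": countries,
            "region": regions,
            "variety": ["v"] * n,
            "process": ["p"] * n,
        },
        columns=META_COLUMNS,
    )


@pytest.fixture
def tiny_ds():
    """2 samples x 2 replicates on a 5-point grid."""
    wl = np.array([900.0, 1000.0, 1100.0, 1200.0, 1300.0])
    rng = np.random.default_rng(42)
    X = rng.uniform(0.1, 1.0, (4, 5))
    meta = make_meta(
        ["A1", "A1", "B1", "B1"], [1, 2, 1, 2], ["Yemen", "Yemen", "Other", "Other"]
    )
    return SpectralDataset(wl, X, meta)


@pytest.fixture(scope="session")
def small_synthetic():
    """Small but full-grid 2-class dataset with all nuisance layers on."""
    spec = SyntheticSpec(n_samples_per_class=12, seed=11)
    ds, scheme = generate_dataset(spec)
    return spec, ds, scheme


def structured_meta(class_sample_counts: dict[str, int], n_replicates: int = 4):
    """Metadata for a dataset with the given samples-per-class design."""
    sample_ids, reps, countries = [], [], []
    for cls, n in class_sample_counts.items():
        for s in range(n):
            sid = f"{cls}_{s + 1:03d}"
            for r in range(1, n_replicates + 1):
                sample_ids.append(sid)
                reps.append(r)
                countries.append(cls)
    return make_meta(sample_ids, reps, countries)


def meta_only_dataset(class_sample_counts, n_replicates=4, n_wavelengths=3, seed=0):
    """Dataset whose absorbance is irrelevant (split-arithmetic fixtures)."""
    meta = structured_meta(class_sample_counts, n_replicates)
    rng = np.random.default_rng(seed)
    wl = np.linspace(900, 2400, n_wavelengths)
    X = rng.uniform(0.1, 1.0, (len(meta), n_wavelengths))
    return SpectralDataset(wl, X, meta)
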