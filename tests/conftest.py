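import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

import hepatoscreen as hs
from hepatoscreen.selection import SelectionConfig


def fast_selection_config(seed: int = 0, **kwargs) -> SelectionConfig:
    """Selection config with a small importance forest for quick tests."""
    defaults = dict(
        importance_estimator=RandomForestClassifier(n_estimators=20),
        boruta_max_iter=15,
        seed=seed,
    )
    defaults.update(kwargs)
    return SelectionConfig(**defaults)


@pytest.fixture(scope="session")
def strong_signal_set():
    """80 compounds, 3 strongly informative + 3 noise continuous features."""
    fm, y, roles = hs.make_classification_set(
        hs.SynthSpec(n=80, p_informative=3, p_redundant=0, p_noise=3,
                     effect_size=2.5, seed=2)
    )
    return fm, y, roles


@pytest.fixture(scope="session")
def pmt():
    return hs.make_pmt_fixture()


@pytest.fixture
def compounds_csv(tmp_path):
    """Factory writing a compound CSV and returning its path."""

    def write(rows, name="compounds.csv", header="id,name,smiles,label"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return write


def aligned_family_views(labels, n_families, effect_size=1.5, p_informative=3,
                         p_noise=3, seed_base=100):
    """Independent synthetic family matrices sharing one label vector."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    fms = {}
    for i in range(n_families):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=n, p_informative=p_informative, p_redundant=0,
                         p_noise=p_noise, effect_size=effect_size,
                         class_balance=labels.mean(), seed=seed_base + i)
        )
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        order = np.empty(n, dtype=int)
        order[np.flatnonzero(labels == 1)] = pos[: (labels == 1).sum()]
        order[np.flatnonzero(labels == 0)] = neg[: (labels == 0).sum()]
        fm = fm.subset_rows(order)
        fm.row_ids = [f"c{j}" for j in range(n)]
        fm.family = f"fam{i}"
        fms[fm.family] = fm
    return fms
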