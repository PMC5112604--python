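import numpy as np
import pandas as pd
import pytest

import mbopls as m


@pytest.fixture(scope="session")
def design96():
    """The 96-run mixed-level screening array (12x2, 1x3, 1x4 levels)."""
    return m.build_design(m.tobacco_screen_factors(), 96, seed=1)


@pytest.fixture(scope="session")
def indicators(design96):
    return m.indicator_matrix(design96)


@pytest.fixture(scope="session")
def screen(design96):
    """One reduced simulated screen: filtered blocks, scaled blocks, fold cache."""
    ds = m.simulate_dataset(
        design96, m.tobacco_screen_config(1, n_features=(200, 180, 180))
    )
    exp = ds.samples_with_role("experiment")
    blanks = ds.samples_with_role("blank")
    adds = ds.samples_with_role("additive")
    raw, scaled, feats = {}, {}, {}
    for name, tab in ds.blocks.items():
        filtered, _ = m.remove_background_features(tab, blanks, adds, 30.0)
        raw[name] = filtered.loc[exp]
        scaled[name] = m.ParetoScaler().fit_transform(raw[name])
        feats[name] = ds.features[name]
    cache = m.FoldKernelCache([b.to_numpy() for b in raw.values()], scale=True)
    return {
        "dataset": ds, "raw": raw, "scaled": scaled, "features": feats,
        "cache": cache,
        "raw_arrays": [b.to_numpy() for b in raw.values()],
    }


def make_label_design(cols: dict) -> m.Design:
    """Assemble a Design directly from label columns (for alias/balance tests)."""
    df = pd.DataFrame({k: np.asarray(v).astype(str) for k, v in cols.items()})
    df.index = pd.RangeIndex(1, len(df) + 1, name="run_id")
    factors = [
        m.FactorSpec(k, tuple(sorted(pd.unique(df[k])))) for k in df
    ]
    return m.Design(factors=factors, assignment=df,
                    run_order=np.arange(len(df)), seed=0)
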