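import numpy as np
import pandas as pd
import pytest

from ago2seed.arrays import ArraySample
from ago2seed.simulate import SimDesign, simulate_study


def make_sample(cy5, cy3=None, flags=None, feature_ids=None, sample_id="s",
                arm="mirna", condition="iri", **meta) -> ArraySample:
    """Hand-built ArraySample for unit tests."""
    n = len(cy5)
    probes = pd.DataFrame({
        "probe_id": [f"P{i}" for i in range(n)],
        "feature_id": feature_ids if feature_ids is not None
        else [f"f{i}" for i in range(n)],
        "cy5": np.asarray(cy5, dtype=float),
        "cy3": np.full(n, np.nan) if cy3 is None else np.asarray(cy3, dtype=float),
        "flag": np.zeros(n, dtype=int) if flags is None else np.asarray(flags, dtype=int),
    })
    return ArraySample(sample_id=sample_id, arm=arm, condition=condition,
                       probes=probes, **meta)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study reused across read-only tests."""
    design = SimDesign(seed=11, n_mirna_probes=100, n_genes=100,
                       n_target_genes=10, timepoints=("rep1d",))
    return simulate_study(design)
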