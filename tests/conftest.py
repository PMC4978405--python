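import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

PAPER_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


def make_experiment(values: np.ndarray, times=PAPER_TIMES, reps=2, genes=None):
    """Assemble a two-group experiment from a raw genes x samples array."""
    from splinegan.containers import TimecourseExperiment

    rows = []
    for group in ("control", "treatment"):
        for t in times:
            for r in range(1, reps + 1):
                rows.append((f"{group}_t{t:g}_r{r}", group, float(t), str(r)))
    ann = pd.DataFrame(rows, columns=["sample", "group", "time", "replicate"]).set_index("sample")
    if genes is None:
        genes = [f"G{i:04d}" for i in range(1, values.shape[0] + 1)]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=ann.index)
    return TimecourseExperiment(frame, ann)


@pytest.fixture
def paper_layout_experiment():
    """Random 20-gene experiment on the 7-time-point, 2-replicate design."""
    rng = np.random.default_rng(42)
    return make_experiment(rng.normal(7.0, 1.0, size=(20, 28)))
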