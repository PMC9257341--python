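import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from imcmicro.presets import DEMO_FREQS, MIN_NUCLEUS_SPACING, demo_panel
from imcmicro.synth import rasterize_pattern, simulate_pattern


@pytest.fixture(scope="session")
def small_roi():
    """A 400-cell noiseless synthetic ROI with non-overlapping nuclei."""
    pattern = simulate_pattern(
        400, DEMO_FREQS, field=(500, 500), seed=11, min_spacing=MIN_NUCLEUS_SPACING
    )
    panel = demo_panel()
    stack, mask, table = rasterize_pattern(pattern, panel, seed=12)
    return {"pattern": pattern, "panel": panel, "stack": stack, "mask": mask, "table": table}


@pytest.fixture()
def random_cells():
    """500 random cell centroids in a 300×300 field (single ROI)."""
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 300, size=(500, 2))
    return pd.DataFrame(
        {"cell_id": np.arange(500) + 1, "x": pts[:, 0], "y": pts[:, 1]}
    )
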