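import pandas as pd
import pytest

import mitodwell as md
from mitodwell.benchmarks import interval_recovery, match_rates  # noqa: F401  (test helpers)
from mitodwell.localization import FrameStack


@pytest.fixture(scope="session")
def small_movie():
    """A 128x128, 200-frame movie with well-separated bound molecules and a
    few diffusing free molecules, plus its ground truth."""
    kin = md.KineticConfig(
        frac_fast=0.3, k_fast=1.0, k_slow=0.1, k_bleach=0.05,
        n_frames=200, n_molecules=20, seed=3,
    )
    mov = md.MovieConfig(width=128, height=128, n_free=5, kinetic=kin)
    stack, truth = md.simulate_movie(mov)
    return FrameStack(stack), truth, mov


def immobile_localizations(positions_um, frames):
    """Localization table for immobile spots seen in the given frames.

    ``positions_um``: list of (x, y); ``frames``: list of frame lists, one per
    spot."""
    rows = []
    for (x, y), fl in zip(positions_um, frames):
        for f in fl:
            rows.append({"frame": f, "x_um": x, "y_um": y})
    return pd.DataFrame(rows).sort_values("frame").reset_index(drop=True)
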