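import dataclasses

import numpy as np
import pytest

from osteodyn.simulate import make_condition_config, simulate_timelapse

# Small field/frame sizes keep single-movie fixtures fast; the simulator's
# condition-defining parameters (motility, secretion, noise) stay at their
# defaults.
SMALL = dict(field_size=(256, 256), n_frames=8, n_cells=8)


@pytest.fixture(scope="session")
def small_untreated():
    """One small untreated movie plus its ground truth (shared, read-only)."""
    cfg = make_condition_config("untreated", seed=11, **SMALL)
    stack, gt = simulate_timelapse(cfg)
    return stack, gt


@pytest.fixture()
def small_config():
    def _make(condition="untreated", seed=11, **overrides):
        return make_condition_config(condition, seed, **{**SMALL, **overrides})

    return _make


def brute_force_overlap(mask_initial, mask_final):
    """Independent per-pixel enumeration of areas (A, B, C)."""
    a = b = c = 0
    mi = np.asarray(mask_initial, dtype=bool)
    mf = np.asarray(mask_final, dtype=bool)
    for p, q in zip(mi.ravel(), mf.ravel()):
        if p and q:
            b += 1
        elif p:
            a += 1
        elif q:
            c += 1
    return a, b, c
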