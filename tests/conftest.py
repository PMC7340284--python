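"""Shared fixtures.

Full simulations are expensive, so every experiment used by more than one
test is a session-scoped fixture: the quantitative runs (level-3 icosphere)
back the strain/drying checks, and the coarse runs (level-2) back the
qualitative trend checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellsph import presets
from cellsph.engine import run_experiment


def _fresh(p):
    """Fresh-cell configs skip most of the (inert) drying stage."""
    p.n_steps_drying = min(p.n_steps_drying, int(round(5e-6 / p.dt)))
    return p


@pytest.fixture(scope="session")
def fresh_run():
    """Fresh cell (X/X0 = 1) at the quantitative reduced resolution:
    settle + short hold + compression."""
    return run_experiment(_fresh(presets.reduced()), seed=1)


@pytest.fixture(scope="session")
def dried_runs():
    """Moderately (0.5) and extremely (0.1) dried cells, full pipeline at
    the quantitative reduced resolution."""
    return {
        x: run_experiment(presets.reduced(target_moisture=x), seed=1)
        for x in (0.5, 0.1)
    }


@pytest.fixture(scope="session")
def trend_runs(fresh_run, dried_runs):
    """Trend-suite runs keyed by (turgor kPa, dryness, plate speed m/s,
    G MPa, radius um).  Comparisons run at the quantitative level-3
    resolution (re-using the session's benchmark runs for the 200 kPa /
    G = 18 members); only the cell-size comparison uses the coarse
    level-2 resolution, where both sizes share the same discretisation
    error.  The turgor-trio and rate runs shorten the compression stage
    (the fitted slope needs only the engaged strain range)."""
    out = {
        (200, 1.0, 2, 18, 75): fresh_run,
        (200, 0.5, 2, 18, 75): dried_runs[0.5],
        (200, 0.1, 2, 18, 75): dried_runs[0.1],
    }

    def run(key, preset, short_comp=False, **kw):
        p = preset(**kw)
        if key[1] >= 0.999:
            _fresh(p)
        if short_comp:
            p.n_steps_compression = int(p.n_steps_compression * 0.6)
        out[key] = run_experiment(p, seed=1)

    run((100, 1.0, 2, 18, 75), presets.reduced, short_comp=True,
        turgor_initial=100e3)
    run((300, 1.0, 2, 18, 75), presets.reduced, short_comp=True,
        turgor_initial=300e3)
    run((100, 0.1, 2, 18, 75), presets.reduced, short_comp=True,
        turgor_initial=100e3, target_moisture=0.1)
    run((300, 0.1, 2, 18, 75), presets.reduced, short_comp=True,
        turgor_initial=300e3, target_moisture=0.1)
    run((200, 1.0, 2, 0.18, 75), presets.reduced, wall_shear_modulus=0.18e6)
    # compression-rate run: match the 2 m/s plate displacement (not its
    # duration) and record densely enough to resolve impact peaks
    fast = presets.reduced(plate_speed=10.0)
    _fresh(fast)
    fast.n_steps_compression //= 5
    fast.output_every = max(1, fast.output_every // 5)
    out[(200, 1.0, 10, 18, 75)] = run_experiment(fast, seed=1)
    # cell-size pair at the coarse resolution
    run((200, 1.0, 2, 18, 75, "L2"), presets.coarse)
    big = dict(cell_radius=100e-6, fluid_mass_total=None,
               wall_mass_total=0.1 * 4.18879e-12 * 1000)
    run((200, 1.0, 2, 18, 100, "L2"), presets.coarse, **big)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
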