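import numpy as np
import pytest

import flypref as fp


@pytest.fixture(scope="session")
def arena():
    """Standard 76 mm arena at 10 fps."""
    return fp.ArenaConfig(duration=12.0, frames_per_second=10)


@pytest.fixture(scope="session")
def synthetic_video(arena):
    """A 15-fly, 120-frame synthetic recording with side-dependent speeds
    (locomotion suppression on sugar), rendering noise, and ground truth.

    Session-scoped: shared by the tracker-accuracy tests.
    """
    dynamics = fp.AgentDynamics(
        k_sin=0.1,
        k_sout=0.05,
        k_win=0.0001,
        k_wout=0.1,
        speed_sugar=3.0,
        speed_water=8.0,
        turn_sd=30.0,
        seed=11,
    )
    truth = fp.simulate_agents(dynamics, arena, 15)
    frames, background = fp.render_frames(truth, arena, noise_sd=4.0, seed=12)
    return truth, frames, background


@pytest.fixture(scope="session")
def tracked_video(synthetic_video, arena):
    """Full tracker output on the shared synthetic recording."""
    truth, frames, background = synthetic_video
    detections, steps, exclusions = fp.track_frames(frames, background, arena)
    return truth, detections, steps, exclusions


def render_single_fly(x_mm=0.0, y_mm=0.0, orientation=30.0, arena_cfg=None, **kw):
    """One noiseless frame with a single fly at a known pose."""
    import pandas as pd

    cfg = arena_cfg or fp.ArenaConfig(duration=0.1, frames_per_second=10)
    truth = pd.DataFrame(
        {
            "frame": [0],
            "id": [0],
            "x_mm": [x_mm],
            "y_mm": [y_mm],
            "orientation_deg": [orientation],
            "state": ["free_walk"],
            "side": ["sugar" if x_mm > 0 else "water"],
        }
    )
    frames, background = fp.render_frames(truth, cfg, noise_sd=0.0, seed=0, **kw)
    return truth, frames[0], background, cfg
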