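import numpy as np
import pytest

from tubekin import GeneratorConfig, RenderConfig, generate_cell, render_tube_stack
from tubekin import tracking as trk
from tubekin.synthetic import true_cycles


@pytest.fixture(scope="session")
def oscillatory_stack():
    """One rendered oscillatory tube tracked end to end (shared across tests)."""
    cfg = GeneratorConfig(seed=5, n_cycles=6, noise_sd=0.0,
                          lambda_cv=0.08, vhat_cv=0.08)
    profile, series = generate_cell(cfg)
    width = int(np.trapezoid(series.v, series.t) / 0.1339) + 180
    render = RenderConfig(image_size=(160, width), seed=0)
    stack, truth_pos = render_tube_stack(series, render)
    initial = trk.auto_initial_outline(stack[0])
    outlines = trk.track_outline(stack, initial)
    axis = trk.growth_axis_and_pole(outlines)
    velocity = trk.tip_velocity_series(outlines, axis, render.pixel_scale,
                                       render.frame_interval)
    return {
        "config": cfg,
        "render": render,
        "profile": profile,
        "series": series,
        "truth_cycles": true_cycles(profile),
        "truth_positions": truth_pos,
        "stack": stack,
        "outlines": outlines,
        "axis": axis,
        "velocity": velocity,
    }


@pytest.fixture(scope="session")
def constant_stack():
    """Constant-growth rendered stack (apex ≈ 1.94 px/frame)."""
    from tubekin.records import VelocityTimeSeries

    render = RenderConfig(image_size=(160, 320), seed=0)
    t = np.arange(60) * 2.0
    series = VelocityTimeSeries(t, np.full(60, 0.13), 2.0)
    stack, truth = render_tube_stack(series, render)
    return {"render": render, "series": series, "stack": stack, "truth": truth}
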