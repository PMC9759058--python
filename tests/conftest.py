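import numpy as np
import pytest

from alveotrack import FrameStats, SyntheticConfig, generate_scene


def make_stats(alveolar_pct, **overrides):
    """FrameStats series with a prescribed alveolar-area signal."""
    defaults = dict(alveoli_count=4, airspace_per_alveolus_pct=0.0,
                    neutrophil_count=3, neutrophil_area_pct=1.0,
                    interstitial_area_pct=80.0)
    defaults.update(overrides)
    return [
        FrameStats(frame_index=i, alveolar_area_pct=float(v),
                   **{k: (vv(i) if callable(vv) else vv)
                      for k, vv in defaults.items()})
        for i, v in enumerate(alveolar_pct)
    ]


def sine_stats(n=64, period=16, mean=10.0, amplitude=5.0, **overrides):
    """Noiseless sinusoidal breathing signal: mean + A*sin(2*pi*t/period)."""
    t = np.arange(n)
    return make_stats(mean + amplitude * np.sin(2 * np.pi * t / period),
                      **overrides)


@pytest.fixture(scope="session")
def small_scene():
    """A small noiseless scene shared by I/O and pipeline tests."""
    cfg = SyntheticConfig(height=160, width=160, n_frames=32,
                          breathing_period=8, n_alveoli=3,
                          alveolus_radius_range=(10.0, 14.0),
                          n_neutrophils=2, n_transients=3,
                          noise_sigma=0.0, seed=7)
    inter, neut, truth = generate_scene(cfg)
    return cfg, inter, neut, truth
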