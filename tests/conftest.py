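import dataclasses

import numpy as np
import pytest

from tribesim import WorldConfig, get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return WorldConfig()


def disable_invention(config: WorldConfig) -> WorldConfig:
    params = {c: dataclasses.replace(p, invention_rate=0.0)
              for c, p in config.meme_params.items()}
    return config.replace(meme_params=params)


def scaled_config(preset_name: str, seed: int, *, invention_rate: float,
                  years: int, r_env: float = 900.0, n0: int = 120,
                  useless_mean_eff: float | None = None) -> WorldConfig:
    """Desk-scale variant of a full-scale preset: smaller environment
    (smaller population), faster invention, shorter horizon.  Used by the
    scaled qualitative checks of the long-run cultural dynamics."""
    cfg = get_preset(preset_name).config
    params = {}
    for cat, p in cfg.meme_params.items():
        if p.enabled:
            p = dataclasses.replace(p, invention_rate=invention_rate)
        if useless_mean_eff is not None and cat == "Useless":
            p = dataclasses.replace(p, mean_eff=useless_mean_eff)
        params[cat] = p
    return cfg.replace(meme_params=params, R_env=r_env, years=years,
                       seed=seed, initial_population=n0)
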