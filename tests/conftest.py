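import numpy as np
import pandas as pd
import pytest

from mircombo.synth import SynthConfig, gen_de_studies


@pytest.fixture
def small_cfg() -> SynthConfig:
    return SynthConfig(seed=7, n_genes=1200, n_sequences=8, n_patients=80)


@pytest.fixture(scope="session")
def de_dataset():
    """One medium synthetic DE dataset shared across read-only tests."""
    cfg = SynthConfig(seed=42, n_genes=3000)
    studies, target_map, truth = gen_de_studies(cfg)
    return cfg, studies, target_map, truth


def toy_curves(values: dict[str, list[float]], time_h: float = 120.0) -> pd.DataFrame:
    """Single-timepoint curve table from replicate endpoint values per arm."""
    rows = []
    for arm, vals in values.items():
        for rep, v in enumerate(vals, start=1):
            rows.append(
                {"arm": arm, "replicate": rep, "time_h": time_h, "signal": v}
            )
    return pd.DataFrame(rows)
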