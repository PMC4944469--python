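import numpy as np
import pytest

from lactscale.pattern_features import IntakePattern
from lactscale.synthetic_data import SimulationConfig, simulate_dataset


def make_pattern(times, mei, pattern_id="p1", species="Mus musculus", breed="b1",
                 diet=12.0, mass=0.03, mass_onset=None):
    return IntakePattern(
        pattern_id=pattern_id,
        species=species,
        breed=breed,
        times=np.asarray(times, float),
        mei=np.asarray(mei, float),
        diet_me_density=diet,
        mass_peak_kg=mass,
        mass_onset_kg=mass if mass_onset is None else mass_onset,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """12-species noisy dataset shared by the regression tests."""
    cfg = SimulationConfig(n_species=12, seed=42)
    patterns, tree, truth = simulate_dataset(cfg)
    return patterns, tree, truth, cfg


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free dataset (no observation noise, no random effects)."""
    cfg = SimulationConfig(
        n_species=10,
        seed=7,
        obs_noise_cv=0.0,
        sigma_phylo=0.0,
        sigma_breed=0.0,
        sigma_resid=0.0,
        fold_sigma=0.0,
        sigma_ttp=0.0,
    )
    patterns, tree, truth = simulate_dataset(cfg)
    return patterns, tree, truth, cfg
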