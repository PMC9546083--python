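import numpy as np
import pytest

from prepost_ma.data_model import Arm, MetaDataset, TrialArmSummary, as_complete
from prepost_ma.pseudo_ipd import generate_dataset
from prepost_ma.synthetic import aggregate_ipd, simulate_ipd


def toy_control() -> TrialArmSummary:
    # sd_CS^2 = 4 + 4 - 2*0.5*2*2 = 4
    return TrialArmSummary(
        trial_id="toy", arm=Arm.control, n=4,
        mean_B=10.0, sd_B=2.0, mean_F=12.0, sd_F=2.0,
        mean_CS=2.0, sd_CS=2.0, r=0.5,
    )


def toy_treatment() -> TrialArmSummary:
    return TrialArmSummary(
        trial_id="toy", arm=Arm.treatment, n=4,
        mean_B=11.0, sd_B=2.0, mean_F=11.0, sd_F=2.0,
        mean_CS=0.0, sd_CS=2.0, r=0.5,
    )


@pytest.fixture
def toy_trial():
    """Closed-form ANCOVA example: beta=0.5, theta=-1.5, variance=1.95."""
    return toy_control(), toy_treatment()


@pytest.fixture
def toy_dataset():
    return as_complete(MetaDataset([toy_control(), toy_treatment()]))


@pytest.fixture(scope="session")
def complete_ds():
    """A 5-trial complete dataset with baseline imbalance."""
    sim = simulate_ipd(k=5, n_per_arm=30, seed=42, baseline_imbalance_sd=1.0)
    return aggregate_ipd(sim)


@pytest.fixture(scope="session")
def complete_ds9():
    """A 9-trial complete dataset (varied arm sizes)."""
    sim = simulate_ipd(k=9, n_per_arm=(20, 60), seed=7, baseline_imbalance_sd=0.8,
                       tau2=0.1)
    return aggregate_ipd(sim)


@pytest.fixture(scope="session")
def pseudo_5(complete_ds):
    return generate_dataset(complete_ds, seed=123)


def random_arm_summaries(rng: np.random.Generator, n_min: int = 4, n_max: int = 60):
    """A random internally-consistent (control, treatment) pair."""
    rows = []
    for arm in (Arm.control, Arm.treatment):
        n = int(rng.integers(n_min, n_max))
        mean_B = float(rng.uniform(-5, 25))
        sd_B = float(rng.uniform(0.3, 4.0))
        mean_F = mean_B + float(rng.uniform(-3, 3))
        sd_F = float(rng.uniform(0.3, 4.0))
        r = float(rng.uniform(-0.9, 0.95))
        mean_CS = mean_F - mean_B
        sd_CS = float(np.sqrt(sd_B**2 + sd_F**2 - 2 * r * sd_B * sd_F))
        rows.append(
            TrialArmSummary(
                trial_id="t", arm=arm, n=n,
                mean_B=mean_B, sd_B=sd_B, mean_F=mean_F, sd_F=sd_F,
                mean_CS=mean_CS, sd_CS=sd_CS, r=r,
            )
        )
    return tuple(rows)
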