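import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import twinmeth as tm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> tm.Cohort:
    """A full-featured small cohort shared by read-only tests."""
    cfg = tm.SimulationConfig(
        seed=11,
        n_probes=1200,
        n_blacklist=60,
        n_snp_artifact=5,
        planted_dmrs=(
            tm.PlantedDmr(10, "asd", 0.08),
            tm.PlantedDmr(11, "combined", -0.05),
        ),
        planted_private=(tm.PlantedPrivate(20, "P02", 0.25),),
        planted_trait_loci=(tm.PlantedTraitLocus(30, "total", 0.44),),
        extreme_pair=True,
        extreme_probe_indices=tuple(range(40, 50)),
    )
    return tm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    return tm.preprocess(small_cohort.signals, small_cohort.manifest)


def noiseless_config(seed=1, n_probes=50, **kwargs) -> tm.SimulationConfig:
    defaults = dict(
        seed=seed,
        n_probes=n_probes,
        n_pairs_discordant_asd=3,
        n_pairs_concordant_asd=1,
        n_pairs_discordant_social=1,
        n_pairs_discordant_rrbi=1,
        n_pairs_discordant_communication=1,
        n_pairs_concordant_unaffected=2,
        between_pair_sd=0.0,
        within_pair_noise_sd=0.0,
        n_blacklist=0,
        n_snp_artifact=0,
        detection_failure_rate=0.0,
    )
    defaults.update(kwargs)
    return tm.SimulationConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def beta_from_signals(signals: tm.SignalSet) -> pd.DataFrame:
    beta, _ = tm.compute_beta(signals.methylated, signals.unmethylated)
    return beta
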