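import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic experiment shared by integration-level tests.

    3 backgrounds x 2 regimes x 2 replicates, 4,000 SNPs with planted
    selection classes on a mildly differentiated ancestral pool.
    """
    from evorepeat.synth import (ExperimentDesign, assign_architecture,
                                 draw_ancestral_frequencies,
                                 generate_experiment)

    design = ExperimentDesign()
    n = 4000
    pool = draw_ancestral_frequencies(n, 3, differentiation=0.05, seed=11,
                                      backgrounds=design.backgrounds)
    arch = assign_architecture(
        n, {"SP": 0.01, "AP": 0.01, "PrivateCold": 0.02, "PrivateHot": 0.02},
        s_magnitude=0.1, seed=12)
    return generate_experiment(design, pool, arch, trait_noise=0.2, seed=13)


@pytest.fixture(scope="session")
def small_detection(small_experiment):
    import evorepeat.io as io
    import evorepeat.pipeline as pipeline

    cfg = io.PipelineConfig(seed=5)
    det = pipeline.detect_stage(small_experiment.snp_panel,
                                small_experiment.design_table, cfg)
    return cfg, det


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
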