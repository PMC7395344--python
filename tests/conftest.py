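import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ehrpheno import GeneratorConfig, PipelineConfig, generate_cohort
from ehrpheno.nlp_engine import build_lexicon
from ehrpheno.pipeline import run_all

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-patient synthetic cohort with planted truth."""
    config = GeneratorConfig(n_patients=2000, rng_seed=42)
    dataset, truth = generate_cohort(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A complete pipeline run (n=2000) with all written artifacts."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig()
    config.generator.n_patients = 2000
    config.generator.rng_seed = 42
    run_all(config, outdir)
    return config, outdir


def load_csv(outdir, name, **kw):
    kw.setdefault("dtype", {"patient_id": str, "case_id": str, "control_id": str})
    if name == "phenotypes.csv":
        kw.setdefault("keep_default_na", False)
    return pd.read_csv(outdir / name, **kw)
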