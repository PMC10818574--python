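import pytest
from hypothesis import HealthCheck, settings

from evoo_nvs import (
    FattyAcidProfile,
    OilSample,
    QualityIndices,
    SensoryAssessment,
    default_config,
    default_curves,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Mid-range, comfortably conforming values for every field.
_DEFAULTS = dict(
    free_acidity=0.25, peroxide_value=6.0, k232=1.80, k270=0.14, delta_k=None,
    oleic=75.0, palmitic=12.0, stearic=2.5, linoleic=7.5, linolenic=0.6,
    palmitoleic=1.0,
    phenolics_total=400.0, tocopherols_total=250.0,
    fruity_median=3.0, defect_median=0.0,
)


def build_sample(sample_id: str = "s1", **overrides) -> OilSample:
    """A conforming sample at interior values, overridable per field."""
    v = dict(_DEFAULTS)
    unknown = set(overrides) - set(v)
    if unknown:
        raise KeyError(f"unknown overrides: {unknown}")
    v.update(overrides)
    sensory = None
    if v["fruity_median"] is not None or v["defect_median"] is not None:
        sensory = SensoryAssessment(
            fruity_median=v["fruity_median"], defect_median=v["defect_median"]
        )
    return OilSample(
        sample_id=sample_id,
        fatty_acids=FattyAcidProfile(
            oleic=v["oleic"], palmitic=v["palmitic"], stearic=v["stearic"],
            linoleic=v["linoleic"], linolenic=v["linolenic"],
            palmitoleic=v["palmitoleic"],
        ),
        quality=QualityIndices(
            free_acidity=v["free_acidity"], peroxide_value=v["peroxide_value"],
            k232=v["k232"], k270=v["k270"], delta_k=v["delta_k"],
        ),
        phenolics_total=v["phenolics_total"],
        tocopherols_total=v["tocopherols_total"],
        sensory=sensory,
    )


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def curves(config):
    return default_curves(config)


@pytest.fixture
def make_sample():
    return build_sample
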