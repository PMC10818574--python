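"""Versioned legal-limit tables for the EVOO commercial category.

The conformity gate compares a sample against a :class:`LegalLimitTable`.
Limits are packaged as data (``data/legal_limits.yaml``) rather than being
hard-coded, because EU regulations revise them periodically; alternative
versions can be loaded from user-supplied YAML files of the same shape.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class LegalLimitTable(BaseModel):
    """Parameter -> closed ``[low, high]`` interval, plus the sensory gate.

    Boundary values conform: a free acidity of exactly 0.80 % is still EVOO.
    """

    model_config = ConfigDict(frozen=True)

    version: str
    limits: dict[str, tuple[float, float]]
    fruity_median_min_exclusive: float = 0.0
    defect_median_exact: float = 0.0

    def interval(self, parameter: str) -> tuple[float, float]:
        return self.limits[parameter]

    def __contains__(self, parameter: str) -> bool:
        return parameter in self.limits


def _from_mapping(raw: dict) -> LegalLimitTable:
    sensory = raw.get("sensory", {})
    return LegalLimitTable(
        version=str(raw["version"]),
        limits={k: (float(v[0]), float(v[1])) for k, v in raw["limits"].items()},
        **sensory,
    )


@lru_cache(maxsize=None)
def default_limits() -> LegalLimitTable:
    """The packaged EU limit table (version ``eu-2022``)."""
    text = resources.files("evoo_nvs").joinpath("data/legal_limits.yaml").read_text()
    return _from_mapping(yaml.safe_load(text))


def load_limits(path: str | Path) -> LegalLimitTable:
    """Load a limit table from a YAML file with the packaged schema."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))
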