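"""Packaged institutional fixtures.

The package ships the published institutional inputs as plain-text data
files: the 264-case free-flap registry (expanded to one row per case from
the published per-type counts, with the five flap losses flagged among the
thrombotic cases), the 13 matched billing pairs, the 9-condition
thrombophilia panel, and the cohort assumptions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .panel import ModelParams, Panel, read_panel_csv, read_params_yaml
from .registry import CostPair, FlapRecord, read_cost_pairs_csv, read_registry_csv

__all__ = [
    "load_registry",
    "load_cost_pairs",
    "load_panel",
    "load_params",
    "data_path",
]

_FILES = {
    "registry": "institutional_registry.csv",
    "cost_pairs": "billing_pairs.csv",
    "panel": "thrombophilia_panel.csv",
    "params": "cohort_params.yaml",
}


def data_path(key: str) -> Path:
    """Filesystem path of a packaged fixture (registry/cost_pairs/panel/params)."""
    return Path(resources.files("thromboflap") / "data" / _FILES[key])


def load_registry() -> list[FlapRecord]:
    """The 264-case institutional free-flap registry."""
    return read_registry_csv(data_path("registry"))


def load_cost_pairs() -> list[CostPair]:
    """The 13 matched complicated/uncomplicated billing pairs."""
    return read_cost_pairs_csv(data_path("cost_pairs"))


def load_panel() -> Panel:
    """The 9-condition thrombophilia panel."""
    return read_panel_csv(data_path("panel"))


def load_params() -> ModelParams:
    """The default cohort assumptions."""
    return read_params_yaml(data_path("params"))
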