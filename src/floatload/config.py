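"""Package defaults: calibrated trait values and physical constants.

The shipped ``defaults.yaml`` carries calibrated stand-in values for the
Water Hyacinth trait synthesis (dry biomass per cover area, tissue N and P
fractions) together with their relative standard errors and study counts.
They reproduce the published per-area nutrient densities; a user trait CSV
passed through :func:`floatload.budget.synthesize_traits` overrides them.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

from .budget import TraitSynthesis

__all__ = ["load_defaults", "default_trait_syntheses"]


def load_defaults(path: str | None = None) -> dict[str, Any]:
    """Load the default configuration, from ``path`` or the packaged YAML."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("floatload").joinpath("data/defaults.yaml")
    return yaml.safe_load(ref.read_text())


def default_trait_syntheses(path: str | None = None) -> dict[str, TraitSynthesis]:
    """Trait syntheses built from the default (or a user) YAML config."""
    cfg = load_defaults(path)
    out = {}
    for trait, params in cfg["traits"].items():
        mean = float(params["mean"])
        out[trait] = TraitSynthesis(
            trait=trait,
            mean=mean,
            se=float(params["rel_se"]) * mean,
            n_studies=int(params["n_studies"]),
        )
    return out
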