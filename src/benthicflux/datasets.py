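"""Packaged summary data used as default budget inputs and preset anchors."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def field_summary() -> dict:
    """Published field-study summary table (cumulative fluxes, budgets)."""
    ref = resources.files("benthicflux.data") / "field_summary.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
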