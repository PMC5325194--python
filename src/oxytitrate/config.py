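"""Configuration: distribution overrides from a YAML/JSON key-value file."""

from __future__ import annotations

from pathlib import Path

import yaml

from .patient_model import CohortDistributions, default_distributions

_ALLOWED_KEYS = {
    "v0_support", "v0_probs", "duration_support",
    "duration_probs", "profile_probs", "k",
}


def distributions_from_mapping(overrides: dict | None) -> CohortDistributions:
    """Apply overrides to the default distributions; reject unknown keys."""
    base = default_distributions().to_dict()
    if overrides:
        unknown = sorted(set(overrides) - _ALLOWED_KEYS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        base.update(overrides)
    return CohortDistributions(**base)


def load_distributions(path: str | Path | None) -> CohortDistributions:
    """Load distribution overrides from a YAML (or JSON) file.

    A missing path returns the defaults. YAML is a superset of JSON, so either
    dialect parses.
    """
    if path is None:
        return default_distributions()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a key-value mapping")
    return distributions_from_mapping(data)
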