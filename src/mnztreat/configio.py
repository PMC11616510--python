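"""YAML run-configuration loading.

Layout::

    reactor:
      length_m: 1.6
      n_cells: 16
      porosity: 0.48
      dispersivity_m: 0.0
      initial_sorbent_g_per_l: 1.0
      sorbent_growth: true
    params:
      k1_per_s: 1.03e-4
      km_per_s: 3.175e-3
      kd_l_per_g: 4.49
      k2: 0.0
    run:
      hrt_a1_days: 0.5
      duration_days: 30
      inlet_mn_mg_l: 19.0
      inlet_zn_mg_l: 8.0

Missing sections fall back to the package defaults.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from .exceptions import SchemaError
from .transport import KineticParameters, ReactorConfig

_REACTOR_KEYS = {
    "length_m": "length_m", "n_cells": "n_cells", "porosity": "porosity",
    "dispersivity_m": "dispersivity_m",
    "initial_sorbent_g_per_l": "initial_sorbent_g_per_l",
    "sorbent_growth": "sorbent_growth",
    "mno2_molar_mass": "mno2_molar_mass",
}
_PARAM_KEYS = {"k1_per_s": "k1", "km_per_s": "km", "kd_l_per_g": "kd", "k2": "k2"}


def load_config(path):
    """Return ``(ReactorConfig, KineticParameters, run: dict, sha256 hex)``."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    for section in doc:
        if section not in ("reactor", "params", "run"):
            raise SchemaError(f"{path}: unknown section {section!r}")

    def pick(section, mapping):
        raw = doc.get(section) or {}
        unknown = set(raw) - set(mapping)
        if unknown:
            raise SchemaError(f"{path}: unknown keys in {section}: {sorted(unknown)}")
        return {mapping[k]: v for k, v in raw.items()}

    reactor = ReactorConfig(**pick("reactor", _REACTOR_KEYS))
    params = KineticParameters(**pick("params", _PARAM_KEYS))
    run = dict(doc.get("run") or {})
    digest = hashlib.sha256(text.encode()).hexdigest()
    return reactor, params, run, digest
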