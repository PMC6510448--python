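"""Loading of shipped and user model-parameter files.

The bundled reference systems are synthetic stand-ins (see the data file's
header): bistable exemplars constructed to realise the qualitative regimes
the analysis operates on, at the default scales Y = 15, Z = 5.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml

from .er_model import ERParams
from .grn_model import GRNParams

__all__ = ["load_reference_systems", "reference_er_params", "reference_grn_params", "load_model_file"]


def _reference_raw() -> dict:
    ref = importlib.resources.files("epigrn.data").joinpath("reference_systems_synthetic.yaml")
    return yaml.safe_load(ref.read_text())


def _er_from_dict(raw: dict, name: str, **over) -> ERParams:
    scales = dict(raw["er_scales"])
    scales.update(over)
    return ERParams(c=np.asarray(raw["er_systems"][name]["c"], dtype=float), **scales)


def load_reference_systems(**over) -> dict[str, ERParams]:
    raw = _reference_raw()
    return {name: _er_from_dict(raw, name, **over) for name in raw["er_systems"]}


def reference_er_params(name: str, **over) -> ERParams:
    """One of the shipped synthetic exemplars: reference, ders1, ders2, pers1, pers2."""
    return _er_from_dict(_reference_raw(), name, **over)


def reference_grn_params(**over) -> GRNParams:
    raw = _reference_raw()["grn"]
    raw = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v) for k, v in raw.items()}
    raw.update(over)
    return GRNParams(**raw)


def load_model_file(path) -> dict:
    """Load a user model-definition file (same schema as the shipped one)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict = {"er_systems": {}, "grn": None}
    if "er_systems" in raw:
        for name in raw["er_systems"]:
            out["er_systems"][name] = _er_from_dict(raw, name)
    if "grn" in raw:
        g = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v) for k, v in raw["grn"].items()}
        out["grn"] = GRNParams(**g)
    return out
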