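"""Reading and writing parameter files.

Flat JSON or YAML keyed by the model's symbol names.  Metabolic keys are
top-level (``c0`` ... ``c14``, ``T1`` ... ``T10``, ``V``, ``K``,
``DMI``); reproductive parameters live under the ``bovcycle`` mapping
(e.g. ``bovcycle: {T_foll_fsh: 1.497}``), with recalibration toggles
under ``bovcycle.table7`` (``reference: [names]`` reverts the named
parameters to their reference-model values).  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

from .metabolic import MetabolicParams
from .reproductive import ReproductiveParams

__all__ = ["load_params", "dump_params"]


def _load_raw(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


def load_params(path) -> tuple[MetabolicParams, ReproductiveParams]:
    """Load a parameter override file on top of the defaults."""
    raw = _load_raw(path)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    bov = raw.pop("bovcycle", {}) or {}
    mnames = {f.name for f in fields(MetabolicParams)}
    unknown = set(raw) - mnames
    if unknown:
        raise KeyError(f"{path}: unknown metabolic keys {sorted(unknown)}")
    mparams = MetabolicParams(**{k: float(v) for k, v in raw.items()})

    table7 = bov.pop("table7", {}) or {}
    rnames = {f.name for f in fields(ReproductiveParams)}
    unknown = set(bov) - rnames
    if unknown:
        raise KeyError(f"{path}: unknown bovcycle keys {sorted(unknown)}")
    rparams = ReproductiveParams(**{k: float(v) for k, v in bov.items()})
    ref = table7.pop("reference", None)
    if table7:
        raise KeyError(f"{path}: unknown table7 keys {sorted(table7)}")
    if ref:
        rparams = rparams.with_reference_values(
            None if ref is True or ref == "all" else list(ref))
    return mparams, rparams


def dump_params(mparams: MetabolicParams, rparams: ReproductiveParams,
                path) -> None:
    """Write the full parameter set as flat JSON (or YAML by suffix)."""
    doc = {f.name: getattr(mparams, f.name) for f in fields(MetabolicParams)}
    doc["bovcycle"] = {f.name: getattr(rparams, f.name)
                       for f in fields(ReproductiveParams)}
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))
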