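"""Run/analysis configuration loading (TOML preferred, YAML accepted).

Cutoff-style lengths given in Å in config files (keys ending ``_angstrom``)
are converted to nm once here, at the boundary.
"""

from __future__ import annotations

from pathlib import Path

from ..units import ANGSTROM_TO_NM

__all__ = ["load_config"]


def load_config(path) -> dict:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        with path.open("rb") as fh:
            cfg = tomllib.load(fh)
    elif suffix in (".yaml", ".yml"):
        import yaml

        with path.open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        raise ValueError(f"unsupported config format {suffix!r} (use TOML or YAML)")
    return _convert_units(cfg)


def _convert_units(obj):
    if isinstance(obj, dict):
        out = {}
        for key, val in obj.items():
            if key.endswith("_angstrom") and isinstance(val, (int, float)):
                out[key[: -len("_angstrom")] + "_nm"] = val * ANGSTROM_TO_NM
            else:
                out[key] = _convert_units(val)
        return out
    if isinstance(obj, list):
        return [_convert_units(v) for v in obj]
    return obj
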