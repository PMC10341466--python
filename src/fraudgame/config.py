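"""Reading parameter sets from flat key-value files.

A parameter file is YAML (JSON is a YAML subset and also accepted) whose
top level maps exactly the sixteen parameter symbol names to numbers::

    Ch1: 8
    Ch2: 5
    ...
    Pg: 3

Unknown keys are rejected so a typo cannot silently become a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .game_model import ParameterSet

__all__ = ["load_parameters", "dump_parameters"]


def load_parameters(path: str | Path) -> ParameterSet:
    """Parse a YAML/JSON parameter file into a :class:`ParameterSet`."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(
            f"parameter file {path} must contain a flat key-value mapping, "
            f"got {type(data).__name__}"
        )
    return ParameterSet.from_mapping(data)


def dump_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a flat YAML mapping."""
    Path(path).write_text(yaml.safe_dump(params.as_dict(), sort_keys=False))
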