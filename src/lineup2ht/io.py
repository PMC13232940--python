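"""Reading and writing the package's file formats.

Frequency CSV (UTF-8, header row)::

    condition,lineup_type,response,count
    combined,culprit_present,suspect,284
    ...

with ``lineup_type`` in {culprit_present, culprit_absent} and ``response``
in {suspect, filler, rejection}. Validation is strict: unknown labels,
negative or non-integer counts, and duplicate rows are rejected with the
offending line number.

Model configuration YAML::

    conditions: [combined, separate]
    guess_split_c: 0.16667
    equalities:
      b: all            # or a list of condition groups
      dA: all
    fixed: {}           # optional: {param: {condition: value}}

Design YAML for the simulator mirrors :class:`~lineup2ht.simulate.DesignSpec`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .estimation import FrequencyData
from .model import DEFAULT_GUESS_SPLIT, ModelSpec, Params2HT, TreeKind, build_model
from .simulate import ConditionDesign, DesignSpec

__all__ = [
    "load_frequencies",
    "write_frequencies",
    "load_model_config",
    "load_design_config",
]

_RESPONSES = ("suspect", "filler", "rejection")
_LINEUP_TYPES = tuple(t.value for t in TreeKind)


def load_frequencies(path: str | Path) -> FrequencyData:
    """Read a frequency CSV, validating schema and labels strictly."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["condition", "lineup_type", "response", "count"]
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    counts: dict[tuple[str, TreeKind], np.ndarray] = {}
    seen: set[tuple[str, str, str]] = set()
    for pos, row in frame.iterrows():
        line = pos + 2  # header is line 1
        cond = row["condition"].strip()
        lineup = row["lineup_type"].strip()
        response = row["response"].strip()
        if not cond:
            raise ValueError(f"{path}:{line}: empty condition label")
        if lineup not in _LINEUP_TYPES:
            raise ValueError(
                f"{path}:{line}: unknown lineup_type {lineup!r} "
                f"(expected one of {_LINEUP_TYPES})"
            )
        if response not in _RESPONSES:
            raise ValueError(
                f"{path}:{line}: unknown response {response!r} "
                f"(expected one of {_RESPONSES})"
            )
        key3 = (cond, lineup, response)
        if key3 in seen:
            raise ValueError(f"{path}:{line}: duplicate row for {key3}")
        seen.add(key3)
        try:
            n = int(row["count"])
        except ValueError:
            raise ValueError(
                f"{path}:{line}: count {row['count']!r} is not an integer"
            ) from None
        if n < 0:
            raise ValueError(f"{path}:{line}: negative count {n}")
        tree = TreeKind(lineup)
        cell = counts.setdefault((cond, tree), np.zeros(3, dtype=np.int64))
        cell[_RESPONSES.index(response)] = n
    if not counts:
        raise ValueError(f"{path}: no data rows")
    return FrequencyData(counts)


def write_frequencies(data: FrequencyData, path: str | Path) -> None:
    """Write a :class:`FrequencyData` to the standard CSV schema."""
    rows = []
    for (cond, tree), cell in data.counts.items():
        for response, n in zip(_RESPONSES, cell):
            rows.append(
                {
                    "condition": cond,
                    "lineup_type": tree.value,
                    "response": response,
                    "count": int(n),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_model_config(path: str | Path) -> ModelSpec:
    """Build a :class:`ModelSpec` from a YAML configuration file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError(f"{path}: model config must be a mapping")
    unknown = set(config) - {"conditions", "guess_split_c", "equalities", "fixed"}
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "conditions" not in config:
        raise ValueError(f"{path}: config must list 'conditions'")
    return build_model(
        condition_names=list(config["conditions"]),
        equalities=config.get("equalities"),
        fixed_values=config.get("fixed"),
        c=float(config.get("guess_split_c", DEFAULT_GUESS_SPLIT)),
    )


def load_design_config(path: str | Path) -> DesignSpec:
    """Build a simulation :class:`DesignSpec` from a YAML file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "conditions" not in config:
        raise ValueError(f"{path}: design config must map 'conditions'")
    conditions = {}
    for name, entry in config["conditions"].items():
        conditions[name] = ConditionDesign(
            n_participants=int(entry["n_participants"]),
            lineups_present=int(entry["lineups_present"]),
            lineups_absent=int(entry["lineups_absent"]),
            params=Params2HT(**{k: float(v) for k, v in entry["params"].items()}),
        )
    return DesignSpec(
        conditions=conditions,
        seed=int(config.get("seed", 0)),
        guess_split_c=float(config.get("guess_split_c", DEFAULT_GUESS_SPLIT)),
    )
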