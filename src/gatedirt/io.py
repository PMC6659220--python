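"""CSV/config plumbing: response matrices, item metadata, manifests.

All interchange is UTF-8 comma-delimited text with a header row.  A
responses file has ``student_id`` in the first column and one column per
item; an items file has ``item_id``, ``exposed`` and optionally
``difficulty``; a cohort file carries the simulated truth.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import ItemBank, ResponseMatrix, StudentCohort
from .simulate import PAPER_SCENARIOS, ScenarioConfig

__all__ = [
    "read_responses",
    "write_responses",
    "read_item_metadata",
    "write_items",
    "write_cohort",
    "read_cohort",
    "read_scenario_grid",
    "write_manifest",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_responses(path: PathLike) -> ResponseMatrix:
    """Read a binary response matrix from delimited text.

    First column ``student_id``, remaining columns item ids, cells 0/1.
    Non-binary cells and duplicated ids raise with the offending location.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected student_id plus at least one item column")
    sid = df.iloc[:, 0].astype(str).to_numpy()
    body = df.iloc[:, 1:]
    vals = body.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary cell {vals[r, c]!r} at student {sid[r]!r}, "
            f"item {body.columns[c]!r}"
        )
    if len(set(sid)) != sid.size:
        raise ValueError(f"{path}: duplicated student ids")
    if len(set(body.columns)) != body.shape[1]:
        raise ValueError(f"{path}: duplicated item ids")
    rm = ResponseMatrix(
        values=vals.astype(np.int8),
        student_id=sid,
        item_id=body.columns.to_numpy(dtype=str),
    )
    logger.info("read %d students x %d items from %s", rm.n_students, rm.n_items, path)
    return rm


def write_responses(responses: ResponseMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        responses.values, index=responses.student_id, columns=responses.item_id
    )
    df.index.name = "student_id"
    df.to_csv(path)


def read_item_metadata(
    path: PathLike, item_ids: Optional[np.ndarray] = None
) -> ItemBank:
    """Read item metadata (``item_id``, ``exposed``, optional ``difficulty``).

    When ``item_ids`` is given (the response-matrix column order), flags are
    aligned to it; items missing from the metadata raise with their names,
    extra metadata rows are logged and ignored.
    """
    df = pd.read_csv(path)
    required = {"item_id", "exposed"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    df["item_id"] = df["item_id"].astype(str)
    if df["item_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated item ids")
    df = df.set_index("item_id")
    if item_ids is not None:
        item_ids = np.asarray(item_ids, dtype=str)
        missing = [i for i in item_ids if i not in df.index]
        if missing:
            raise ValueError(f"{path}: metadata missing items {missing}")
        extra = [i for i in df.index if i not in set(item_ids)]
        if extra:
            logger.warning("%s: ignoring %d extra metadata rows: %s", path, len(extra), extra)
        df = df.loc[item_ids]
    exposed = df["exposed"].to_numpy()
    if not np.isin(exposed, (0, 1)).all():
        raise ValueError(f"{path}: exposed flags must be 0/1")
    difficulty = (
        df["difficulty"].to_numpy(dtype=float)
        if "difficulty" in df.columns
        else np.zeros(len(df))
    )
    return ItemBank(
        difficulty=difficulty,
        exposed=exposed.astype(int),
        item_id=df.index.to_numpy(dtype=str),
    )


def write_items(items: ItemBank, path: PathLike) -> None:
    pd.DataFrame(
        {
            "item_id": items.item_id,
            "difficulty": items.difficulty,
            "exposed": items.exposed,
        }
    ).to_csv(path, index=False)


def write_cohort(cohort: StudentCohort, path: PathLike) -> None:
    pd.DataFrame(
        {
            "student_id": cohort.student_id,
            "theta_true": cohort.theta_true,
            "theta_cheat": cohort.theta_cheat,
            "gain": cohort.gain,
            "is_cheater": cohort.is_cheater,
        }
    ).to_csv(path, index=False)


def read_cohort(path: PathLike) -> StudentCohort:
    df = pd.read_csv(path)
    return StudentCohort(
        theta_true=df["theta_true"].to_numpy(float),
        theta_cheat=df["theta_cheat"].to_numpy(float),
        gain=df["gain"].to_numpy(float),
        is_cheater=df["is_cheater"].to_numpy(int),
        student_id=df["student_id"].astype(str).to_numpy(),
    )


def read_scenario_grid(path: PathLike) -> list[ScenarioConfig]:
    """Read a scenario grid from YAML or JSON.

    The file holds a mapping with a ``scenarios`` list; each entry is either
    a preset name (e.g. ``"5-high"``) or a mapping of ScenarioConfig fields.
    Top-level ``seed`` and ``n_replicates`` apply to all scenarios unless
    overridden per entry.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenarios" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'scenarios' list")
    defaults = {
        k: cfg[k] for k in ("seed", "n_replicates", "n_students", "n_items", "n_exposed")
        if k in cfg
    }
    out = []
    for entry in cfg["scenarios"]:
        if isinstance(entry, str):
            if entry not in PAPER_SCENARIOS:
                raise ValueError(
                    f"unknown scenario preset {entry!r}; "
                    f"known: {sorted(PAPER_SCENARIOS)}"
                )
            base = PAPER_SCENARIOS[entry]
            fields = {**defaults}
            scen = ScenarioConfig(
                prop_cheaters=base.prop_cheaters, efficacy=base.efficacy, **fields
            )
        else:
            scen = ScenarioConfig(**{**defaults, **entry})
        out.append(scen)
    return out


def write_manifest(path: PathLike, config: dict) -> None:
    """Write a run manifest (config echo, seed, package versions)."""
    import gatedirt

    manifest = {
        "config": config,
        "versions": {
            "gatedirt": gatedirt.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
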