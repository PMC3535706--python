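"""File formats: long-format screen CSV, results TSV/JSON, configs, manifests.

The canonical on-disk screen format is a tidy CSV with one well per row:

    plate,replicate,condition,kind,sirna_id,viability[,truth_label]

``condition`` is treated/untreated, ``kind`` active/control; ``sirna_id``
is empty for control wells; ``truth_label`` is present only for simulated
data.  Validation is strict and every failure names the offending column
or row — screening pipelines should fail loudly, not coerce.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    ACTIVE,
    CONTROL,
    LABEL_ANTAGONIZING,
    LABEL_NON_HIT,
    LABEL_SENSITIZING,
    TREATED,
    UNTREATED,
    ScenarioConfig,
    ScreenDataset,
    ScreenDesign,
    TruthTable,
)

SCREEN_COLUMNS = ("plate", "replicate", "condition", "kind", "sirna_id", "viability")
TRUTH_LABELS = (LABEL_NON_HIT, LABEL_SENSITIZING, LABEL_ANTAGONIZING)

#: YAML/JSON scenario-file keys that belong to the screen design rather
#: than the generative parameters.
_DESIGN_KEYS = ("replicates_per_condition",)


class ScreenValidationError(ValueError):
    """Raised for malformed or inconsistent screen files."""


def read_screen_csv(path) -> ScreenDataset:
    """Read and validate a long-format screen CSV.

    Returns a ScreenDataset; a ``truth_label`` column, if present, becomes
    the truth table (multipliers unknown, set to NaN).  The design is left
    unset — real screens need not follow the default 96-well layout.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sirna_id": str}, keep_default_na=False)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"{path.name}: missing required columns {missing}")

    bad = ~df["condition"].isin([TREATED, UNTREATED])
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header line is row 1
        raise ScreenValidationError(
            f"{path.name} row {row}: unknown condition {df.loc[bad, 'condition'].iloc[0]!r}"
        )
    bad = ~df["kind"].isin([ACTIVE, CONTROL])
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ScreenValidationError(
            f"{path.name} row {row}: unknown kind {df.loc[bad, 'kind'].iloc[0]!r}"
        )
    viability = pd.to_numeric(df["viability"], errors="coerce")
    bad = viability.isna()
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ScreenValidationError(f"{path.name} row {row}: non-numeric viability")
    bad = viability < 0
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ScreenValidationError(
            f"{path.name} row {row}: negative viability {viability[bad].iloc[0]}"
        )
    df["viability"] = viability

    active = df["kind"] == ACTIVE
    if (df.loc[active, "sirna_id"] == "").any():
        row = int(df.index[active & (df["sirna_id"] == "")][0]) + 2
        raise ScreenValidationError(f"{path.name} row {row}: active well without sirna_id")

    # every (plate, replicate, condition) block must carry NS controls
    ctl_blocks = df.loc[~active].groupby(["plate", "replicate", "condition"]).size()
    all_blocks = df.groupby(["plate", "replicate", "condition"]).size()
    missing_blocks = set(all_blocks.index) - set(ctl_blocks.index)
    if missing_blocks:
        raise ScreenValidationError(
            f"{path.name}: plate/replicate/condition blocks without NS controls: "
            f"{sorted(missing_blocks)[:3]}"
        )
    if not ((df["kind"] == CONTROL) & (df["condition"] == UNTREATED)).any():
        raise ScreenValidationError(
            f"{path.name}: no untreated NS controls; normalization is impossible"
        )

    truth = None
    if "truth_label" in df.columns:
        lab = df.loc[active, ["sirna_id", "truth_label"]].drop_duplicates()
        bad_lab = ~lab["truth_label"].isin(TRUTH_LABELS)
        if bad_lab.any():
            raise ScreenValidationError(
                f"{path.name}: unknown truth_label {lab.loc[bad_lab, 'truth_label'].iloc[0]!r}"
            )
        if lab["sirna_id"].duplicated().any():
            dup = lab.loc[lab["sirna_id"].duplicated(), "sirna_id"].iloc[0]
            raise ScreenValidationError(
                f"{path.name}: inconsistent truth_label for siRNA {dup!r}"
            )
        table = lab.rename(columns={"truth_label": "label"}).reset_index(drop=True)
        table = table.sort_values("sirna_id", ignore_index=True)
        table["multiplier"] = np.nan
        truth = TruthTable(table)
        df = df.drop(columns=["truth_label"])

    return ScreenDataset(wells=df.reset_index(drop=True), truth=truth)


def write_screen_csv(screen: ScreenDataset, path, include_truth: bool = True) -> None:
    """Write a ScreenDataset to the canonical long-format CSV."""
    df = screen.wells.loc[:, list(SCREEN_COLUMNS)].copy()
    if include_truth and screen.truth is not None:
        labels = screen.truth.labels
        df["truth_label"] = df["sirna_id"].map(labels).fillna("")
        df.loc[df["kind"] == CONTROL, "truth_label"] = ""
    df.to_csv(path, index=False)


def _round_sig(x, digits=6):
    if isinstance(x, float):
        if not np.isfinite(x):
            return x
        return float(f"{x:.{digits}g}")
    return x


def write_results(results: pd.DataFrame, path, format: str = "tsv", allow_empty: bool = False) -> None:
    """Write a results table byte-stably (floats at 6 significant digits)."""
    if results.empty and not allow_empty:
        raise ValueError("refusing to write an empty results table (pass allow_empty=True)")
    path = Path(path)
    if format == "tsv":
        results.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        records = [
            {k: _round_sig(v) for k, v in rec.items()}
            for rec in results.to_dict(orient="records")
        ]
        path.write_text(json.dumps(records, indent=1, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown results format {format!r}")


def load_scenario_file(path) -> Tuple[ScenarioConfig, ScreenDesign]:
    """Load a scenario config (YAML or JSON) into (ScenarioConfig, ScreenDesign)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ScreenValidationError(f"{path}: scenario file must be a mapping")
    design_kwargs = {k: data.pop(k) for k in list(data) if k in _DESIGN_KEYS}
    valid = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ScreenValidationError(f"{path}: unknown scenario keys {sorted(unknown)}")
    return ScenarioConfig(**data), ScreenDesign(**design_kwargs)


def dump_scenario_file(config: ScenarioConfig, design: ScreenDesign, path) -> None:
    data = dataclasses.asdict(config)
    data["replicates_per_condition"] = design.replicates_per_condition
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    tool_version: str
    command: str
    config_hash: str
    seed: Optional[int]
    timestamp: str
    inputs: list
    outputs: list

    @classmethod
    def create(cls, command: str, config: dict, seed, inputs, outputs):
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            tool_version=__version__,
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")
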