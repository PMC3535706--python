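"""Normalization of raw screen read-outs to untreated NS controls.

Drug-sensitivity screens must not be normalized plate-by-plate against
each plate's own treated level: that removes exactly the treated-versus-
untreated difference the experiment is after.  Instead the whole screen is
divided by one global constant, the mean (or median) viability of the
untreated non-silencing control wells, putting the data on a relative
scale where an untreated control reads ~1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import (
    CONTROL,
    UNTREATED,
    ScenarioConfig,
    ScreenDataset,
    ScreenDesign,
    TruthTable,
)


class NormalizationError(ValueError):
    """Raised when a screen cannot be normalized."""


@dataclass
class NormalizedScreen(ScreenDataset):
    """A ScreenDataset whose viabilities were divided by a global constant."""

    constant: float = 1.0
    center: str = "mean"


def normalize_to_untreated_controls(
    screen: ScreenDataset, center: str = "mean"
) -> NormalizedScreen:
    """Divide every well by the global center of untreated NS-control wells.

    ``center`` is ``"mean"`` or ``"median"``.  The constant is computed over
    all untreated control wells across plates and recorded on the result.
    """
    if center not in ("mean", "median"):
        raise NormalizationError(f"center must be 'mean' or 'median', got {center!r}")
    wells = screen.wells
    mask = (wells["kind"] == CONTROL) & (wells["condition"] == UNTREATED)
    values = wells.loc[mask, "viability"].to_numpy(float)
    if values.size == 0:
        raise NormalizationError(
            "drug-sensitivity normalization requires untreated NS controls on all plates"
        )
    constant = float(np.mean(values) if center == "mean" else np.median(values))
    if not constant > 0:
        raise NormalizationError(
            f"non-positive normalization constant ({constant}); "
            "check the untreated control wells"
        )
    out = wells.copy()
    out["viability"] = out["viability"].to_numpy(float) / constant
    return NormalizedScreen(
        wells=out,
        design=screen.design,
        config=screen.config,
        truth=screen.truth,
        constant=constant,
        center=center,
    )
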