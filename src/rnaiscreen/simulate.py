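"""Plate-based simulation of RNAi drug-sensitivity screens.

The generative model mimics a typical arrayed siRNA viability screen run
with and without a chemotherapeutic drug: ten 96-well plates carry 90
active siRNAs plus 6 non-silencing (NS) control wells each, and the whole
plate set is replicated ``r`` times per condition (treated / untreated).

Per-well viability is drawn around a cell mean built from four multipliers:

* ``mu_nh``   — baseline viability of a non-hit well (relative scale, 1.0);
* ``c1 > 1`` / ``c2 < 1`` — multiplicative shift of true hits (sensitizing /
  antagonizing), applied to the siRNA's mean;
* ``0 < d <= 1`` — drug kill factor applied to every treated well;
* ``k >= 1``  — control wells sit slightly above siRNA-transfected wells.

Noise is either Gaussian with a common standard deviation ``sigma`` or, to
emulate skewed assay read-outs, a gamma distribution that preserves each
cell mean at a requested skewness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

TREATED = "treated"
UNTREATED = "untreated"
ACTIVE = "active"
CONTROL = "control"

LABEL_NON_HIT = "non-hit"
LABEL_SENSITIZING = "sensitizing"
LABEL_ANTAGONIZING = "antagonizing"

#: Qualitative level -> numeric parameter maps used by :func:`make_scenario`.
#: Endpoints of the parameter menus: noise is the per-well SD, drug is the
#: kill multiplier (smaller = stronger kill), RNAi is the (c1, c2) hit pair.
NOISE_LEVELS = {"low": 0.2, "moderate": 0.4, "strong": 0.8}
DRUG_LEVELS = {"strong": 0.3, "moderate": 0.6, "weak": 0.8}
RNAI_LEVELS = {"strong": (7.0, 0.15), "moderate": (2.0, 0.5), "weak": (1.25, 0.8)}

#: The nine representative (noise, drug, rnai) scenarios of the simulation study.
NINE_SCENARIOS = (
    ("low", "strong", "strong"),
    ("moderate", "strong", "strong"),
    ("strong", "strong", "strong"),
    ("low", "moderate", "strong"),
    ("low", "weak", "strong"),
    ("moderate", "weak", "strong"),
    ("strong", "weak", "strong"),
    ("low", "strong", "moderate"),
    ("low", "strong", "weak"),
)

REPLICATE_LEVELS = (3, 6, 9, 12)


class ConfigurationError(ValueError):
    """Raised for invalid scenario or design parameters."""


@dataclass(frozen=True)
class ScreenDesign:
    """Plate/well/replicate layout of one screen.

    ``replicates_per_condition`` is the number of physical plate copies per
    arm: ``r`` treated plus ``r`` untreated replicates of the full plate set.
    """

    n_plates: int = 10
    wells_per_plate: int = 96
    control_wells_per_plate: int = 6
    sirna_wells_per_plate: int = 90
    replicates_per_condition: int = 3

    def __post_init__(self) -> None:
        if self.sirna_wells_per_plate + self.control_wells_per_plate != self.wells_per_plate:
            raise ConfigurationError(
                "sirna_wells_per_plate + control_wells_per_plate must equal wells_per_plate"
            )
        if self.n_plates < 1:
            raise ConfigurationError("n_plates must be >= 1")
        if self.replicates_per_condition < 2:
            raise ConfigurationError(
                "replicates_per_condition must be >= 2 (two-sample statistics need "
                ">= 2 wells per arm)"
            )

    @property
    def n_sirnas(self) -> int:
        return self.n_plates * self.sirna_wells_per_plate


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of one simulation scenario.

    Defaults correspond to the low-noise / strong-drug / strong-RNAi
    scenario on a relative-viability scale (``mu_nh = 1``).
    """

    mu_nh: float = 1.0
    sigma: float = 0.2
    c1: float = 7.0
    c2: float = 0.15
    d: float = 0.3
    k: float = 1.1
    skewness: float = 0.0
    n_hit_low: int = 10
    n_hit_high: int = 60
    n_sims: int = 500
    seed: Optional[int] = None
    hit_effect: str = "both"
    floor_epsilon: Optional[float] = 1e-6

    def __post_init__(self) -> None:
        if not self.mu_nh > 0:
            raise ConfigurationError("mu_nh must be > 0")
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be > 0")
        if not self.c1 > 1:
            raise ConfigurationError("c1 (sensitizing multiplier) must be > 1")
        if not 0 < self.c2 < 1:
            raise ConfigurationError("c2 (antagonizing multiplier) must be in (0, 1)")
        if not 0 < self.d <= 1:
            raise ConfigurationError("d (drug multiplier) must be in (0, 1]")
        if not self.k >= 1:
            raise ConfigurationError("k (control multiplier) must be >= 1")
        if self.skewness < 0:
            raise ConfigurationError("skewness must be >= 0")
        if not 0 <= self.n_hit_low <= self.n_hit_high:
            raise ConfigurationError("need 0 <= n_hit_low <= n_hit_high")
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")
        if self.hit_effect not in ("both", "treated-only"):
            raise ConfigurationError("hit_effect must be 'both' or 'treated-only'")
        if self.floor_epsilon is not None and self.floor_epsilon < 0:
            raise ConfigurationError("floor_epsilon must be >= 0 or None")


@dataclass
class TruthTable:
    """Ground-truth hit labels of a simulated screen.

    One row per siRNA: ``sirna_id``, ``label`` (non-hit / sensitizing /
    antagonizing) and the mean ``multiplier`` applied (1, c1 or c2).
    """

    table: pd.DataFrame

    @property
    def n_true_hits(self) -> int:
        return int((self.table["label"] != LABEL_NON_HIT).sum())

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("sirna_id")["label"]

    def hit_ids(self) -> set:
        mask = self.table["label"] != LABEL_NON_HIT
        return set(self.table.loc[mask, "sirna_id"])


@dataclass
class ScreenDataset:
    """Per-well viability readings of one screen.

    ``wells`` is a long-format frame with columns plate, replicate,
    condition, kind, sirna_id, viability.  ``truth`` is attached for
    simulated data and absent (None) for real screens.
    """

    wells: pd.DataFrame
    design: Optional[ScreenDesign] = None
    config: Optional[ScenarioConfig] = None
    truth: Optional[TruthTable] = None


def draw_n_true_hits(config: ScenarioConfig, rng: np.random.Generator) -> int:
    """Draw the number of true hits uniformly on {n_hit_low, ..., n_hit_high}."""
    if config.n_hit_low > config.n_hit_high:
        raise ConfigurationError("n_hit_low must be <= n_hit_high")
    return int(rng.integers(config.n_hit_low, config.n_hit_high + 1))


def sirna_ids(design: ScreenDesign) -> np.ndarray:
    """Deterministic siRNA identifiers, plate-major (``s0001`` .. ``s0900``)."""
    return np.array([f"s{i + 1:04d}" for i in range(design.n_sirnas)])


def assign_truth(
    n_th: int,
    design: ScreenDesign,
    rng: np.random.Generator,
    config: ScenarioConfig,
) -> TruthTable:
    """Pick ``n_th`` hit siRNAs uniformly without replacement.

    ceil(n_th/2) are labelled sensitizing (multiplier c1) and floor(n_th/2)
    antagonizing (multiplier c2), so both directions carry about the same
    number of true hits.
    """
    total = design.n_sirnas
    if n_th > total:
        raise ConfigurationError(f"n_th={n_th} exceeds the {total} siRNAs in the design")
    ids = sirna_ids(design)
    labels = np.full(total, LABEL_NON_HIT, dtype=object)
    mult = np.ones(total)
    chosen = rng.choice(total, size=n_th, replace=False)
    n_sens = math.ceil(n_th / 2)
    labels[chosen[:n_sens]] = LABEL_SENSITIZING
    mult[chosen[:n_sens]] = config.c1
    labels[chosen[n_sens:]] = LABEL_ANTAGONIZING
    mult[chosen[n_sens:]] = config.c2
    return TruthTable(pd.DataFrame({"sirna_id": ids, "label": labels, "multiplier": mult}))


def cell_mean(kind: str, condition: str, multiplier: float, config: ScenarioConfig) -> float:
    """Expected viability of one well type.

    Active wells: ``mu_nh * multiplier`` untreated and ``mu_nh * multiplier
    * d`` treated (with ``hit_effect='treated-only'`` the multiplier is
    dropped from untreated wells).  NS-control wells: ``mu_nh * k``
    untreated and ``mu_nh * d * k`` treated; the control multiplier is
    always 1.
    """
    mu = config.mu_nh
    if kind == CONTROL:
        base = mu * config.k
    elif kind == ACTIVE:
        if config.hit_effect == "treated-only" and condition == UNTREATED:
            base = mu
        else:
            base = mu * multiplier
    else:
        raise ValueError(f"unknown well kind: {kind!r}")
    if condition == TREATED:
        return base * config.d
    if condition == UNTREATED:
        return base
    raise ValueError(f"unknown condition: {condition!r}")


def gamma_params(
    mu: float,
    skewness: Optional[float] = None,
    sigma: Optional[float] = None,
) -> tuple:
    """Gamma (shape, scale) matching a target mean.

    Exactly one of ``skewness`` and ``sigma`` must be given.  With
    ``skewness`` s the shape is ``r = 4/s**2`` (gamma skewness is
    ``2/sqrt(r)``) and the scale ``mu/r``, so the mean is preserved.  With
    ``sigma`` the first two moments are matched by solving ``mu = r*lambda``
    and ``sigma**2 = r*lambda**2``, giving ``r = mu**2/sigma**2`` and
    ``lambda = sigma**2/mu``.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if (skewness is None) == (sigma is None):
        raise ValueError("give exactly one of skewness or sigma")
    if skewness is not None:
        if skewness <= 0:
            raise ValueError("skewness must be > 0")
        shape = 4.0 / skewness**2
        return shape, mu / shape
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    shape = mu**2 / sigma**2
    return shape, sigma**2 / mu


def _well_means(config: ScenarioConfig, design: ScreenDesign, truth: TruthTable):
    """Cell-mean vector for every well, in the canonical row order.

    Row order: all active wells sorted by (siRNA, condition, replicate)
    with untreated before treated, then all control wells sorted by
    (plate, condition, replicate, control well index).
    """
    r = design.replicates_per_condition
    mult = truth.table["multiplier"].to_numpy()
    mu = config.mu_nh
    unt = mu * (np.ones_like(mult) if config.hit_effect == "treated-only" else mult)
    trt = mu * mult * config.d
    # (S, 2, r): condition-major inside each siRNA
    active = np.stack([np.repeat(unt, r), np.repeat(trt, r)], axis=0)
    active = active.reshape(2, -1, r).transpose(1, 0, 2).ravel()
    n_ctl = design.n_plates * 2 * r * design.control_wells_per_plate
    ctl_means = np.where(
        np.tile(
            np.repeat([0, 1], r * design.control_wells_per_plate), design.n_plates
        )
        == 1,
        mu * config.k * config.d,
        mu * config.k,
    ).astype(float)
    assert ctl_means.size == n_ctl
    return np.concatenate([active, ctl_means])


def _assemble_wells(config, design, truth, values) -> pd.DataFrame:
    r = design.replicates_per_condition
    s = design.n_sirnas
    ids = sirna_ids(design)
    n_active = s * 2 * r
    plate_of_sirna = np.repeat(np.arange(1, design.n_plates + 1), design.sirna_wells_per_plate)

    a_plate = np.repeat(plate_of_sirna, 2 * r)
    a_rep = np.tile(np.arange(1, r + 1), 2 * s)
    a_cond = np.tile(np.repeat([UNTREATED, TREATED], r), s)
    a_id = np.repeat(ids, 2 * r)

    cw = design.control_wells_per_plate
    c_plate = np.repeat(np.arange(1, design.n_plates + 1), 2 * r * cw)
    c_cond = np.tile(np.repeat([UNTREATED, TREATED], r * cw), design.n_plates)
    c_rep = np.tile(np.repeat(np.arange(1, r + 1), cw), 2 * design.n_plates)
    c_id = np.full(c_plate.size, "", dtype=object)

    wells = pd.DataFrame(
        {
            "plate": np.concatenate([a_plate, c_plate]),
            "replicate": np.concatenate([a_rep, c_rep]),
            "condition": np.concatenate([a_cond, c_cond]),
            "kind": np.concatenate(
                [np.full(n_active, ACTIVE), np.full(c_plate.size, CONTROL)]
            ),
            "sirna_id": np.concatenate([a_id, c_id]),
            "viability": values,
        }
    )
    return wells


def _simulate(config: ScenarioConfig, design: ScreenDesign, rng: np.random.Generator) -> ScreenDataset:
    n_th = draw_n_true_hits(config, rng)
    truth = assign_truth(n_th, design, rng, config)
    means = _well_means(config, design, truth)
    if config.skewness == 0:
        values = rng.normal(loc=means, scale=config.sigma)
    else:
        shape = 4.0 / config.skewness**2
        values = rng.gamma(shape, means / shape)
    if config.floor_epsilon is not None:
        values = np.maximum(values, config.floor_epsilon)
    return ScreenDataset(
        wells=_assemble_wells(config, design, truth, values),
        design=design,
        config=config,
        truth=truth,
    )


def simulate_screen(
    config: ScenarioConfig,
    design: Optional[ScreenDesign] = None,
    rng=None,
) -> ScreenDataset:
    """Simulate one full screen (Gaussian noise, or gamma if skewness > 0).

    ``rng`` may be a :class:`numpy.random.Generator`, a seed, or None (in
    which case ``config.seed`` is used).
    """
    design = design or ScreenDesign()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    return _simulate(config, design, rng)


def simulate_screen_gamma(
    config: ScenarioConfig,
    design: Optional[ScreenDesign] = None,
    rng=None,
) -> ScreenDataset:
    """Simulate a skewed (gamma-noise) screen; requires ``skewness > 0``."""
    if config.skewness == 0:
        raise ConfigurationError(
            "skewness is 0; use simulate_screen for the Gaussian model"
        )
    return simulate_screen(config, design, rng)


def make_scenario(noise: str, drug: str, rnai: str, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from qualitative (noise, drug, rnai) levels.

    noise low/moderate/strong -> sigma 0.2/0.4/0.8; drug strong/moderate/
    weak -> d 0.3/0.6/0.8; rnai strong/moderate/weak -> (c1, c2)
    (7, 0.15)/(2, 0.5)/(1.25, 0.8).  Keyword overrides pass through to the
    config (e.g. k, skewness, n_sims, seed).
    """
    try:
        sigma = NOISE_LEVELS[noise]
    except KeyError:
        raise ConfigurationError(f"unknown noise level {noise!r}") from None
    try:
        d = DRUG_LEVELS[drug]
    except KeyError:
        raise ConfigurationError(f"unknown drug level {drug!r}") from None
    try:
        c1, c2 = RNAI_LEVELS[rnai]
    except KeyError:
        raise ConfigurationError(f"unknown rnai level {rnai!r}") from None
    params = dict(sigma=sigma, d=d, c1=c1, c2=c2)
    params.update(overrides)
    return ScenarioConfig(**params)
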