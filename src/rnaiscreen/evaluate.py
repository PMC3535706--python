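"""Hit calling, error rates, and the scenario simulation sweep.

Because no significance threshold is comparable across the four methods,
hits are called by rank: in every simulated round exactly n_TH siRNAs (the
true number of hits in that round) are selected per method, half in each
direction.  Methods without p-values (fold change, SI) are ranked by their
signed statistic; methods with p-values (t, LM, Wilcoxon) by signed
significance, direction x (1 - p).  Calls are compared against the ground
truth to produce false-positive and false-negative rates

    FPR = FP / (FP + TN) = 1 - specificity
    FNR = FN / (TP + FN) = 1 - sensitivity

which are averaged over the simulation rounds of a scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import methods as m
from .normalize import normalize_to_untreated_controls
from .simulate import (
    ACTIVE,
    CONTROL,
    LABEL_NON_HIT,
    TREATED,
    UNTREATED,
    NINE_SCENARIOS,
    REPLICATE_LEVELS,
    ScenarioConfig,
    ScreenDataset,
    ScreenDesign,
    TruthTable,
    make_scenario,
    simulate_screen,
)

RESULT_COLUMNS = (
    "scenario",
    "noise",
    "drug",
    "rnai",
    "replicates",
    "method",
    "mean_fpr",
    "mean_fnr",
    "mc_se_fpr",
    "mc_se_fnr",
    "rank",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class EvalRates:
    fpr: float
    fnr: float


@dataclass
class ScenarioResult:
    """Per-method mean error rates of one scenario."""

    config: ScenarioConfig
    design: ScreenDesign
    n_sims: int
    summary: pd.DataFrame  # method, mean_fpr, mean_fnr, mc_se_fpr, mc_se_fnr
    ranking: tuple  # methods ordered by increasing mean FNR


def ranking_key(scores: pd.DataFrame) -> pd.Series:
    """Signed ranking value per score row; larger = more sensitizing.

    Fold change: -statistic.  SI: +statistic.  p-value methods: direction
    sign times (1 - p), a monotone transform of the signed statistic.
    """
    key = pd.Series(np.nan, index=scores.index)
    stat = scores["statistic"]
    for method, sub in scores.groupby("method"):
        if method == m.FOLD_CHANGE:
            key.loc[sub.index] = -sub["statistic"]
        elif method == m.SI:
            key.loc[sub.index] = sub["statistic"]
        elif method in (m.T_TEST, m.WILCOXON):
            key.loc[sub.index] = -np.sign(sub["statistic"]) * (1 - sub["p_value"])
        elif method == m.LM:
            sign = sub["direction"].map(
                {m.SENSITIZING: 1.0, m.ANTAGONIZING: -1.0, m.NONE: 0.0}
            )
            key.loc[sub.index] = sign * (1 - sub["p_value"])
        else:
            raise ValueError(f"unknown method {method!r}")
    return key


def select_top_hits(scores: pd.DataFrame, n_th: int) -> Dict[str, str]:
    """Call the top n_th siRNAs of one method, half in each direction.

    ceil(n_th/2) calls in the sensitizing direction, floor(n_th/2) in the
    antagonizing direction; ties broken by siRNA id.  Returns a mapping
    sirna_id -> called direction.  Invalid scores are never selected.
    """
    if scores.empty and n_th == 0:
        return {}
    if scores["method"].nunique() > 1:
        raise ValueError("select_top_hits expects scores for a single method")
    valid = scores.loc[scores["valid"] & scores["statistic"].notna()].copy()
    if n_th > len(valid):
        raise ValueError(f"n_th={n_th} exceeds the {len(valid)} valid scores")
    if n_th == 0:
        return {}
    valid["_key"] = ranking_key(valid)
    n_sens = math.ceil(n_th / 2)
    n_ant = n_th // 2
    sens_order = valid.sort_values(["_key", "sirna_id"], ascending=[False, True])
    sens_ids = list(sens_order["sirna_id"].iloc[:n_sens])
    rest = sens_order.iloc[n_sens:]
    ant_order = rest.sort_values(["_key", "sirna_id"], ascending=[True, True])
    ant_ids = list(ant_order["sirna_id"].iloc[:n_ant])
    calls = {sid: m.SENSITIZING for sid in sens_ids}
    calls.update({sid: m.ANTAGONIZING for sid in ant_ids})
    return calls


def confusion(
    hits: Mapping[str, str] | Iterable[str],
    truth: TruthTable,
    strict_direction: bool = False,
) -> ConfusionCounts:
    """Compare hit calls against the truth table.

    A true positive is a called siRNA that is a true hit; by default the
    called direction need not match the true one (hit/non-hit only).  With
    ``strict_direction=True`` a direction mismatch counts as FP + FN.
    """
    labels = truth.labels
    if isinstance(hits, Mapping):
        call_dirs = dict(hits)
    else:
        call_dirs = {sid: None for sid in hits}
    unknown = set(call_dirs) - set(labels.index)
    if unknown:
        raise ValueError(f"called siRNAs missing from the truth table: {sorted(unknown)[:5]}")
    tp = fp = 0
    for sid, called_dir in call_dirs.items():
        true_label = labels[sid]
        if true_label == LABEL_NON_HIT:
            fp += 1
        elif strict_direction and called_dir is not None and called_dir != true_label:
            fp += 1
        else:
            tp += 1
    n_hits = int((labels != LABEL_NON_HIT).sum())
    fn = n_hits - tp
    tn = len(labels) - n_hits - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def rates(c: ConfusionCounts) -> EvalRates:
    """FPR = FP/(FP+TN), FNR = FN/(TP+FN)."""
    if c.fp + c.tn == 0:
        raise ZeroDivisionError("FPR undefined: no true non-hits (FP + TN = 0)")
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("FNR undefined: no true hits (TP + FN = 0)")
    return EvalRates(fpr=c.fp / (c.fp + c.tn), fnr=c.fn / (c.tp + c.fn))


def run_scenario(
    config: ScenarioConfig,
    design: Optional[ScreenDesign] = None,
    methods: Sequence[str] = m.DEFAULT_METHODS,
    *,
    n_sims: Optional[int] = None,
    center: str = "mean",
    lm_test: str = "chi2",
    t_variant: str = "pooled",
    strict_direction: bool = False,
) -> ScenarioResult:
    """Monte-Carlo error rates of each method under one scenario.

    Each round simulates a screen, normalizes it, scores every siRNA, calls
    the top n_TH per method and accumulates FPR/FNR.  Per-round RNG streams
    are spawned deterministically from ``config.seed``.
    """
    design = design or ScreenDesign()
    n_sims = config.n_sims if n_sims is None else n_sims
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_sims)
    fprs: Dict[str, list] = {mm: [] for mm in methods}
    fnrs: Dict[str, list] = {mm: [] for mm in methods}
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        try:
            ds = simulate_screen(config, design, rng)
            norm = normalize_to_untreated_controls(ds, center=center)
            scores = m.score_all(norm, methods, lm_test=lm_test, t_variant=t_variant)
            n_th = ds.truth.n_true_hits
            for mm in methods:
                sub = scores.loc[scores["method"] == mm]
                calls = select_top_hits(sub, n_th)
                r = rates(confusion(calls, ds.truth, strict_direction=strict_direction))
                fprs[mm].append(r.fpr)
                fnrs[mm].append(r.fnr)
        except Exception as exc:
            raise RuntimeError(f"scenario round {i} failed: {exc}") from exc
    rows = []
    for mm in methods:
        a_fpr = np.asarray(fprs[mm])
        a_fnr = np.asarray(fnrs[mm])
        se = lambda a: float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else float("nan")
        rows.append(
            {
                "method": mm,
                "mean_fpr": float(a_fpr.mean()),
                "mean_fnr": float(a_fnr.mean()),
                "mc_se_fpr": se(a_fpr),
                "mc_se_fnr": se(a_fnr),
            }
        )
    summary = pd.DataFrame(rows)
    ranking = tuple(summary.sort_values(["mean_fnr", "method"])["method"])
    return ScenarioResult(
        config=config, design=design, n_sims=n_sims, summary=summary, ranking=ranking
    )


def sweep(
    scenarios: Sequence[tuple] = NINE_SCENARIOS,
    replicate_levels: Sequence[int] = REPLICATE_LEVELS,
    methods: Sequence[str] = m.DEFAULT_METHODS,
    *,
    n_sims: int = 500,
    seed: Optional[int] = None,
    config_overrides: Optional[dict] = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Run the full scenario x replicate grid.

    Returns one row per (scenario, replicate level, method) with mean
    FPR/FNR, Monte-Carlo standard errors and the within-scenario rank of
    the method by mean FNR (1 = best).
    """
    if not scenarios or not replicate_levels:
        raise ValueError("scenarios and replicate_levels must be non-empty")
    seed_rng = np.random.default_rng(seed)
    overrides = dict(config_overrides or {})
    rows = []
    for s_num, (noise, drug, rnai) in enumerate(scenarios, start=1):
        for r in replicate_levels:
            sub_seed = int(seed_rng.integers(2**31))
            config = make_scenario(noise, drug, rnai, n_sims=n_sims, seed=sub_seed, **overrides)
            design = ScreenDesign(replicates_per_condition=r)
            res = run_scenario(config, design, methods, **run_kwargs)
            summary = res.summary.copy()
            summary["rank"] = summary["mean_fnr"].rank(method="min").astype(int)
            for _, row in summary.iterrows():
                rows.append(
                    {
                        "scenario": s_num,
                        "noise": noise,
                        "drug": drug,
                        "rnai": rnai,
                        "replicates": r,
                        **row.to_dict(),
                    }
                )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def ranking_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(replicates, scenario) method order by mean FNR, best first."""
    rows = []
    for (r, s), sub in results.groupby(["replicates", "scenario"], sort=True):
        sub = sub.sort_values(["mean_fnr", "method"])
        rows.append(
            {
                "replicates": r,
                "scenario": s,
                "noise": sub["noise"].iloc[0],
                "drug_effect": sub["drug"].iloc[0],
                "rna_effect": sub["rnai"].iloc[0],
                "ranking": ", ".join(sub["method"]),
            }
        )
    return pd.DataFrame(rows)


def figure_tables(results: pd.DataFrame) -> Dict[int, pd.DataFrame]:
    """Per-scenario numeric FNR-vs-replicates tables (method columns)."""
    out = {}
    for s, sub in results.groupby("scenario"):
        out[int(s)] = sub.pivot(index="replicates", columns="method", values="mean_fnr")
    return out


def estimate_diagnostics(screen: ScreenDataset) -> dict:
    """Data-driven guides to method choice for one screen.

    Noise level: coefficient of variation (CV = sd/mean) and variance-to-
    mean ratio (VMR = var/mean) of the untreated wells.  Effect sizes: the
    screen-average RNAi effect Rc/Cc and drug effect Cd/Cc.
    """
    wells = screen.wells
    unt = wells.loc[wells["condition"] == UNTREATED, "viability"].to_numpy(float)
    if unt.size == 0:
        raise ValueError("no untreated wells; diagnostics need untreated data")
    mean = float(unt.mean())
    sd = float(unt.std(ddof=1)) if unt.size > 1 else 0.0
    if mean == 0:
        raise ValueError("untreated mean is zero; CV/VMR undefined")
    arr = m._ScreenArrays(screen)
    with np.errstate(divide="ignore", invalid="ignore"):
        rnai_eff = arr.rc / arr.cc
        drug_eff = arr.mean_c[:, 1] / arr.mean_c[:, 0]  # per-plate Cd/Cc
    return {
        "cv": sd / mean,
        "vmr": sd**2 / mean,
        "mean_rnai_effect": float(np.nanmean(rnai_eff)),
        "mean_drug_effect": float(np.nanmean(drug_eff)),
        "n_untreated_wells": int(unt.size),
    }
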