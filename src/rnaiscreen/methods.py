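"""Per-siRNA hit-selection statistics.

Four statistics are compared throughout:

``fold_change``
    log2 ratio of mean treated to mean untreated viability of the siRNA's
    active wells.  No p-value; negative values point to sensitization.
``t_test``
    Student's two-sample t (pooled variance by default, Welch optional) of
    treated vs untreated active wells, sign = treated - untreated.
``si``
    Sensitivity index ``SI = (Rc/Cc)*(Cd/Cc) - Rd/Cc`` where Rc/Rd are the
    siRNA's untreated/treated means and Cc/Cd the NS-control means on the
    same plates: the gap between the expected multiplicative combination of
    the RNAi and drug effects and the observed combined effect.  Positive
    values indicate sensitization; no p-value is defined.
``lm``
    A per-siRNA linear model of viability on drug status x1, active-siRNA
    status x2 and their interaction, fit to the siRNA's active wells plus
    the NS-control wells on its plates:

        Y = b0 + b1*x1 + b2*x2 + b3*x1*x2 + e        (full)
        Y = b0 + b1*x1 + e                           (reduced)

    The statistic is the scaled deviance difference
    (RSS_reduced - RSS_full) / sigma2_hat with sigma2_hat =
    RSS_full/(n-4), referred to chi-square with 2 df (an exact
    F(2, n-4) variant is available).  It tests the RNAi main effect and
    the drug x RNAi interaction jointly; the direction is the sign of the
    fitted interaction b3 (negative = sensitizing).

A fifth, optional ``wilcoxon`` rank-sum statistic mirrors the t-test
non-parametrically and is excluded from the default comparison.

``score_all`` computes all requested statistics for every siRNA in one
vectorized pass over the well table; the per-siRNA functions are the
readable reference implementations of the same quantities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ACTIVE, CONTROL, TREATED, UNTREATED, ScreenDataset

logger = logging.getLogger(__name__)

FOLD_CHANGE = "fold_change"
T_TEST = "t_test"
SI = "si"
LM = "lm"
WILCOXON = "wilcoxon"

#: The four methods of the default comparison (wilcoxon is opt-in).
DEFAULT_METHODS = (FOLD_CHANGE, T_TEST, SI, LM)
ALL_METHODS = DEFAULT_METHODS + (WILCOXON,)

SENSITIZING = "sensitizing"
ANTAGONIZING = "antagonizing"
NONE = "none"

#: Columns of the score table, in output order.
SCORE_COLUMNS = ("sirna_id", "method", "statistic", "p_value", "direction", "valid")


@dataclass
class CellSummaries:
    """Mean viabilities of the four well classes relevant to one siRNA.

    rc/rd: active wells untreated/treated; cc/cd: NS-control wells on the
    same plates, untreated/treated.
    """

    rc: float
    rd: float
    cc: float
    cd: float


@dataclass
class MethodScore:
    """One method's score for one siRNA."""

    sirna_id: str
    method: str
    statistic: float
    p_value: Optional[float] = None
    direction: str = NONE
    valid: bool = True
    extras: dict = field(default_factory=dict)


def _active_values(screen: ScreenDataset, sirna_id: str):
    wells = screen.wells
    mask = (wells["kind"] == ACTIVE) & (wells["sirna_id"] == sirna_id)
    if not mask.any():
        raise KeyError(f"siRNA {sirna_id!r} not found in the screen")
    sub = wells.loc[mask]
    unt = sub.loc[sub["condition"] == UNTREATED, "viability"].to_numpy(float)
    trt = sub.loc[sub["condition"] == TREATED, "viability"].to_numpy(float)
    plates = sub["plate"].unique()
    for name, arr in ((UNTREATED, unt), (TREATED, trt)):
        if arr.size == 0:
            raise ValueError(f"siRNA {sirna_id!r} has no {name} wells")
    return unt, trt, plates


def _control_values(screen: ScreenDataset, plates):
    wells = screen.wells
    mask = (wells["kind"] == CONTROL) & wells["plate"].isin(plates)
    sub = wells.loc[mask]
    unt = sub.loc[sub["condition"] == UNTREATED, "viability"].to_numpy(float)
    trt = sub.loc[sub["condition"] == TREATED, "viability"].to_numpy(float)
    return unt, trt


def summarize_cells(screen: ScreenDataset, sirna_id: str) -> CellSummaries:
    """Rc, Rd, Cc, Cd means for one siRNA (controls from its own plates)."""
    unt, trt, plates = _active_values(screen, sirna_id)
    c_unt, c_trt = _control_values(screen, plates)
    for name, arr in (("untreated control", c_unt), ("treated control", c_trt)):
        if arr.size == 0:
            raise ValueError(f"siRNA {sirna_id!r}: no {name} wells on its plates")
    return CellSummaries(
        rc=float(unt.mean()), rd=float(trt.mean()), cc=float(c_unt.mean()), cd=float(c_trt.mean())
    )


def _fc_direction(stat: float) -> str:
    if stat < 0:
        return SENSITIZING
    if stat > 0:
        return ANTAGONIZING
    return NONE


def fold_change(screen: ScreenDataset, sirna_id: str) -> MethodScore:
    """log2(mean treated / mean untreated) over the siRNA's active wells."""
    unt, trt, _ = _active_values(screen, sirna_id)
    mu_u, mu_t = unt.mean(), trt.mean()
    if mu_u <= 0:
        logger.warning("fold_change: non-positive untreated mean for %s", sirna_id)
        return MethodScore(sirna_id, FOLD_CHANGE, float("nan"), valid=False)
    if mu_t <= 0:
        # ranked most-sensitizing: complete kill under drug
        return MethodScore(sirna_id, FOLD_CHANGE, float("-inf"), direction=SENSITIZING)
    stat = math.log2(mu_t / mu_u)
    return MethodScore(sirna_id, FOLD_CHANGE, stat, direction=_fc_direction(stat))


def _pooled_t(trt: np.ndarray, unt: np.ndarray, variant: str = "pooled"):
    n1, n0 = trt.size, unt.size
    diff = trt.mean() - unt.mean()
    if variant == "pooled":
        df = n1 + n0 - 2
        sp2 = ((trt.var(ddof=1) * (n1 - 1)) + (unt.var(ddof=1) * (n0 - 1))) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n0))
    elif variant == "welch":
        v1, v0 = trt.var(ddof=1) / n1, unt.var(ddof=1) / n0
        se = math.sqrt(v1 + v0)
        df = (v1 + v0) ** 2 / (v1**2 / (n1 - 1) + v0**2 / (n0 - 1)) if v1 + v0 > 0 else n1 + n0 - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se == 0:
        if diff == 0:
            return 0.0, 1.0, df
        return math.copysign(float("inf"), diff), 0.0, df
    t = diff / se
    return t, 2 * float(stats.t.sf(abs(t), df)), df


def t_statistic(screen: ScreenDataset, sirna_id: str, variant: str = "pooled") -> MethodScore:
    """Two-sample t of treated vs untreated active wells (sign: treated - untreated)."""
    unt, trt, _ = _active_values(screen, sirna_id)
    if unt.size < 2 or trt.size < 2:
        raise ValueError(f"siRNA {sirna_id!r}: need >= 2 wells per condition for a t-test")
    t, p, df = _pooled_t(trt, unt, variant)
    direction = SENSITIZING if t < 0 else ANTAGONIZING if t > 0 else NONE
    return MethodScore(sirna_id, T_TEST, t, p_value=p, direction=direction, extras={"df": df})


def sensitivity_index(screen: ScreenDataset, sirna_id: str) -> MethodScore:
    """SI = (Rc/Cc)*(Cd/Cc) - Rd/Cc; positive = sensitizing."""
    cells = summarize_cells(screen, sirna_id)
    if cells.cc <= 0:
        logger.warning("sensitivity_index: non-positive Cc for %s", sirna_id)
        return MethodScore(sirna_id, SI, float("nan"), valid=False)
    stat = (cells.rc / cells.cc) * (cells.cd / cells.cc) - cells.rd / cells.cc
    direction = SENSITIZING if stat > 0 else ANTAGONIZING if stat < 0 else NONE
    return MethodScore(sirna_id, SI, stat, direction=direction)


def _lm_score_from_rss(
    sirna_id: str, rss_full: float, rss_red: float, n: int, beta3: float, test: str
) -> MethodScore:
    df_resid = n - 4
    extras = {"beta3": beta3, "rss_full": rss_full, "rss_reduced": rss_red, "n": n}
    # numerically perfect fits leave RSS_full at rounding-noise level
    if rss_full <= 1e-12 * (rss_full + rss_red):
        if rss_red > 0:
            stat, p = float("inf"), 0.0
        else:
            stat, p = 0.0, 1.0
    else:
        sigma2 = rss_full / df_resid
        stat = (rss_red - rss_full) / sigma2
        stat = max(stat, 0.0)
        if test == "chi2":
            p = float(stats.chi2.sf(stat, 2))
        elif test == "f":
            stat = stat / 2
            p = float(stats.f.sf(stat, 2, df_resid))
        else:
            raise ValueError(f"unknown lm test {test!r}")
    direction = SENSITIZING if beta3 < 0 else ANTAGONIZING if beta3 > 0 else NONE
    return MethodScore(sirna_id, LM, stat, p_value=p, direction=direction, extras=extras)


def lm_interaction_test(screen: ScreenDataset, sirna_id: str, test: str = "chi2") -> MethodScore:
    """Deviance-difference test of the drug x RNAi linear model for one siRNA.

    Fits the full and the drug-only models by ordinary least squares on the
    siRNA's active wells plus the NS-control wells on its plates.
    """
    import statsmodels.api as sm

    unt, trt, plates = _active_values(screen, sirna_id)
    c_unt, c_trt = _control_values(screen, plates)
    if c_unt.size == 0 or c_trt.size == 0:
        raise ValueError(
            f"siRNA {sirna_id!r}: design is singular (no control wells in one condition)"
        )
    y = np.concatenate([unt, trt, c_unt, c_trt])
    x1 = np.concatenate(
        [np.zeros_like(unt), np.ones_like(trt), np.zeros_like(c_unt), np.ones_like(c_trt)]
    )
    x2 = np.concatenate(
        [np.ones_like(unt), np.ones_like(trt), np.zeros_like(c_unt), np.zeros_like(c_trt)]
    )
    n = y.size
    if n < 5:
        raise ValueError(f"siRNA {sirna_id!r}: need at least 5 wells to fit the full model")
    x_full = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(n), x1])).fit()
    return _lm_score_from_rss(
        sirna_id,
        float(full.ssr),
        float(reduced.ssr),
        n,
        float(full.params[3]),
        test,
    )


def wilcoxon_test(screen: ScreenDataset, sirna_id: str) -> MethodScore:
    """Wilcoxon rank-sum of treated vs untreated active wells.

    Exact p for <= 10 wells per arm, normal approximation otherwise.  The
    statistic is the centered Mann-Whitney U (sign: treated - untreated).
    """
    unt, trt, _ = _active_values(screen, sirna_id)
    if unt.size < 2 or trt.size < 2:
        raise ValueError(f"siRNA {sirna_id!r}: need >= 2 wells per condition")
    method = "exact" if max(unt.size, trt.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(trt, unt, alternative="two-sided", method=method)
    stat = float(res.statistic) - trt.size * unt.size / 2.0
    direction = SENSITIZING if stat < 0 else ANTAGONIZING if stat > 0 else NONE
    return MethodScore(
        sirna_id, WILCOXON, stat, p_value=float(res.pvalue), direction=direction
    )


# ---------------------------------------------------------------------------
# Vectorized scoring of a whole screen
# ---------------------------------------------------------------------------


def _groupby_stats(idx: np.ndarray, cond: np.ndarray, y: np.ndarray, n_groups: int):
    """Per (group, condition) count, sum and sum of squares."""
    n = np.zeros((n_groups, 2))
    s = np.zeros((n_groups, 2))
    q = np.zeros((n_groups, 2))
    np.add.at(n, (idx, cond), 1.0)
    np.add.at(s, (idx, cond), y)
    np.add.at(q, (idx, cond), y * y)
    return n, s, q


def _within_ss(n, s, q):
    with np.errstate(divide="ignore", invalid="ignore"):
        w = q - np.where(n > 0, s * s / np.where(n > 0, n, 1.0), 0.0)
    return np.clip(w, 0.0, None)


class _ScreenArrays:
    """Per-siRNA and per-plate sufficient statistics of one screen."""

    def __init__(self, screen: ScreenDataset):
        wells = screen.wells
        kind = wells["kind"].to_numpy()
        act_mask = kind == ACTIVE
        act = wells.loc[act_mask]
        ctl = wells.loc[~act_mask]

        self.sirna_ids, s_idx = np.unique(act["sirna_id"].to_numpy(), return_inverse=True)
        n_s = len(self.sirna_ids)
        cond_a = (act["condition"].to_numpy() == TREATED).astype(np.intp)
        ya = act["viability"].to_numpy(float)
        self.n_a, self.sum_a, self.ssq_a = _groupby_stats(s_idx, cond_a, ya, n_s)

        plates_a = act["plate"].to_numpy()
        self.plate_ids, p_idx_a = np.unique(plates_a, return_inverse=True)
        plate_of = np.empty(n_s, dtype=np.intp)
        plate_of[s_idx[::-1]] = p_idx_a[::-1]  # first occurrence wins
        if np.any(p_idx_a != plate_of[s_idx]):
            bad = self.sirna_ids[np.unique(s_idx[p_idx_a != plate_of[s_idx]])]
            raise ValueError(
                f"siRNAs spanning multiple plates are not supported: {list(bad[:5])}"
            )
        self.plate_of = plate_of

        cond_c = (ctl["condition"].to_numpy() == TREATED).astype(np.intp)
        yc = ctl["viability"].to_numpy(float)
        plates_c = ctl["plate"].to_numpy()
        if not np.isin(plates_c, self.plate_ids).all():
            raise ValueError("control wells found on plates without active siRNAs")
        p_idx_c = np.searchsorted(self.plate_ids, plates_c)
        self.n_c, self.sum_c, self.ssq_c = _groupby_stats(
            p_idx_c, cond_c, yc, len(self.plate_ids)
        )

        with np.errstate(divide="ignore", invalid="ignore"):
            self.mean_a = np.where(self.n_a > 0, self.sum_a / np.where(self.n_a > 0, self.n_a, 1), np.nan)
            self.mean_c = np.where(self.n_c > 0, self.sum_c / np.where(self.n_c > 0, self.n_c, 1), np.nan)
        self.w_a = _within_ss(self.n_a, self.sum_a, self.ssq_a)
        self.w_c = _within_ss(self.n_c, self.sum_c, self.ssq_c)

    # cell means, sirna-aligned
    @property
    def rc(self):
        return self.mean_a[:, 0]

    @property
    def rd(self):
        return self.mean_a[:, 1]

    @property
    def cc(self):
        return self.mean_c[self.plate_of, 0]

    @property
    def cd(self):
        return self.mean_c[self.plate_of, 1]


def _score_fold_change(arr: _ScreenArrays) -> pd.DataFrame:
    rc, rd = arr.rc, arr.rd
    valid = rc > 0
    stat = np.full(rc.shape, np.nan)
    with np.errstate(divide="ignore"):
        pos = valid & (rd > 0)
        stat[pos] = np.log2(rd[pos] / rc[pos])
        stat[valid & (rd <= 0)] = -np.inf
    direction = np.where(stat < 0, SENSITIZING, np.where(stat > 0, ANTAGONIZING, NONE))
    direction[~valid] = NONE
    return pd.DataFrame(
        {
            "sirna_id": arr.sirna_ids,
            "method": FOLD_CHANGE,
            "statistic": stat,
            "p_value": np.nan,
            "direction": direction,
            "valid": valid,
        }
    )


def _score_t(arr: _ScreenArrays, variant: str) -> pd.DataFrame:
    n0, n1 = arr.n_a[:, 0], arr.n_a[:, 1]
    valid = (n0 >= 2) & (n1 >= 2)
    diff = arr.rd - arr.rc
    if variant == "pooled":
        df = n0 + n1 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (arr.w_a[:, 0] + arr.w_a[:, 1]) / df
            se = np.sqrt(sp2 * (1 / n0 + 1 / n1))
    elif variant == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            v0 = arr.w_a[:, 0] / (n0 - 1) / n0
            v1 = arr.w_a[:, 1] / (n1 - 1) / n1
            se = np.sqrt(v0 + v1)
            df = np.where(
                v0 + v1 > 0,
                (v0 + v1) ** 2 / (v0**2 / (n0 - 1) + v1**2 / (n1 - 1)),
                n0 + n1 - 2,
            )
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    stat = np.full(diff.shape, np.nan)
    p = np.full(diff.shape, np.nan)
    zero_se = valid & (se == 0)
    stat[zero_se] = np.where(diff[zero_se] == 0, 0.0, np.copysign(np.inf, diff[zero_se]))
    p[zero_se] = np.where(diff[zero_se] == 0, 1.0, 0.0)
    ok = valid & (se > 0)
    stat[ok] = diff[ok] / se[ok]
    p[ok] = 2 * stats.t.sf(np.abs(stat[ok]), np.asarray(df)[ok])
    direction = np.where(stat < 0, SENSITIZING, np.where(stat > 0, ANTAGONIZING, NONE))
    direction[~valid] = NONE
    return pd.DataFrame(
        {
            "sirna_id": arr.sirna_ids,
            "method": T_TEST,
            "statistic": stat,
            "p_value": p,
            "direction": direction,
            "valid": valid,
        }
    )


def _score_si(arr: _ScreenArrays) -> pd.DataFrame:
    rc, rd, cc, cd = arr.rc, arr.rd, arr.cc, arr.cd
    valid = cc > 0
    stat = np.full(rc.shape, np.nan)
    stat[valid] = (rc[valid] / cc[valid]) * (cd[valid] / cc[valid]) - rd[valid] / cc[valid]
    direction = np.where(stat > 0, SENSITIZING, np.where(stat < 0, ANTAGONIZING, NONE))
    direction[~valid] = NONE
    return pd.DataFrame(
        {
            "sirna_id": arr.sirna_ids,
            "method": SI,
            "statistic": stat,
            "p_value": np.nan,
            "direction": direction,
            "valid": valid,
        }
    )


def _score_lm(arr: _ScreenArrays, test: str) -> pd.DataFrame:
    """Closed-form cell-mean OLS for the full and reduced models.

    The full model is the saturated 2x2 layout, so RSS_full is the pooled
    within-cell sum of squares; the reduced (intercept + drug) model fits
    the per-condition means, so RSS_reduced is the within-condition sum of
    squares.  Both are exact for arbitrary cell counts.
    """
    p = arr.plate_of
    n_cells = np.column_stack([arr.n_a, arr.n_c[p]])  # au, at, cu, ct
    rss_full = arr.w_a[:, 0] + arr.w_a[:, 1] + arr.w_c[p, 0] + arr.w_c[p, 1]
    rss_red = np.zeros_like(rss_full)
    for cond in (0, 1):
        n = arr.n_a[:, cond] + arr.n_c[p, cond]
        s = arr.sum_a[:, cond] + arr.sum_c[p, cond]
        q = arr.ssq_a[:, cond] + arr.ssq_c[p, cond]
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_red += np.clip(q - np.where(n > 0, s * s / np.where(n > 0, n, 1), 0), 0, None)
    n_tot = n_cells.sum(axis=1)
    valid = (n_cells >= 1).all(axis=1) & (n_tot >= 5)
    beta3 = (arr.rd - arr.rc) - (arr.cd - arr.cc)
    df_resid = n_tot - 4
    stat = np.full(rss_full.shape, np.nan)
    pval = np.full(rss_full.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss_full / df_resid
    nonzero = rss_full > 1e-12 * (rss_full + rss_red)
    pos = valid & nonzero
    stat[pos] = np.clip((rss_red[pos] - rss_full[pos]) / sigma2[pos], 0, None)
    degen = valid & ~nonzero
    stat[degen] = np.where(rss_red[degen] > 0, np.inf, 0.0)
    pval[degen] = np.where(rss_red[degen] > 0, 0.0, 1.0)
    if test == "chi2":
        pval[pos] = stats.chi2.sf(stat[pos], 2)
    elif test == "f":
        stat[pos] = stat[pos] / 2
        pval[pos] = stats.f.sf(stat[pos], 2, df_resid[pos])
    else:
        raise ValueError(f"unknown lm test {test!r}")
    direction = np.where(beta3 < 0, SENSITIZING, np.where(beta3 > 0, ANTAGONIZING, NONE))
    direction[~valid] = NONE
    return pd.DataFrame(
        {
            "sirna_id": arr.sirna_ids,
            "method": LM,
            "statistic": stat,
            "p_value": pval,
            "direction": direction,
            "valid": valid,
            "beta3": beta3,
        }
    )


def _score_wilcoxon(screen: ScreenDataset, arr: _ScreenArrays) -> pd.DataFrame:
    rows = []
    for sid in arr.sirna_ids:
        try:
            sc = wilcoxon_test(screen, sid)
            rows.append((sid, sc.statistic, sc.p_value, sc.direction, True))
        except ValueError:
            rows.append((sid, np.nan, np.nan, NONE, False))
    out = pd.DataFrame(rows, columns=["sirna_id", "statistic", "p_value", "direction", "valid"])
    out.insert(1, "method", WILCOXON)
    return out


def score_all(
    screen: ScreenDataset,
    methods: Sequence[str] = DEFAULT_METHODS,
    *,
    lm_test: str = "chi2",
    t_variant: str = "pooled",
) -> pd.DataFrame:
    """Score every siRNA with each requested method.

    Returns one row per (siRNA, method) with columns ``sirna_id, method,
    statistic, p_value, direction, valid`` (plus ``beta3`` for lm rows).
    Invalid scores are kept, flagged ``valid=False``, never dropped.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        return pd.DataFrame(columns=list(SCORE_COLUMNS))
    arr = _ScreenArrays(screen)
    parts = []
    for m in methods:
        if m == FOLD_CHANGE:
            parts.append(_score_fold_change(arr))
        elif m == T_TEST:
            parts.append(_score_t(arr, t_variant))
        elif m == SI:
            parts.append(_score_si(arr))
        elif m == LM:
            parts.append(_score_lm(arr, lm_test))
        elif m == WILCOXON:
            parts.append(_score_wilcoxon(screen, arr))
    table = pd.concat(parts, ignore_index=True)
    n_invalid = int((~table["valid"]).sum())
    if n_invalid:
        logger.warning("score_all: %d invalid scores flagged", n_invalid)
    return table
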