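"""Condition pooling and mixed-effects comparison of coordination measures.

One row per retained trial (mean CRP, SD of CRP, deviation from intended
phase) is pooled into four analysis strata (coordination mode x cycling
frequency).  Within each stratum a linear mixed model

    response ~ load_condition + (1 | participant) + (1 | trial)

is fitted by REML, with the no-load/no-load pair as the reference level so
the intercept estimates the unperturbed condition.  Pairwise differences
between the nine load-condition marginal means are Tukey-adjusted via the
studentized range distribution.  A learning-effect variant adds the trial
index as a fixed slope.  Also includes the Edinburgh-handedness laterality
classifier used to describe participant samples.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .crp import TrialSummary
from .synth import LoadType, Mode

_LOADS = (LoadType.NONE, LoadType.VISCOUS, LoadType.ELASTIC)

__all__ = [
    "REFERENCE_LEVEL",
    "ModelResult",
    "build_condition_table",
    "split_strata",
    "fit_lme",
    "pairwise_emm",
    "learning_effect_check",
    "classify_handedness",
    "simulate_summary_table",
]

log = logging.getLogger(__name__)

REFERENCE_LEVEL = "none/none"

_RESPONSE_COL = {"mean": "mean_crp_deg", "sd": "sd_crp_deg"}


def build_condition_table(summaries: Iterable[TrialSummary]) -> pd.DataFrame:
    """Pool trial summaries into one analysis table.

    Excluded (phase-transition) trials are dropped with a logged count.
    ``load_condition`` is the ordered "left/right" pair label.  Raises on
    duplicate (participant, mode, trial) keys or unknown load labels.
    """
    rows = []
    n_excluded = 0
    known = {"none", "viscous", "elastic"}
    for s in summaries:
        if s.load_left not in known or s.load_right not in known:
            raise ValueError(f"unknown load label: {s.load_left}/{s.load_right}")
        if s.excluded:
            n_excluded += 1
            continue
        rows.append(
            {
                "participant": s.participant,
                "trial": s.trial,
                "mode": s.mode.value if isinstance(s.mode, Mode) else str(s.mode),
                "cycle_ms": float(s.cycle_ms),
                "load_condition": f"{s.load_left}/{s.load_right}",
                "mean_crp_deg": s.mean_crp_deg,
                "sd_crp_deg": s.sd_crp_deg,
                "deviation_deg": s.deviation_deg,
            }
        )
    if n_excluded:
        log.info("build_condition_table: dropped %d excluded trials", n_excluded)
    df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn("condition table is empty (all trials excluded?)", RuntimeWarning)
        return df
    dup = df.duplicated(subset=["participant", "mode", "trial"])
    if dup.any():
        raise ValueError(
            f"duplicate (participant, mode, trial) keys: {df[dup].head().to_dict('records')}"
        )
    return df


def split_strata(table: pd.DataFrame) -> dict[tuple[str, float], pd.DataFrame]:
    """Partition a condition table into the four (mode, cycle) strata."""
    return {
        (mode, cyc): g.reset_index(drop=True)
        for (mode, cyc), g in table.groupby(["mode", "cycle_ms"], sort=True)
    }


@dataclass
class ModelResult:
    """Fitted mixed model for one stratum and response."""

    response: str
    stratum: str
    levels: list[str]  # condition levels, reference first
    beta: pd.Series  # fixed effects: Intercept then non-reference levels
    se: pd.Series
    pvalues: pd.Series  # Wald chi-square p per coefficient
    cov: np.ndarray  # covariance of the fixed effects
    random_sd: dict  # group label -> SD of random intercept
    residual_sd: float
    n_obs: int
    df_resid: float
    converged: bool
    note: str = ""
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Fixed-effects table (beta, SE, p) in reporting layout."""
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "p_chi2": self.pvalues}
        ).rename_axis("term")


def _wald_chi2_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z2 = (beta / se) ** 2
    return sps.chi2.sf(z2, df=1)


def _fit_mixedlm(formula: str, df: pd.DataFrame, crossed_trial: bool):
    """REML fit with random intercepts for participant (and crossed trial)."""
    data = df.copy()
    data["_all"] = 1
    if crossed_trial:
        vc = {"participant": "0 + C(participant)", "trial": "0 + C(trial)"}
        model = smf.mixedlm(formula, data, groups="_all", vc_formula=vc, re_formula="0")
    else:
        model = smf.mixedlm(formula, data, groups="participant")
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=True, method=[method])
        except Exception as exc:  # optimizer-specific failures; try the next
            last_exc = exc
    raise RuntimeError(f"mixed-model optimization failed: {last_exc}") from last_exc


def fit_lme(
    table: pd.DataFrame,
    response: str = "mean",
    stratum: str = "",
) -> ModelResult:
    """Fit response ~ load_condition with participant and trial intercepts.

    ``table`` is one stratum of a condition table; ``response`` selects the
    mean CRP ("mean") or its SD ("sd").  The reference level is the
    no-load/no-load pair.  If the crossed-random-intercept fit fails to
    converge or is singular, the model is refitted with a participant-only
    random intercept and the downgrade is logged in ``note``.
    """
    if response not in _RESPONSE_COL:
        raise ValueError("response must be 'mean' or 'sd'")
    col = _RESPONSE_COL[response]
    if table["participant"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 participants")
    if REFERENCE_LEVEL not in set(table["load_condition"]):
        raise ValueError(f"reference level {REFERENCE_LEVEL!r} absent from table")
    levels = [REFERENCE_LEVEL] + sorted(
        set(table["load_condition"]) - {REFERENCE_LEVEL}
    )
    formula = f"{col} ~ C(load_condition, Treatment(reference='{REFERENCE_LEVEL}'))"

    note = ""
    result = _fit_mixedlm(formula, table, crossed_trial=True)
    if not result.converged or not np.all(np.isfinite(result.bse_fe)):
        note = "crossed trial intercept dropped (non-convergence); participant-only fit"
        log.warning("fit_lme[%s/%s]: %s", stratum, response, note)
        result = _fit_mixedlm(formula, table, crossed_trial=False)
        if not result.converged:
            raise RuntimeError(f"mixed model failed to converge for stratum {stratum!r}")

    k = len(result.fe_params)
    beta = result.fe_params.copy()
    se = result.bse_fe.copy()
    # readable term names: Intercept then condition levels
    pretty = ["Intercept"] + levels[1:]
    beta.index = pretty
    se.index = pretty
    pvals = pd.Series(_wald_chi2_p(beta.to_numpy(), se.to_numpy()), index=pretty)
    cov = np.asarray(result.cov_params())[:k, :k]

    random_sd = {}
    if result.k_re > 0:
        random_sd["participant"] = float(np.sqrt(result.cov_re.iloc[0, 0]))
    for name, var in zip(result.model.exog_vc.names, np.atleast_1d(result.vcomp)):
        random_sd[name] = float(np.sqrt(max(var, 0.0)))
    return ModelResult(
        response=response,
        stratum=stratum,
        levels=levels,
        beta=beta,
        se=se,
        pvalues=pvals,
        cov=cov,
        random_sd=random_sd,
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(len(table)),
        df_resid=float(max(len(table) - k, 2)),
        converged=bool(result.converged),
        note=note,
    )


def pairwise_emm(model: ModelResult, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of the condition marginal means.

    With treatment coding and load condition as the only fixed factor, the
    marginal mean of level i is intercept + beta_i (reference beta = 0).
    Each pairwise difference gets a studentized-range ("Tukey HSD") adjusted
    p-value and a simultaneous confidence interval; the unadjusted p uses
    the t distribution at the model's residual df.  Adjusted p >= raw p for
    every contrast.
    """
    if not model.converged:
        raise ValueError(f"model for stratum {model.stratum!r} did not converge")
    k = len(model.levels)
    beta = model.beta.to_numpy()
    # coefficient row for each level's marginal mean
    rows = np.zeros((k, len(beta)))
    rows[:, 0] = 1.0
    for i in range(1, k):
        rows[i, i] = 1.0
    emm = rows @ beta
    df = model.df_resid
    q_crit = sps.studentized_range.ppf(1.0 - alpha, k, df)

    records = []
    for i, j in itertools.combinations(range(k), 2):
        c = rows[i] - rows[j]
        diff = float(emm[i] - emm[j])
        var = float(c @ model.cov @ c)
        if var <= 0:
            raise ValueError(
                f"degenerate contrast variance in stratum {model.stratum!r}"
            )
        se = np.sqrt(var)
        q = abs(diff) / se * np.sqrt(2.0)
        p_adj = float(sps.studentized_range.sf(q, k, df))
        p_raw = float(2.0 * sps.t.sf(abs(diff) / se, df))
        hw = q_crit / np.sqrt(2.0) * se
        records.append(
            {
                "level_1": model.levels[i],
                "level_2": model.levels[j],
                "emm_1": float(emm[i]),
                "emm_2": float(emm[j]),
                "estimate": diff,
                "se": se,
                "ci_low": diff - hw,
                "ci_high": diff + hw,
                "p_raw": min(p_raw, 1.0),
                "p_tukey": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame.from_records(records)


def learning_effect_check(
    table: pd.DataFrame,
    response: str = "mean",
    stratum: str = "",
    alpha: float = 0.05,
) -> ModelResult:
    """Test for a drift of the response across trial order.

    Adds the numeric trial index as a fixed slope alongside the condition
    factor (participant random intercept).  The slope estimate, its CI and
    whether it differs from zero at ``alpha`` are stored in ``extra``.
    """
    if response not in _RESPONSE_COL:
        raise ValueError("response must be 'mean' or 'sd'")
    col = _RESPONSE_COL[response]
    if table["participant"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 participants")
    formula = (
        f"{col} ~ C(load_condition, Treatment(reference='{REFERENCE_LEVEL}')) + trial"
    )
    result = _fit_mixedlm(formula, table, crossed_trial=False)
    beta = result.fe_params
    se = result.bse_fe
    slope = float(beta.iloc[-1])
    slope_se = float(se.iloc[-1])
    df_resid = float(max(len(table) - len(beta), 2))
    p = float(2.0 * sps.t.sf(abs(slope) / slope_se, df_resid))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df_resid)
    levels = [REFERENCE_LEVEL] + sorted(set(table["load_condition"]) - {REFERENCE_LEVEL})
    pretty = ["Intercept"] + levels[1:] + ["trial"]
    beta = beta.copy()
    se = se.copy()
    beta.index = pretty
    se.index = pretty
    return ModelResult(
        response=response,
        stratum=stratum,
        levels=levels,
        beta=beta,
        se=se,
        pvalues=pd.Series(_wald_chi2_p(beta.to_numpy(), se.to_numpy()), index=pretty),
        cov=np.asarray(result.cov_params())[: len(beta), : len(beta)],
        random_sd={"participant": float(np.sqrt(result.cov_re.iloc[0, 0]))},
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(len(table)),
        df_resid=df_resid,
        converged=bool(result.converged),
        extra={
            "slope_per_trial": slope,
            "slope_se": slope_se,
            "slope_ci": (slope - tcrit * slope_se, slope + tcrit * slope_se),
            "slope_p": p,
            "significant": p < alpha,
        },
    )


def classify_handedness(lq: float) -> str:
    """Classify an Edinburgh laterality quotient into left/mixed/right.

    Cutoffs: right-handed for LQ >= 61, left-handed for LQ <= -61, mixed
    in between.  LQ must lie in [-100, 100].
    """
    if not (-100.0 <= lq <= 100.0):
        raise ValueError(f"laterality quotient out of range [-100, 100]: {lq}")
    if lq >= 61.0:
        return "right"
    if lq <= -61.0:
        return "left"
    return "mixed"


def simulate_summary_table(
    n_participants: int,
    n_reps: int = 5,
    baseline: float = 5.0,
    level_offsets: dict | None = None,
    participant_sd: float = 1.5,
    trial_sd: float = 0.3,
    residual_sd: float = 2.0,
    trial_slope: float = 0.0,
    mode: str = "in_phase",
    cycle_ms: float = 750.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic one-stratum condition table directly at summary level.

    A fast generative model matching the mixed-model structure (additive
    condition offsets, participant and trial-index random intercepts,
    i.i.d. residuals), used for parameter-recovery and error-rate
    simulations where rendering full kinematics would be wasteful.  All
    nine load conditions are present with ``n_reps`` trials each per
    participant.
    """
    rng = np.random.default_rng(seed)
    levels = [f"{l.value}/{r.value}" for l in _LOADS for r in _LOADS]
    offsets = {lv: 0.0 for lv in levels}
    if level_offsets:
        unknown = set(level_offsets) - set(levels)
        if unknown:
            raise ValueError(f"unknown condition levels: {sorted(unknown)}")
        offsets.update(level_offsets)
    n_trials = len(levels) * n_reps
    trial_effects = rng.normal(0.0, trial_sd, n_trials)
    rows = []
    for p in range(1, n_participants + 1):
        p_eff = rng.normal(0.0, participant_sd)
        order = rng.permutation(np.repeat(np.arange(len(levels)), n_reps))
        for tidx, lv_idx in enumerate(order, start=1):
            lv = levels[lv_idx]
            y = (
                baseline
                + offsets[lv]
                + p_eff
                + trial_effects[tidx - 1]
                + trial_slope * tidx
                + rng.normal(0.0, residual_sd)
            )
            rows.append(
                {
                    "participant": p,
                    "trial": tidx,
                    "mode": mode,
                    "cycle_ms": cycle_ms,
                    "load_condition": lv,
                    "mean_crp_deg": y,
                    "sd_crp_deg": abs(y),
                    "deviation_deg": abs(y),
                }
            )
    return pd.DataFrame(rows)
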