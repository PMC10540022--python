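"""Effect reporting on three scales, subgroup tables, and moderated curves.

A fitted dose coefficient beta lives on the natural-log scale of the
weekly T score.  It is reported alongside

* the percentage-scale improvement ``exp(beta) - 1`` (the relative
  change in the raw score implied by the log-linear model), and
* the score-scale improvement ``(exp(beta) - 1) * reference``, where
  the reference is the mean raw score over valid no-message weeks
  (recomputed per outcome, and per subgroup for subgroup tables).

Both transformations are strictly increasing, so confidence bounds map
through them with their order preserved.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mrtdose.synth import DOSE_LEVELS, GROUPS
from mrtdose.wcls import ContrastResult, FitResult, wald_contrast


def pct_improvement(beta_log: float | np.ndarray) -> float | np.ndarray:
    """Percentage-scale improvement implied by a log-scale effect.

    ``exp(beta) - 1``; elementwise for arrays, strictly increasing,
    maps 0 to 0.
    """
    arr = np.expm1(beta_log)
    return float(arr) if np.isscalar(beta_log) else arr


def score_improvement(
    pct: float | np.ndarray, reference_score: float
) -> float | np.ndarray:
    """T-score-scale improvement: ``pct * reference_score``.

    The reference must be a positive raw score (typically the
    zero-dose sample mean); the sign of ``pct`` is preserved.
    """
    if not (np.isfinite(reference_score) and reference_score > 0):
        raise ValueError(f"reference_score must be > 0, got {reference_score!r}")
    out = np.asarray(pct, dtype=float) * reference_score
    return float(out) if np.isscalar(pct) else out


def display_2dp(x: float) -> float:
    """Two-decimal display with truncation toward zero (so −0.2366 shows
    as −0.23, and a small negative keeps its sign as −0.00)."""
    return math.trunc(x * 100) / 100


def reference_score(
    table: pd.DataFrame, outcome: str, subgroup: str | None = None
) -> float:
    """Mean raw weekly score over valid no-message person-weeks."""
    df = table
    if "valid" in df.columns:
        df = df[df["valid"] == 1]
    df = df[df["dose_category"] == "none"]
    if subgroup is not None:
        df = df[df["group"] == subgroup]
    vals = pd.to_numeric(df[f"score_{outcome}"]).dropna()
    if len(vals) == 0:
        raise ValueError(
            f"no valid zero-dose weeks to anchor the score scale ({outcome}, {subgroup})"
        )
    return float(vals.mean())


def _effect_row(
    contrast: ContrastResult, outcome: str, subgroup: str, level: str, ref: float
) -> dict:
    row = {
        "outcome": outcome,
        "subgroup": subgroup,
        "dose_level": level,
        "beta": contrast.estimate,
        "beta_lo": contrast.ci_lower,
        "beta_hi": contrast.ci_upper,
        "p_value": contrast.p_value,
        "reference_score": ref,
    }
    for src, dst in (("beta", "pct"), ("beta_lo", "pct_lo"), ("beta_hi", "pct_hi")):
        row[dst] = float(pct_improvement(row[src]))
    for src, dst in (("pct", "score"), ("pct_lo", "score_lo"), ("pct_hi", "score_hi")):
        row[dst] = float(score_improvement(row[src], ref))
    return row


def dose_response_table(
    fits: Mapping[str, FitResult], table: pd.DataFrame
) -> pd.DataFrame:
    """Overall dose-response effect table (one primary fit per outcome).

    Each dose level's coefficient is mapped through the percentage and
    score-scale transformations; the no-message reference level is
    emitted as a blank row.
    """
    rows = []
    for outcome, fit in fits.items():
        ref = reference_score(table, outcome)
        rows.append(
            {"outcome": outcome, "subgroup": "overall", "dose_level": "none",
             "reference_score": ref}
        )
        for lvl in DOSE_LEVELS:
            name = f"dose_{lvl}"
            if name not in fit.params.index:
                raise KeyError(f"fit for {outcome!r} lacks coefficient {name!r}")
            c = wald_contrast(fit, {name: 1.0})
            rows.append(_effect_row(c, outcome, "overall", lvl, ref))
    return pd.DataFrame(rows)


def subgroup_table(
    fits: Mapping[str, FitResult],
    table: pd.DataFrame,
    reference_group: str = "HCT",
) -> pd.DataFrame:
    """Per-group dose effects from group x dose interaction fits.

    For the reference group the effect is the bare dose coefficient;
    for the others it is ``dose + dose:group`` via a Wald contrast on
    the joint robust covariance.  Score-scale references are the
    per-subgroup zero-dose means.
    """
    rows = []
    for outcome, fit in fits.items():
        for grp in GROUPS:
            ref = reference_score(table, outcome, subgroup=grp)
            for lvl in DOSE_LEVELS:
                terms = {f"dose_{lvl}": 1.0}
                if grp != reference_group:
                    terms[f"dose_{lvl}:group_{grp}"] = 1.0
                c = wald_contrast(fit, terms)
                rows.append(_effect_row(c, outcome, grp, lvl, ref))
    return pd.DataFrame(rows)


def moderated_curve(
    fit: FitResult,
    dose_level: str,
    moderator: str,
    grid: Iterable[float],
) -> pd.DataFrame:
    """Dose effect as a function of a moderator, with pointwise 95% CI.

    ``effect(m) = beta_dose + eta_dose * m`` where ``eta_dose`` is the
    ``dose_<level>:<moderator>`` interaction coefficient; the CI uses
    the joint robust covariance of the two coefficients.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("moderator grid is empty")
    dose_term = f"dose_{dose_level}"
    inter_term = f"{dose_term}:{moderator}"
    if inter_term not in fit.params.index:
        raise KeyError(
            f"fit lacks interaction term {inter_term!r}; available: "
            f"{[t for t in fit.params.index if ':' in t]}"
        )
    rows = []
    for m in grid:
        c = wald_contrast(fit, {dose_term: 1.0, inter_term: float(m)})
        rows.append(
            {
                "moderator": moderator,
                "dose_level": dose_level,
                "moderator_value": float(m),
                "estimate": c.estimate,
                "ci_lower": c.ci_lower,
                "ci_upper": c.ci_upper,
            }
        )
    return pd.DataFrame(rows)


def default_moderator_grid(
    table: pd.DataFrame, moderator_col: str, n_points: int = 50
) -> np.ndarray:
    """5th-95th percentile grid of the observed moderator."""
    vals = pd.to_numeric(table[moderator_col]).dropna().to_numpy()
    if vals.size == 0:
        raise ValueError(f"no observed values for moderator {moderator_col!r}")
    lo, hi = np.percentile(vals, [5, 95])
    return np.linspace(lo, hi, n_points)


#: Named preset: depression previous-week T-score grid used in the
#: moderated-effect illustration.
DEPRESSION_PREV_SCORE_GRID = (40.0, 50.0, 60.0)
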