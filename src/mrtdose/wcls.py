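"""Weighted-and-centered least squares (WCLS) with cluster-robust variance.

The causal excursion effect of a weekly prompt-dose category on the
log-transformed weekly outcome is estimated by solving a linear
estimating equation with an independence working correlation: point
estimates coincide with pooled (weighted) least squares, and inference
uses the cluster sandwich

    V = B^{-1} M B^{-1},   B = sum_i X_i' W_i X_i,
                           M = sum_i X_i' W_i r_i r_i' W_i X_i,

clustered by participant.  Treatment is encoded as three indicator
columns for low / medium / high weekly dose (no-message weeks are the
reference); the "centered" variant subtracts the known randomization
probability of each category given the week's eligible days, which
makes the estimator robust to misspecified control terms.  Control
covariates follow the trial's analysis: linear week-in-study, sex, and
baseline age.

:class:`WCLSRegressor` is the scikit-learn-style estimator operating on
a numeric design matrix; :func:`build_design` / :func:`fit_wcls` build
that matrix from a weekly analysis table according to a
:class:`ModelSpec`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from mrtdose.synth import DOSE_LEVELS, GROUPS, OUTCOMES
from mrtdose.weekly import category_probabilities

logger = logging.getLogger(__name__)

TREATMENT_COLS = tuple(f"dose_{lvl}" for lvl in DOSE_LEVELS)


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient; offending columns are reported."""


class WCLSRegressor(RegressorMixin, BaseEstimator):
    """Pooled weighted least squares with cluster-robust sandwich variance.

    The design matrix is taken as-is (include your own intercept
    column); ``groups`` passed to :meth:`fit` identifies clusters
    (participants).  Without groups every row is its own cluster and the
    sandwich reduces to the HC0 heteroskedasticity-consistent estimator.

    Parameters
    ----------
    small_sample_correction
        ``False`` (default): plain cluster sandwich, normal reference —
        mirrors standard GEE software output.  ``"mancl-derouen"`` (or
        ``True``): inflate each cluster's residuals by
        ``(I - H_i)^{-1}`` in the meat.  ``"bell-mccaffrey"``: CR2
        adjustment ``(I - H_i)^{-1/2}`` plus per-contrast Satterthwaite
        degrees of freedom for a t reference — the recommended choice
        below ~50 clusters (requires unit weights).

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Solution of the weighted normal equations.
    robust_covariance_ : ndarray of shape (p, p)
        Cluster sandwich covariance of ``coef_``.
    bse_ : ndarray of shape (p,)
        Robust standard errors.
    n_obs_, n_clusters_ : int
    feature_names_in_ : ndarray of str, when fit on a DataFrame.
    residuals_ : ndarray of shape (n,)
    """

    def __init__(self, small_sample_correction: bool | str = False) -> None:
        self.small_sample_correction = small_sample_correction

    def _variant(self) -> str:
        v = self.small_sample_correction
        if v in (False, None, "none"):
            return "none"
        if v in (True, "mancl-derouen", "md"):
            return "mancl-derouen"
        if v in ("bell-mccaffrey", "bm", "cr2"):
            return "bell-mccaffrey"
        raise ValueError(f"unknown small_sample_correction {v!r}")

    def fit(self, X, y, groups=None, sample_weight=None) -> "WCLSRegressor":
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float).ravel()
        if Xa.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = Xa.shape
        if ya.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if n == 0:
            raise ValueError("empty design matrix")
        if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
            raise ValueError("X and y must be finite (drop missing rows first)")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if w.shape[0] != n or np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("sample_weight must be positive and finite per row")
        g = np.arange(n) if groups is None else np.asarray(groups)
        if g.shape[0] != n:
            raise ValueError("groups must have one entry per row")

        rank = np.linalg.matrix_rank(Xa)
        if rank < p:
            names = getattr(self, "feature_names_in_", None)
            bad = self._collinear_columns(Xa)
            if names is not None:
                bad = [names[c] for c in bad]
            raise CollinearDesignError(
                f"design matrix is rank deficient; offending column(s): {bad}"
            )
        Xw = Xa * w[:, None]
        bread = Xa.T @ Xw
        try:
            bread_inv = np.linalg.inv(bread)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank check above
            raise CollinearDesignError("singular bread matrix") from exc
        coef = bread_inv @ (Xw.T @ ya)
        resid = ya - Xa @ coef

        variant = self._variant()
        if variant == "bell-mccaffrey" and not np.allclose(w, w[0]):
            raise ValueError(
                "bell-mccaffrey adjustment is implemented for unit weights only"
            )
        labels, inverse = np.unique(g, return_inverse=True)
        n_clusters = len(labels)
        if n_clusters < 2:
            logger.warning("only %d cluster(s); robust variance unreliable", n_clusters)
        meat = np.zeros((p, p))
        cluster_idx: list[np.ndarray] = []
        bm_adjust: list[np.ndarray] = []
        for ci in range(n_clusters):
            idx = np.where(inverse == ci)[0]
            cluster_idx.append(idx)
            Xi = Xa[idx]
            Wi = w[idx]
            ri = resid[idx]
            if variant == "mancl-derouen":
                Hi = Xi @ bread_inv @ (Xi * Wi[:, None]).T
                ri = np.linalg.solve(np.eye(len(idx)) - Hi, ri)
            elif variant == "bell-mccaffrey":
                Hi = Xi @ bread_inv @ Xi.T
                evals, evecs = np.linalg.eigh(np.eye(len(idx)) - Hi)
                Ai = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
                bm_adjust.append(Ai)
                ri = Ai @ ri
            s = Xi.T @ (Wi * ri)
            meat += np.outer(s, s)
        V = bread_inv @ meat @ bread_inv
        V = (V + V.T) / 2.0

        self.coef_ = coef
        self.robust_covariance_ = V
        self.bse_ = np.sqrt(np.maximum(np.diag(V), 0.0))
        self.n_obs_ = n
        self.n_clusters_ = n_clusters
        self.residuals_ = resid
        self.n_features_in_ = p
        self.inference_variant_ = variant
        self._bm_cache = (
            (Xa, bread_inv, cluster_idx, bm_adjust)
            if variant == "bell-mccaffrey"
            else None
        )
        return self

    def satterthwaite_df(self, contrast: np.ndarray) -> float | None:
        """Bell-McCaffrey Satterthwaite degrees of freedom for L'beta.

        Returns ``None`` unless the estimator was fit with the
        ``bell-mccaffrey`` adjustment.  Uses the homoskedastic
        independent reference distribution for the residual quadratic
        form, per the original proposal.
        """
        if getattr(self, "_bm_cache", None) is None:
            return None
        Xa, bread_inv, cluster_idx, bm_adjust = self._bm_cache
        c = np.asarray(contrast, dtype=float)
        n = Xa.shape[0]
        U = np.zeros((n, len(cluster_idx)))
        bc = bread_inv @ c
        for gi, idx in enumerate(cluster_idx):
            U[idx, gi] = bm_adjust[gi] @ (Xa[idx] @ bc)
        UX = U.T @ Xa
        M = U.T @ U - UX @ bread_inv @ UX.T
        tr = float(np.trace(M))
        tr2 = float(np.trace(M @ M))
        if tr2 <= 0:
            return None
        return tr * tr / tr2

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("WCLSRegressor is not fitted yet")
        return np.asarray(X, dtype=float) @ self.coef_

    @staticmethod
    def _collinear_columns(Xa: np.ndarray) -> list[int]:
        # pivoted QR: columns with negligible R diagonal are redundant
        from scipy.linalg import qr

        _, r, piv = qr(Xa, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xa.shape) * np.finfo(float).eps if diag.size else 0.0
        return sorted(int(c) for c in piv[np.where(diag <= tol)[0]])


@dataclass
class ModelSpec:
    """Configuration of one dose-response model.

    Parameters
    ----------
    outcome
        One of ``strain`` / ``anxiety`` / ``depression``; the response
        is the natural log of that weekly final T score.
    centering
        Subtract the per-row randomization probabilities of each dose
        category (computed from ``eligible_days`` and ``p_rand``) from
        the treatment indicators.
    p_rand
        Daily randomization probability used for centering.
    controls
        Control covariates; the default mirrors the trial analysis
        (linear week-in-study, sex, baseline age).
    moderators
        Dose x moderator interactions to include, names among
        ``group``, ``prev_score``, ``week``, ``steps``, ``sleep``.
        Moderator main effects are added automatically.
    weight_column
        Optional column of per-row positive weights (general WCLS form
        reference-probability / randomization-probability); default 1.
    small_sample_correction
        Use the Mancl-DeRouen corrected sandwich.
    drop_zero_eligible
        Exclude weeks whose dose category had no randomization variance
        (eligible_days = 0).  ``None`` means "only when centering".
    """

    outcome: str = "strain"
    centering: bool = False
    p_rand: float = 0.5
    controls: tuple[str, ...] = ("week_index", "sex", "baseline_age")
    moderators: tuple[str, ...] = ()
    weight_column: str | None = None
    small_sample_correction: bool | str = False
    drop_zero_eligible: bool | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        unknown = set(self.moderators) - {"group", "prev_score", "week", "steps", "sleep"}
        if unknown:
            raise ValueError(f"unknown moderator(s): {sorted(unknown)}")

    def moderator_column(self, name: str) -> str:
        return {
            "prev_score": f"prev_score_{self.outcome}",
            "week": "week_index",
            "steps": "mean_steps",
            "sleep": "mean_sleep",
        }[name]


@dataclass
class ContrastResult:
    """A linear combination of coefficients with Wald inference.

    ``df`` is the Satterthwaite degrees of freedom when the fit used
    the Bell-McCaffrey adjustment; ``None`` means a normal reference.
    """

    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    df: float | None = None


@dataclass
class FitResult:
    """Fitted WCLS model: named coefficients plus robust covariance."""

    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    n_dropped: int = 0
    spec: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None
    #: the fitted estimator (in-memory only, not serialized); needed for
    #: Satterthwaite degrees of freedom under the Bell-McCaffrey variant
    estimator: "WCLSRegressor | None" = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.vcov.to_numpy()), 0.0)),
            index=self.params.index,
        )

    def contrast_vector(self, terms: dict[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(terms, dict):
            L = np.zeros(len(self.params))
            for name, val in terms.items():
                if name not in self.params.index:
                    raise KeyError(f"term {name!r} not in fit: {list(self.params.index)}")
                L[self.params.index.get_loc(name)] = val
            return L
        L = np.asarray(terms, dtype=float)
        if L.shape != (len(self.params),):
            raise ValueError("contrast length must equal the coefficient length")
        return L

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "vcov": {
                "columns": list(self.vcov.columns),
                "values": self.vcov.to_numpy().tolist(),
            },
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "n_dropped": int(self.n_dropped),
            "spec": self.spec,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        cols = d["vcov"]["columns"]
        return cls(
            params=pd.Series(d["params"]),
            vcov=pd.DataFrame(np.asarray(d["vcov"]["values"]), index=cols, columns=cols),
            n_obs=d["n_obs"],
            n_clusters=d["n_clusters"],
            n_dropped=d.get("n_dropped", 0),
            spec=d.get("spec", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_design(
    spec: ModelSpec, table: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, np.ndarray]:
    """Build (response, design, weights, cluster ids) from a weekly table.

    The response is ``log(score_<outcome>)``.  Columns are ordered
    intercept, controls, moderator main effects, treatment indicators,
    interactions — deterministically, for reproducible serialization.
    Rows with a missing value in any required column are dropped (count
    logged and recorded on the subsequent fit).
    """
    df = table
    if "valid" in df.columns:
        df = df[df["valid"] == 1]
    drop_zero = spec.drop_zero_eligible
    if drop_zero is None:
        drop_zero = spec.centering
    if drop_zero:
        df = df[df["eligible_days"] > 0]
    df = df.reset_index(drop=True)

    score_col = f"score_{spec.outcome}"
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for ctrl in spec.controls:
        if ctrl == "sex":
            cols["sex_male"] = (df["sex"].astype(str) == "male").astype(float).to_numpy()
        else:
            cols[ctrl] = pd.to_numeric(df[ctrl]).to_numpy(dtype=float)
    needs_group = "group" in spec.moderators
    if needs_group:
        for g in GROUPS:
            if g == "HCT":  # reference group
                continue
            cols[f"group_{g}"] = (df["group"].astype(str) == g).astype(float).to_numpy()
    mod_cols: list[str] = []
    for m in spec.moderators:
        if m == "group":
            continue
        c = spec.moderator_column(m)
        if c not in cols:
            cols[c] = pd.to_numeric(df[c]).to_numpy(dtype=float)
        mod_cols.append(c)

    cat = df["dose_category"].astype(str).to_numpy()
    ind = {lvl: (cat == lvl).astype(float) for lvl in DOSE_LEVELS}
    if spec.centering:
        elig = df["eligible_days"].to_numpy(dtype=int)
        probs = np.array(
            [category_probabilities(d, spec.p_rand) for d in np.arange(7)]
        )  # lookup by eligible days
        for j, lvl in enumerate(DOSE_LEVELS, start=1):
            cols[f"dose_{lvl}"] = ind[lvl] - probs[elig, j]
    else:
        for lvl in DOSE_LEVELS:
            cols[f"dose_{lvl}"] = ind[lvl]

    for m in spec.moderators:
        if m == "group":
            for g in GROUPS:
                if g == "HCT":
                    continue
                for lvl in DOSE_LEVELS:
                    cols[f"dose_{lvl}:group_{g}"] = (
                        cols[f"dose_{lvl}"] * cols[f"group_{g}"]
                    )
        else:
            c = spec.moderator_column(m)
            for lvl in DOSE_LEVELS:
                cols[f"dose_{lvl}:{c}"] = cols[f"dose_{lvl}"] * cols[c]

    X = pd.DataFrame(cols, index=df.index)
    y_raw = pd.to_numeric(df[score_col]).to_numpy(dtype=float)
    if np.any(y_raw[np.isfinite(y_raw)] <= 0):
        raise ValueError(f"{score_col} must be strictly positive for the log transform")
    y = pd.Series(np.log(y_raw), index=df.index, name=f"log_{score_col}")
    w = (
        pd.to_numeric(df[spec.weight_column]).to_numpy(dtype=float)
        if spec.weight_column
        else np.ones(len(df))
    )
    groups = df["participant_id"].to_numpy()

    keep = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y.to_numpy()) & np.isfinite(w)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "build_design(%s): dropped %d of %d rows with missing values",
            spec.outcome, n_dropped, len(df),
        )
    X, y, w, groups = X[keep], y[keep], w[keep], groups[keep]
    if len(X) == 0:
        raise ValueError("no complete rows remain after filtering")
    X.attrs["n_dropped"] = n_dropped
    return y, X, w, groups


def fit_wcls(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit the dose-response model defined by *spec* on a weekly table."""
    y, X, w, groups = build_design(spec, table)
    n_clusters = len(np.unique(groups))
    n_treat = sum(c.startswith("dose_") for c in X.columns)
    if n_clusters < n_treat:
        logger.warning(
            "only %d clusters for %d treatment columns; inference unreliable",
            n_clusters, n_treat,
        )
    est = WCLSRegressor(small_sample_correction=spec.small_sample_correction)
    est.fit(X, y, groups=groups, sample_weight=w)
    names = list(X.columns)
    return FitResult(
        params=pd.Series(est.coef_, index=names),
        vcov=pd.DataFrame(est.robust_covariance_, index=names, columns=names),
        n_obs=est.n_obs_,
        n_clusters=est.n_clusters_,
        n_dropped=X.attrs.get("n_dropped", 0),
        spec=dataclasses.asdict(spec),
        residuals=est.residuals_,
        estimator=est,
    )


def wald_contrast(
    fit: FitResult, combination: dict[str, float] | Sequence[float]
) -> ContrastResult:
    """Wald inference for a linear combination L'beta of fitted coefficients.

    Two-sided p-value and 95% CI; normal (z) reference by default, a
    Satterthwaite-t reference when the fit used the Bell-McCaffrey
    adjustment and the in-memory estimator is available.
    """
    L = fit.contrast_vector(combination)
    est = float(L @ fit.params.to_numpy())
    var = float(L @ fit.vcov.to_numpy() @ L)
    if not np.isfinite(var) or var < 0:
        raise ValueError(f"non-finite contrast variance: {var!r}")
    se = float(np.sqrt(var))
    df = fit.estimator.satterthwaite_df(L) if fit.estimator is not None else None
    crit = float(stats.t.ppf(0.975, df)) if df else float(stats.norm.ppf(0.975))
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
    elif df:
        p = float(2.0 * stats.t.sf(abs(est) / se, df))
    else:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    return ContrastResult(
        estimate=est,
        se=se,
        ci_lower=est - crit * se,
        ci_upper=est + crit * se,
        p_value=p,
        df=df,
    )
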