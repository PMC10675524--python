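"""Mixed-model condition contrasts with influence-based exclusion.

Fits a linear mixed-effects model to trial-wise responses from the 2 x 2
emotion-by-presentation design, with "subject" as the grouping factor and
treatment coding against the Negative / Video reference cells:

    response ~ 1 + emo * pres + (random structure | subject)

The random structure is chosen by parsimonious forward comparison (intercept;
+ emotion slope; + presentation slope; + interaction slope), stopping when the
more complex model is no longer significantly superior by likelihood-ratio
test or produces a singular/non-converged fit. Influence diagnostics follow
the standard multilevel workflow: trial-level standardized conditional
residuals and Cook's distances (via GLS whitening under the estimated
covariance), then subject-level Cook's distances from leave-one-subject-out
refits; flagged rows/subjects are excluded and the model refitted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .design import GroundTruthParams, SessionDesign
from .preprocess import PreprocParams
from .responses import ResponseWindows, response_pairs
from .synthetic import simulate_cohort

FE_NAMES = ("Intercept", "emo", "pres", "emo:pres")

#: Ordered candidate random structures for forward selection.
RANDOM_CANDIDATES = ("1", "1 + emo", "1 + emo + pres", "1 + emo + pres + emo:pres")


class ModelFitError(RuntimeError):
    """Raised when the base mixed model cannot be fitted."""


@dataclass(frozen=True)
class ExclusionRule:
    """Influence-based exclusion thresholds.

    Trials with |standardized conditional residual| > ``resid_abs_threshold``
    or Cook's distance above Q3 + ``cooks_iqr_factor`` x IQR of the trial
    Cook's distances are excluded; with ``subject_level_check`` the same
    boxplot rule is applied to leave-one-subject-out Cook's distances.
    """

    resid_abs_threshold: float = 3.0
    cooks_iqr_factor: float = 1.5
    subject_level_check: bool = True

    def __post_init__(self) -> None:
        if self.resid_abs_threshold <= 0 or self.cooks_iqr_factor <= 0:
            raise ValueError("exclusion thresholds must be positive")


def _prepare(data: pd.DataFrame, response, subject, emotion, presentation) -> pd.DataFrame:
    df = data[[subject, emotion, presentation, response]].copy()
    df.columns = ["subject", "emotion", "presentation", "response"]
    df = df[np.isfinite(df["response"])]
    # treatment coding with Negative / Video as reference levels
    df["emo"] = (df["emotion"] == "positive").astype(float)
    df["pres"] = (df["presentation"] == "live").astype(float)
    return df.reset_index(drop=True)


def _n_cov_params(re_formula: str) -> int:
    k = re_formula.count("+") + 1
    return k * (k + 1) // 2


@dataclass
class SelectionStep:
    re_formula: str
    llf: float | None
    converged: bool
    singular: bool
    lr_stat: float | None = None
    lr_pvalue: float | None = None
    accepted: bool = False


class ConditionContrastModel:
    """Linear mixed model for 2 x 2 condition contrasts of trial responses.

    Parameters
    ----------
    data : DataFrame
        Trial-level table with subject, emotion (positive/negative),
        presentation (live/video) and the response column.
    response : str
        Name of the response column (e.g. ``"au12_response"``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        subject: str = "subject",
        emotion: str = "emotion",
        presentation: str = "presentation",
    ):
        self.data = _prepare(data, response, subject, emotion, presentation)
        if self.data["subject"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        self.response_name = response

    # -- fitting ---------------------------------------------------------

    def _fit_one(self, df: pd.DataFrame, re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                "response ~ emo * pres",
                groups="subject",
                re_formula=re_formula,
                data=df,
            )
            fit = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    cand = model.fit(reml=True, method=method, maxiter=500)
                except Exception:
                    continue
                fit = cand
                if getattr(cand, "converged", False) and np.isfinite(cand.llf):
                    break
            if fit is None:
                return None, False, True
        converged = bool(getattr(fit, "converged", False))
        cov = np.atleast_2d(np.asarray(fit.cov_re, dtype=float))
        eig = np.linalg.eigvalsh(cov)
        singular = bool(eig.min() <= 1e-10 * max(eig.max(), 1.0) or not np.isfinite(fit.llf))
        return fit, converged, singular

    def fit(
        self,
        select_random: bool = True,
        alpha: float = 0.05,
        re_formula: str = "1",
    ) -> "ConditionContrastResults":
        """Fit the model, optionally with forward random-structure selection.

        With ``select_random`` the candidates in :data:`RANDOM_CANDIDATES`
        are compared stepwise by REML likelihood-ratio test at ``alpha``;
        otherwise ``re_formula`` is used directly.
        """
        df = self.data
        steps: list[SelectionStep] = []
        if not select_random:
            fit, converged, singular = self._fit_one(df, re_formula)
            if fit is None or not converged:
                raise ModelFitError(
                    f"mixed model with re_formula={re_formula!r} failed to converge "
                    f"(n={len(df)}, subjects={df['subject'].nunique()})"
                )
            steps.append(SelectionStep(re_formula, fit.llf, converged, singular, accepted=True))
            return ConditionContrastResults(self, fit, re_formula, steps, alpha)

        best_fit = None
        best_formula = None
        for cand in RANDOM_CANDIDATES:
            fit, converged, singular = self._fit_one(df, cand)
            step = SelectionStep(
                cand, None if fit is None else fit.llf, converged, singular
            )
            if fit is None or not converged:
                steps.append(step)
                break
            if best_fit is None:
                # base model: accept even when singular (zero variance
                # components are legitimate under a null generator), but do
                # not grow the structure from a singular base
                step.accepted = True
                best_fit, best_formula = fit, cand
                steps.append(step)
                if singular:
                    break
                continue
            if singular:
                steps.append(step)
                break
            lr = 2.0 * (fit.llf - best_fit.llf)
            ddf = _n_cov_params(cand) - _n_cov_params(best_formula)
            p = float(stats.chi2.sf(max(lr, 0.0), ddf))
            step.lr_stat = float(lr)
            step.lr_pvalue = p
            if p < alpha and lr > 0:
                step.accepted = True
                best_fit, best_formula = fit, cand
                steps.append(step)
            else:
                steps.append(step)
                break
        if best_fit is None:
            raise ModelFitError(
                "base random-intercept model failed to converge "
                f"(n={len(df)}, subjects={df['subject'].nunique()})"
            )
        return ConditionContrastResults(self, best_fit, best_formula, steps, alpha)

    def fit_with_exclusion(
        self,
        rule: ExclusionRule | None = None,
        select_random: bool = True,
        alpha: float = 0.05,
    ) -> tuple["ConditionContrastResults", "ExclusionReport"]:
        """Fit, apply influence-based exclusion, and refit once."""
        rule = rule if rule is not None else ExclusionRule()
        first = self.fit(select_random=select_random, alpha=alpha)
        retained, excluded_trials, excluded_subjects = influence_exclude(first, rule)
        report = ExclusionReport(
            n_input=len(self.data),
            n_retained=len(retained),
            excluded_trials=excluded_trials,
            excluded_subjects=excluded_subjects,
            re_formula=first.re_formula,
        )
        if len(excluded_trials) == 0 and len(excluded_subjects) == 0:
            return first, report
        refit_model = ConditionContrastModel.__new__(ConditionContrastModel)
        refit_model.data = retained.reset_index(drop=True)
        refit_model.response_name = self.response_name
        final = refit_model.fit(select_random=False, re_formula=first.re_formula, alpha=alpha)
        return final, report


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    excluded_trials: pd.Index
    excluded_subjects: list
    re_formula: str


class ConditionContrastResults:
    """Results wrapper exposing fixed effects, contrasts and diagnostics.

    P-values use t with residual degrees of freedom (N - 4); the underlying
    statsmodels fit is available as ``.mixedlm`` for Wald-z inference.
    """

    def __init__(self, model, mixedlm_results, re_formula, selection_steps, alpha):
        self.model = model
        self.mixedlm = mixedlm_results
        self.re_formula = re_formula
        self.selection_steps = selection_steps
        self.alpha = alpha
        self.n_obs = len(model.data)
        self.df_resid = self.n_obs - len(FE_NAMES)

    @property
    def fe_params(self) -> pd.Series:
        return self.mixedlm.fe_params

    @property
    def bse(self) -> pd.Series:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.mixedlm.bse_fe

    @property
    def tvalues(self) -> pd.Series:
        return self.fe_params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        return pd.Series(
            2.0 * stats.t.sf(np.abs(t.to_numpy()), self.df_resid), index=t.index
        )

    @property
    def scale(self) -> float:
        return float(self.mixedlm.scale)

    def fixed_effects_table(self) -> pd.DataFrame:
        t = self.tvalues
        ci = stats.t.ppf(0.975, self.df_resid) * self.bse
        return pd.DataFrame(
            {
                "estimate": self.fe_params,
                "se": self.bse,
                "df": float(self.df_resid),
                "ci_lower": self.fe_params - ci,
                "ci_upper": self.fe_params + ci,
                "t": t,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Condition-contrast mixed model: {self.model.response_name}",
            f"random structure: ({self.re_formula} | subject)   "
            f"N={self.n_obs}  subjects={self.model.data['subject'].nunique()}",
            "=" * 72,
            self.fixed_effects_table().to_string(float_format=lambda v: f"{v: .4g}"),
            "-" * 72,
            "Simple effects (cell means and contrasts):",
            self.simple_effects().to_string(float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)

    # -- simple effects --------------------------------------------------

    def _fe_cov(self) -> np.ndarray:
        cov = self.mixedlm.cov_params()
        names = list(self.fe_params.index)
        if isinstance(cov, pd.DataFrame):
            return cov.loc[names, names].to_numpy()
        return np.asarray(cov)[: len(names), : len(names)]

    def simple_effects(self) -> pd.DataFrame:
        """Estimated marginal cell means and the four simple-effect contrasts.

        Cells: PL, PV, NL, NV (positive/negative x live/video); contrasts
        PL-PV and NL-NV (live effect within emotion), PL-NL and PV-NV
        (emotion effect within presentation). t and p use residual df.
        """
        beta = self.fe_params.to_numpy()
        cov = self._fe_cov()
        # design rows in (Intercept, emo, pres, emo:pres) order
        cells = {
            "PL": np.array([1.0, 1.0, 1.0, 1.0]),
            "PV": np.array([1.0, 1.0, 0.0, 0.0]),
            "NL": np.array([1.0, 0.0, 1.0, 0.0]),
            "NV": np.array([1.0, 0.0, 0.0, 0.0]),
        }
        contrasts = {
            "PL-PV": cells["PL"] - cells["PV"],
            "NL-NV": cells["NL"] - cells["NV"],
            "PL-NL": cells["PL"] - cells["NL"],
            "PV-NV": cells["PV"] - cells["NV"],
        }
        tcrit = stats.t.ppf(0.975, self.df_resid)
        rows = []
        for name, L in {**cells, **contrasts}.items():
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            tval = est / se if se > 0 else np.nan
            p = float(2.0 * stats.t.sf(abs(tval), self.df_resid)) if se > 0 else np.nan
            rows.append(
                {
                    "term": name,
                    "kind": "cell" if name in cells else "contrast",
                    "estimate": est,
                    "se": se,
                    "df": float(self.df_resid),
                    "ci_lower": est - tcrit * se,
                    "ci_upper": est + tcrit * se,
                    "t": tval,
                    "p": p,
                }
            )
        return pd.DataFrame(rows).set_index("term")


# -- influence diagnostics ----------------------------------------------


def _group_blocks(results: ConditionContrastResults):
    """Yield (row_indices, X_j, Z_j, y_j) per subject, in data order."""
    m = results.mixedlm.model
    X = np.asarray(m.exog, dtype=float)
    Z = np.asarray(m.exog_re, dtype=float)
    y = np.asarray(m.endog, dtype=float)
    groups = np.asarray(m.groups)
    for g in pd.unique(groups):
        idx = np.nonzero(groups == g)[0]
        yield g, idx, X[idx], Z[idx], y[idx]


def conditional_residuals(results: ConditionContrastResults) -> np.ndarray:
    """y - X b - Z u, using the estimated (BLUP) random effects."""
    m = results.mixedlm.model
    beta = results.fe_params.to_numpy()
    re = results.mixedlm.random_effects
    out = np.empty(len(m.endog))
    for g, idx, Xj, Zj, yj in _group_blocks(results):
        u = np.asarray(re[g], dtype=float)
        out[idx] = yj - Xj @ beta - Zj @ u
    return out


def standardized_residuals(results: ConditionContrastResults) -> np.ndarray:
    """Conditional residuals divided by the estimated residual SD."""
    return conditional_residuals(results) / np.sqrt(results.scale)


def trial_cooks_distance(results: ConditionContrastResults) -> np.ndarray:
    """Per-trial Cook's distance for the fixed effects.

    Computed from the whitened (GLS) representation under the estimated
    marginal covariance V_j = Z_j G Z_j' + sigma^2 I per subject, using the
    standard OLS influence formula on the whitened design.
    """
    cov_re = np.atleast_2d(np.asarray(results.mixedlm.cov_re, dtype=float))
    sigma2 = results.scale
    beta = results.fe_params.to_numpy()
    Xw_parts, yw_parts, order = [], [], []
    for _g, idx, Xj, Zj, yj in _group_blocks(results):
        Vj = Zj @ cov_re @ Zj.T + sigma2 * np.eye(len(idx))
        L = np.linalg.cholesky(Vj)
        Xw_parts.append(np.linalg.solve(L, Xj))
        yw_parts.append(np.linalg.solve(L, yj))
        order.append(idx)
    Xw = np.vstack(Xw_parts)
    yw = np.concatenate(yw_parts)
    order = np.concatenate(order)
    p = Xw.shape[1]
    XtXi = np.linalg.inv(Xw.T @ Xw)
    h = np.einsum("ij,jk,ik->i", Xw, XtXi, Xw)
    e = yw - Xw @ beta
    s2 = float(e @ e) / max(len(yw) - p, 1)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    d = (e**2 * h) / (p * s2 * (1.0 - h) ** 2)
    out = np.empty_like(d)
    out[order] = d
    return out


def subject_cooks_distance(
    results: ConditionContrastResults, model: ConditionContrastModel | None = None
) -> pd.Series:
    """Leave-one-subject-out Cook's distance for the fixed effects.

    D_j = (beta - beta_(-j))' Cov(beta)^-1 (beta - beta_(-j)) / p, with each
    beta_(-j) obtained by a brute-force refit without subject j under the
    selected random structure.
    """
    model = model if model is not None else results.model
    beta = results.fe_params.to_numpy()
    cov_inv = np.linalg.pinv(results._fe_cov())
    p = len(beta)
    out = {}
    for subj in pd.unique(model.data["subject"]):
        sub = model.data[model.data["subject"] != subj]
        m = ConditionContrastModel.__new__(ConditionContrastModel)
        m.data = sub.reset_index(drop=True)
        m.response_name = model.response_name
        fit, converged, _sing = m._fit_one(m.data, results.re_formula)
        if fit is None or not converged:
            out[subj] = np.nan
            continue
        diff = beta - fit.fe_params.to_numpy()
        out[subj] = float(diff @ cov_inv @ diff) / p
    return pd.Series(out, name="cooks_distance")


def _boxplot_upper(x: np.ndarray, factor: float) -> float:
    q1, q3 = np.nanpercentile(x, [25, 75])
    return q3 + factor * (q3 - q1)


def influence_exclude(
    results: ConditionContrastResults, rule: ExclusionRule | None = None
) -> tuple[pd.DataFrame, pd.Index, list]:
    """Apply the trial- and subject-level exclusion rules.

    Returns (retained data, excluded trial row index, excluded subjects).
    Aborts if more than half of the data would be excluded, which signals a
    mis-specified model rather than a few influential points.
    """
    rule = rule if rule is not None else ExclusionRule()
    df = results.model.data
    std_res = standardized_residuals(results)
    cooks = trial_cooks_distance(results)
    cut = _boxplot_upper(cooks, rule.cooks_iqr_factor)
    bad_trial = (np.abs(std_res) > rule.resid_abs_threshold) | (cooks > cut)

    excluded_subjects: list = []
    if rule.subject_level_check:
        d_subj = subject_cooks_distance(results)
        s_cut = _boxplot_upper(d_subj.to_numpy(), rule.cooks_iqr_factor)
        excluded_subjects = [s for s, v in d_subj.items() if np.isfinite(v) and v > s_cut]

    drop = bad_trial | df["subject"].isin(excluded_subjects).to_numpy()
    if drop.sum() > 0.5 * len(df):
        raise ModelFitError(
            f"influence exclusion would remove {int(drop.sum())} of {len(df)} trials; "
            "check model specification"
        )
    retained = df[~drop]
    excluded_trials = df.index[bad_trial]
    return retained, excluded_trials, excluded_subjects


# -- simulation-based power ----------------------------------------------


@dataclass
class PowerResult:
    """Power-by-simulation output."""

    power: dict[int, float]
    minimal_n: int | None
    reps: int
    alpha: float
    target: float = 0.8

    def mc_se(self, n: int) -> float:
        p = self.power[n]
        return float(np.sqrt(p * (1 - p) / self.reps))

    def summary(self) -> str:
        lines = [f"Interaction power by simulation ({self.reps} reps, alpha={self.alpha})"]
        for n in sorted(self.power):
            lines.append(f"  n={n:4d}  power={self.power[n]:.3f}  (MC SE {self.mc_se(n):.3f})")
        lines.append(
            f"minimal n reaching {self.target:.0%}: "
            + (str(self.minimal_n) if self.minimal_n is not None else "none in grid")
        )
        return "\n".join(lines)


def power_by_simulation(
    params: GroundTruthParams,
    n_grid: list[int],
    reps: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    design: SessionDesign | None = None,
    response: str = "zm_response",
    target: float = 0.8,
) -> PowerResult:
    """Estimate interaction power per sample size by cohort simulation.

    For each n in ``n_grid``, ``reps`` cohorts are generated through the full
    signal-level pipeline (simulate, preprocess, extract responses) and the
    emotion-by-presentation interaction is tested in a mixed model with the
    generator's random structure (intercept + emotion slope). Power is the
    fraction of replicates with p < alpha.

    The template ``design`` fixes trials_per_condition and sampling rates;
    its n_subjects is replaced by each grid value.
    """
    base = design if design is not None else SessionDesign()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    preproc = PreprocParams.for_rate(base.emg_rate_hz)
    windows = ResponseWindows()
    power: dict[int, float] = {}
    for n in n_grid:
        d = replace(base, n_subjects=n)
        hits = 0
        for _ in range(reps):
            child = int(rng.integers(0, 2**31 - 1))
            trials = simulate_cohort(d, params, seed=child)
            pairs = response_pairs(trials, preproc=preproc, windows=windows)
            try:
                res = ConditionContrastModel(pairs, response).fit(
                    select_random=False, re_formula="1 + emo"
                )
                p = float(res.pvalues["emo:pres"])
            except ModelFitError:
                continue
            if p < alpha:
                hits += 1
        power[n] = hits / reps
    minimal = None
    for n in sorted(power):
        if power[n] >= target:
            minimal = n
            break
    return PowerResult(power=power, minimal_n=minimal, reps=reps, alpha=alpha, target=target)
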