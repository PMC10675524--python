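"""Repeated-measures correlation.

Models the common within-subject association between two repeatedly measured
variables with a subject-specific intercept and a shared slope:

    y_ij = alpha_i + beta * x_ij + e_ij

The repeated-measures correlation coefficient is

    r_rm = sign(beta) * sqrt(SS_x / (SS_x + SS_e)),   df = N - k - 1

with N observations from k subjects, SS_x the sum of squares explained by the
common slope and SS_e the residual sum of squares. Algebraically r_rm equals
the Pearson correlation of the subject-mean-centered variables. Confidence
intervals come from a cluster bootstrap that resamples subjects with
replacement, keeping each subject's trials intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RmcorrResults:
    """Fitted repeated-measures correlation."""

    r: float
    df: int
    pvalue: float
    slope: float
    n_obs: int
    n_subjects: int
    ci95: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    n_redrawn: int = 0
    dropped_subjects: tuple = ()

    def summary(self) -> str:
        lines = [
            "Repeated-measures correlation",
            "=" * 45,
            f"r        {self.r: .4f}",
            f"df       {self.df}",
            f"p        {self.pvalue:.3e}",
            f"N obs    {self.n_obs}   subjects {self.n_subjects}",
        ]
        if self.ci95 is not None:
            lines.append(
                f"95% CI   ({self.ci95[0]:.3f}, {self.ci95[1]:.3f})"
                f"   [cluster bootstrap, {self.n_boot} resamples]"
            )
        if self.dropped_subjects:
            lines.append(f"dropped subjects (<2 obs): {list(self.dropped_subjects)}")
        return "\n".join(lines)


def _centered(x: np.ndarray, y: np.ndarray, codes: np.ndarray, k: int):
    """Subject-mean-centered copies of x and y."""
    cnt = np.bincount(codes, minlength=k).astype(float)
    mx = np.bincount(codes, weights=x, minlength=k) / cnt
    my = np.bincount(codes, weights=y, minlength=k) / cnt
    return x - mx[codes], y - my[codes]


def _r_centered(x: np.ndarray, y: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Fast r via the subject-centering identity (used inside the bootstrap)."""
    xc, yc = _centered(x, y, codes, k)
    den = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc))
    if den == 0:
        return np.nan
    return float(np.sum(xc * yc) / den)


class RepeatedMeasuresCorr:
    """Repeated-measures correlation model.

    Parameters
    ----------
    x, y : array-like
        Paired trial-level measurements (e.g. ZM EMG response and AU12
        response).
    subjects : array-like
        Subject identifier per observation.

    Subjects contributing fewer than two complete observations cannot inform
    a within-subject slope and are dropped with a warning; rows with
    non-finite values are removed first.
    """

    def __init__(self, x, y, subjects):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        subjects = np.asarray(subjects)
        if not (len(x) == len(y) == len(subjects)):
            raise ValueError("x, y and subjects must have equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y, subjects = x[ok], y[ok], subjects[ok]

        uniq, codes = np.unique(subjects, return_inverse=True)
        counts = np.bincount(codes)
        small = uniq[counts < 2]
        if small.size:
            warnings.warn(
                f"dropping {small.size} subject(s) with fewer than 2 observations",
                stacklevel=2,
            )
            keep = ~np.isin(subjects, small)
            x, y, subjects = x[keep], y[keep], subjects[keep]
            uniq, codes = np.unique(subjects, return_inverse=True)
        if uniq.size < 2:
            raise ValueError("need at least 2 subjects with >= 2 observations each")
        self.x = x
        self.y = y
        self.subjects = subjects
        self._codes = codes
        self._uniq = uniq
        self.dropped_subjects = tuple(small.tolist())

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        x: str = "emg_response",
        y: str = "au_response",
        subject: str = "subject",
    ) -> "RepeatedMeasuresCorr":
        return cls(data[x], data[y], data[subject])

    # -- estimation ------------------------------------------------------

    def _anova_fit(self) -> tuple[float, float, float, int]:
        """Subject-dummy OLS fit: returns (r, slope, pvalue, df)."""
        n = len(self.x)
        k = self._uniq.size
        # Full model: y ~ subject dummies + x
        D = np.zeros((n, k + 1))
        D[np.arange(n), self._codes] = 1.0
        D[:, k] = self.x
        beta, _, rank, _ = np.linalg.lstsq(D, self.y, rcond=None)
        resid = self.y - D @ beta
        ss_err = float(resid @ resid)
        # Reduced model: y ~ subject dummies (residuals = within-subject dev.)
        _, yc = _centered(self.x, self.y, self._codes, k)
        ss_red = float(yc @ yc)
        ss_x = max(ss_red - ss_err, 0.0)
        df = n - k - 1
        if df <= 0:
            raise ValueError("non-positive error degrees of freedom")
        denom = ss_x + ss_err
        r = 0.0 if denom == 0 else np.sqrt(ss_x / denom)
        slope = float(beta[k])
        r = float(np.copysign(r, slope)) if slope != 0 else float(r)
        if ss_err == 0:
            p = 0.0 if ss_x > 0 else 1.0
        else:
            f = ss_x / (ss_err / df)
            p = float(stats.f.sf(f, 1, df))
        return r, slope, p, df

    def fit(self, n_boot: int = 0, seed: int | None = None) -> RmcorrResults:
        """Estimate the correlation; optionally bootstrap a 95% CI.

        ``n_boot`` subject-level (cluster) resamples; deterministic given
        ``seed``. The conventional choice for a stable percentile interval is
        10,000 resamples.
        """
        r, slope, p, df = self._anova_fit()
        res = RmcorrResults(
            r=r,
            df=df,
            pvalue=p,
            slope=slope,
            n_obs=len(self.x),
            n_subjects=self._uniq.size,
            dropped_subjects=self.dropped_subjects,
        )
        if n_boot > 0:
            res.ci95, res.n_redrawn = self._bootstrap_ci(n_boot, seed)
            res.n_boot = n_boot
            res.seed = seed
        return res

    def _bootstrap_ci(self, n_boot: int, seed: int | None):
        """Percentile 2.5/97.5 interval of r over subject resamples."""
        rng = np.random.default_rng(seed)
        k = self._uniq.size
        by_subj = [np.nonzero(self._codes == c)[0] for c in range(k)]
        rs = np.empty(n_boot)
        redrawn = 0
        for b in range(n_boot):
            for _attempt in range(100):
                pick = rng.integers(0, k, size=k)
                idx = np.concatenate([by_subj[c] for c in pick])
                codes = np.repeat(np.arange(k), [len(by_subj[c]) for c in pick])
                rb = _r_centered(self.x[idx], self.y[idx], codes, k)
                if np.isfinite(rb):
                    break
                redrawn += 1  # degenerate resample (zero within-subject variance)
            rs[b] = rb
        lo, hi = np.percentile(rs, [2.5, 97.5])
        return (float(lo), float(hi)), redrawn
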