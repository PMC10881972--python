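"""Multiple-testing and logistic-LRT helpers shared by the analysis stages."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["bh_adjust", "bonferroni_adjust", "logit_lrt"]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg FDR; NaNs propagate and do not enter the family."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def bonferroni_adjust(p: np.ndarray | pd.Series, n_tested: int | None = None
                      ) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = n_tested if n_tested is not None else int((~np.isnan(p)).sum())
    return np.minimum(1.0, p * n)


def logit_lrt(y: np.ndarray, x: np.ndarray, covariates: pd.DataFrame | None = None
              ) -> tuple[float, float, str]:
    """Likelihood-ratio test (1 df) for ``x`` in  y ~ x + covariates.

    Returns (coefficient, p, flag); flag is '' on success, 'separation' when
    the fit is degenerate (p is NaN then, never 0), 'constant' when x or y
    has no variation.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2 or np.ptp(x) == 0:
        return np.nan, np.nan, "constant"
    parts = [np.ones(len(y))]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(np.asarray(covariates, dtype=float))
    X_red = np.column_stack(parts)
    X_full = np.column_stack([X_red, x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_full = sm.Logit(y, X_full).fit(disp=0, maxiter=35)
            coef = float(m_full.params[-1])
            if not np.isfinite(m_full.llf) or abs(coef) > 25:
                return coef, np.nan, "separation"
            m_red = sm.Logit(y, X_red).fit(disp=0, maxiter=35)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return np.nan, np.nan, "separation"
    if not np.isfinite(m_red.llf):
        return coef, np.nan, "separation"
    lr = 2.0 * (m_full.llf - m_red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return coef, p, ""
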