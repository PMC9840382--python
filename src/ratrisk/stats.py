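"""Repeated-measures ANOVA with two within-subject factors, with Mauchly's
sphericity test and Greenhouse-Geisser correction per effect.

Implemented here because the established Python routines offer
Greenhouse-Geisser correction only for a single within factor, while the
stability criterion for block-wise choice data needs it for a session x block
design.  F ratios agree with statsmodels' AnovaRM (tested); the
Greenhouse-Geisser epsilon follows the standard orthonormal-contrast form
eps = tr(E)^2 / (d * tr(E^2)) with E = M S M' for the effect's contrast M and
the subjects' cell covariance S.

When the covariance matrix is rank-deficient (fewer subjects than effect df),
Mauchly's statistic is undefined; the correction is then applied
unconditionally (conservative) and the Mauchly p reported as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the space orthogonal to the constant."""
    return linalg.null_space(np.ones((1, k)))


def _gg_epsilon(S: np.ndarray, M: np.ndarray) -> float:
    E = M @ S @ M.T
    d = E.shape[0]
    tr = np.trace(E)
    denom = d * np.sum(E * E)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _mauchly(S: np.ndarray, M: np.ndarray, n: int) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value; (nan, nan) when undefined."""
    E = M @ S @ M.T
    d = E.shape[0]
    if d < 2:
        return 1.0, 1.0
    if n - 1 <= d or np.trace(E) <= 0:
        return np.nan, np.nan
    sign, logdet = np.linalg.slogdet(E)
    if sign <= 0:
        return np.nan, np.nan
    logW = logdet - d * np.log(np.trace(E) / d)
    W = float(np.exp(logW))
    c = (2 * d**2 + d + 2) / (6 * d * (n - 1))
    chi2 = -(n - 1) * (1 - c) * logW
    dof = d * (d + 1) / 2 - 1
    return W, float(sps.chi2.sf(chi2, dof))


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-within-factor repeated-measures ANOVA on a balanced long table.

    Returns one row per effect (A, B, A*B) with uncorrected and
    Greenhouse-Geisser-corrected p-values, Mauchly's test, partial eta
    squared, and a final ``p`` column that uses the corrected value whenever
    sphericity is violated (Mauchly p < ``alpha``) or untestable.
    """
    fa, fb = within
    wide = data.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if wide.isna().any().any():
        raise ValueError("design must be balanced with no missing cells")
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    n = wide.shape[0]
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels of each factor")
    # cube ordered (subject, A, B)
    Y = wide.loc[:, pd.MultiIndex.from_product([a_levels, b_levels])].to_numpy()
    Y = Y.reshape(n, a, b)

    G = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - G) ** 2)
    ss_b = n * a * np.sum((m_b - G) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + G) ** 2)
    ss_as = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + G) ** 2)
    ss_bs = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + G) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - G
    )
    ss_abs = np.sum(resid**2)

    S = np.cov(Y.reshape(n, a * b), rowvar=False)
    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    ones_a = np.ones((1, a)) / np.sqrt(a)
    ones_b = np.ones((1, b)) / np.sqrt(b)
    contrasts = {
        fa: np.kron(Ca.T, ones_b),
        fb: np.kron(ones_a, Cb.T),
        f"{fa}*{fb}": np.kron(Ca.T, Cb.T),
    }
    effects = {
        fa: (ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        fb: (ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        f"{fa}*{fb}": (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }

    rows = []
    for name, (ss, df1, ss_err, df2) in effects.items():
        ms, ms_err = ss / df1, ss_err / df2
        if ms_err > 0:
            F = ms / ms_err
        else:
            # degenerate error term: no within-cell variance at all
            F = np.inf if ms > 0 else 0.0
        p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        M = contrasts[name]
        eps = _gg_epsilon(S, M)
        W, p_mauchly = _mauchly(S, M, n)
        p_gg = float(sps.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
        violated = bool(np.isnan(p_mauchly) or p_mauchly < alpha)
        rows.append(
            {
                "effect": name,
                "ss": ss,
                "df1": df1,
                "df2": df2,
                "F": F,
                "p_uncorrected": p_unc,
                "eps_gg": eps,
                "p_gg": p_gg,
                "mauchly_W": W,
                "mauchly_p": p_mauchly,
                "sphericity_violated": violated,
                "p": p_gg if violated else p_unc,
                "eta_sq_partial": ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cohens_d(x, y) -> float:
    """Pooled-SD standardized mean difference (x minus y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    return float((x.mean() - y.mean()) / pooled) if pooled > 0 else np.nan
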