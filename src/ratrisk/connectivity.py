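"""Seed-based resting-state functional connectivity from ROI time series.

Starting from per-subject ROI x time matrices (the product of any upstream
image preprocessing, which is outside this package's scope), connectivity is
quantified per ROI pair as a bootstrapped Pearson correlation, Fisher
z-transformed for inference.  Group comparisons use a two-factor mixed ANOVA
(age between subjects, ROI pair within) followed by Bonferroni-adjusted
per-pair age contrasts, and behavior-connectivity relationships use Spearman
rank correlations per pair within each age group.

The bootstrap resampling unit is the timepoint: whole columns of the ROI x T
matrix are resampled with replacement, jointly across ROIs, so every replicate
preserves the cross-ROI pairing.  A moving-block bootstrap (``block_size``) is
available to respect temporal autocorrelation; it is off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ROIS = ("VTA", "PrL", "NAcSh", "lOFC", "vOFC", "BLA")

#: ROI pairs for which the aged group's synthetic connectivity is elevated
#: (basolateral amygdala-orbitofrontal, orbitofrontal-accumbens and
#: VTA-prefrontal couplings reported stronger in aged animals).
AGED_ELEVATED_PAIRS = (
    ("BLA", "lOFC"),
    ("BLA", "vOFC"),
    ("lOFC", "NAcSh"),
    ("lOFC", "vOFC"),
    ("PrL", "VTA"),
    ("VTA", "NAcSh"),
)

_R_CLIP = 1.0 - 1e-12


@dataclass
class ROITimeSeriesSet:
    """Named ROI x time matrix for one subject."""

    subject_id: str
    roi_names: tuple[str, ...]
    data: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.roi_names):
            raise ValueError("data must be (n_rois, T) with rows matching roi_names")
        if self.data.shape[1] < 30:
            raise ValueError(f"need T >= 30 timepoints, got {self.data.shape[1]}")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain missing/non-finite values")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[1])


def fisher_z(r):
    """Fisher z transform atanh(r); odd and strictly increasing on (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pair_label(a: str, b: str) -> str:
    return f"{a}-{b}"


def roi_pairs(roi_names) -> list[tuple[str, str]]:
    return list(itertools.combinations(roi_names, 2))


def _bootstrap_indices(rng, T: int, n_boot: int, block_size: int | None):
    if block_size is None:
        return rng.integers(0, T, size=(n_boot, T))
    n_blocks = int(np.ceil(T / block_size))
    starts = rng.integers(0, T - block_size + 1, size=(n_boot, n_blocks))
    offs = np.arange(block_size)
    return (starts[:, :, None] + offs[None, None, :]).reshape(n_boot, -1)[:, :T]


def pairwise_bootstrap_pearson(
    ts: ROITimeSeriesSet,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
    block_size: int | None = None,
) -> pd.DataFrame:
    """Point and bootstrapped Pearson r, with Fisher z, for every ROI pair.

    Returns one row per unordered pair: point r on the full series, the mean
    of ``n_boot`` timepoint-resampled replicates, a percentile confidence
    interval, and z = atanh(r_point).  Constant ROI series make their pairs'
    correlations undefined; those rows carry NaN and ``degenerate=True``.
    |r| = 1 is clipped to 1 - 1e-12 before the z transform and flagged.
    """
    X = ts.data
    k, T = X.shape
    rng = np.random.default_rng(seed)
    constant = X.std(axis=1) == 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)

    idx = _bootstrap_indices(rng, T, n_boot, block_size)
    boot = np.empty((n_boot, k, k))
    for b in range(n_boot):
        with np.errstate(invalid="ignore", divide="ignore"):
            boot[b] = np.corrcoef(X[:, idx[b]])

    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        degenerate = bool(constant[i] or constant[j])
        r_point = float(R[i, j]) if not degenerate else np.nan
        clipped = False
        if not degenerate and abs(r_point) >= _R_CLIP:
            r_z = float(np.clip(r_point, -_R_CLIP, _R_CLIP))
            clipped = True
            degenerate = True  # perfectly collinear pair: boundary case
        else:
            r_z = r_point
        reps = boot[:, i, j]
        reps = reps[np.isfinite(reps)]
        rows.append(
            {
                "subject_id": ts.subject_id,
                "roi_a": ts.roi_names[i],
                "roi_b": ts.roi_names[j],
                "pair": pair_label(ts.roi_names[i], ts.roi_names[j]),
                "r_point": r_point,
                "r_boot_mean": float(reps.mean()) if reps.size else np.nan,
                "ci_lo": float(np.percentile(reps, lo_q)) if reps.size else np.nan,
                "ci_hi": float(np.percentile(reps, hi_q)) if reps.size else np.nan,
                "z": float(np.arctanh(r_z)) if np.isfinite(r_z) else np.nan,
                "n_boot": n_boot,
                "degenerate": degenerate,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows)


def connectivity_z_wide(conn: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy edge table to subjects x pairs of Fisher z values."""
    return conn.pivot(index="subject_id", columns="pair", values="z")


def bonferroni_age_contrasts(
    z_wide: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-pair independent-samples age contrasts with Bonferroni correction.

    ``labels`` maps subject_id -> age group.  The family is the full set of
    ROI pairs (the correction multiplies each p by the number of pairs).
    """
    labels = labels.reindex(z_wide.index)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two age groups, got {list(groups)}")
    g0, g1 = sorted(groups)
    a = z_wide.loc[labels == g0].to_numpy()
    b = z_wide.loc[labels == g1].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("each age group needs at least 2 subjects")
    t, p = sps.ttest_ind(a, b, axis=0)
    n_pairs = z_wide.shape[1]
    pooled_sd = np.sqrt(
        ((len(a) - 1) * a.var(axis=0, ddof=1) + (len(b) - 1) * b.var(axis=0, ddof=1))
        / (len(a) + len(b) - 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (b.mean(axis=0) - a.mean(axis=0)) / pooled_sd
    out = pd.DataFrame(
        {
            "pair": z_wide.columns,
            f"mean_z_{g0}": a.mean(axis=0),
            f"mean_z_{g1}": b.mean(axis=0),
            "t": t,
            "p_uncorrected": p,
            "p_bonferroni": np.minimum(1.0, p * n_pairs),
            "cohen_d": d,
        }
    )
    out["significant"] = out["p_bonferroni"] <= alpha
    return out


def group_connectivity_analysis(
    conn: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> dict:
    """Two-factor (age x ROI pair) comparison of Fisher z connectivity.

    ROI pair is a within-subject factor, age a between-subjects factor;
    the omnibus test is a mixed ANOVA, followed by Bonferroni-adjusted
    per-pair age contrasts.  Requires >= 2 subjects per group (>= 3
    recommended for the ANOVA to be meaningful).
    """
    import pingouin as pg

    labels = labels.rename("age_group")
    df = conn.drop(columns=["age_group"], errors="ignore").merge(
        labels, left_on="subject_id", right_index=True
    )
    counts = df.groupby("age_group")["subject_id"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(f"need >= 2 subjects in each of two groups, got {counts.to_dict()}")
    anova = pg.mixed_anova(
        data=df, dv="z", within="pair", subject="subject_id", between="age_group"
    )
    posthoc = bonferroni_age_contrasts(
        connectivity_z_wide(conn), labels, alpha=alpha
    )
    return {"anova": anova, "posthoc": posthoc}


def behavior_connectivity_correlation(
    risk_scores: pd.Series,
    conn: pd.DataFrame,
    labels: pd.Series,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Spearman rho between a per-subject behavioral score and per-pair z,
    separately within each age group (one row per pair per group)."""
    conn_subjects = set(conn["subject_id"])
    mismatch = conn_subjects.symmetric_difference(risk_scores.index)
    if mismatch:
        raise ValueError(f"subject sets differ between inputs: {sorted(mismatch)}")
    z_wide = connectivity_z_wide(conn)
    labels = labels.reindex(z_wide.index)
    rows = []
    n_pairs = z_wide.shape[1]
    for group in sorted(labels.unique()):
        members = labels.index[labels == group]
        scores = risk_scores.reindex(members)
        for pair in z_wide.columns:
            z = z_wide.loc[members, pair]
            ok = scores.notna() & z.notna()
            if ok.sum() >= 3 and scores[ok].nunique() > 1 and z[ok].nunique() > 1:
                rho, p = sps.spearmanr(scores[ok], z[ok])
            else:
                rho, p = np.nan, np.nan
            row = {"pair": pair, "group": group, "rho": rho, "p": p, "n": int(ok.sum())}
            if bonferroni:
                row["p_bonferroni"] = min(1.0, p * n_pairs) if np.isfinite(p) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def default_group_corr(age_group: str, roi_names=DEFAULT_ROIS) -> np.ndarray:
    """Population ROI correlation matrix used for synthetic subjects.

    Both groups share a uniform baseline coupling of r = 0.25; the aged matrix
    adds +0.3 in Fisher z to the six pairs in :data:`AGED_ELEVATED_PAIRS`,
    giving the aged group higher average connectivity.  Values are fabricated
    (chosen for a positive-definite matrix with a clear group contrast), not
    estimates from any animal data.
    """
    k = len(roi_names)
    base = np.full((k, k), 0.25)
    np.fill_diagonal(base, 1.0)
    if age_group == "aged":
        idx = {name: i for i, name in enumerate(roi_names)}
        hi = float(np.tanh(np.arctanh(0.25) + 0.3))
        for a, b in AGED_ELEVATED_PAIRS:
            if a in idx and b in idx:
                base[idx[a], idx[b]] = base[idx[b], idx[a]] = hi
    elif age_group != "young":
        raise ValueError(f"unknown age group {age_group!r}")
    return base
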