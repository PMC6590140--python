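"""Per-patient lesion-detection ROC analysis and inter-method comparison.

A patient's Z-map is swept over cutoffs spanning its observed range; voxels
beyond the cutoff in the modality's abnormal direction are called lesional
and scored against the ground-truth lesion mask.  Per-subject AUCs are then
compared across methods with a Friedman omnibus test and pairwise Wilcoxon
signed-rank tests under Bonferroni-Holm correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RocResult",
    "AucComparison",
    "roc_curve",
    "average_roc_at_fixed_fpr",
    "friedman_test",
    "wilcoxon_signed_rank",
    "holm_correct",
    "compare_methods",
    "DEFAULT_DIRECTIONS",
]

#: abnormality direction per modality (lesions lose myelin/MT saturation
#: and gain T1)
DEFAULT_DIRECTIONS = {"mwf_g": "low_abnormal", "mwf_d": "low_abnormal",
                      "mtr": "low_abnormal", "qt1": "high_abnormal"}


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    subject_id: str = ""
    modality: str = ""
    direction: str = "low_abnormal"
    valid: bool = True
    n_lesion: int = 0
    n_background: int = 0


@dataclass
class AucComparison:
    auc: pd.DataFrame  # subjects x methods
    friedman_chi2: float
    friedman_df: int
    friedman_p: float
    pairwise: pd.DataFrame  # method_a, method_b, w, p_raw, p_holm
    summary: pd.DataFrame  # method, mean, sd, min, max
    excluded_subjects: tuple = ()


def roc_curve(z, lesion_mask, analysis_mask, direction="low_abnormal",
              max_thresholds=512, subject_id="", modality="") -> RocResult:
    """ROC of a Z-map against the lesion mask inside ``analysis_mask``.

    ``direction`` selects the abnormal tail: ``low_abnormal`` (myelin-like
    measures), ``high_abnormal`` (T1-like) or ``abs`` (two-sided).  All
    unique observed values serve as cutoffs when there are at most
    ``max_thresholds``; otherwise quantile-spaced cutoffs are used.  AUC is
    the trapezoidal area, which with the full cutoff set equals the
    normalized Mann-Whitney U statistic.
    """
    z = np.asarray(z, dtype=float)
    lesion = np.asarray(lesion_mask, dtype=bool)
    analysis = np.asarray(analysis_mask, dtype=bool)
    if not (lesion & ~analysis).sum() == 0:
        raise ValueError("lesion mask must lie inside the analysis mask")
    sel = analysis & np.isfinite(z)
    labels = lesion[sel]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("ROC undefined: empty lesion or background")
        return RocResult(np.array([]), np.array([]), np.array([]),
                         np.nan, subject_id, modality, direction,
                         valid=False, n_lesion=n_pos, n_background=n_neg)
    vals = z[sel]
    if direction == "low_abnormal":
        score = -vals
    elif direction == "high_abnormal":
        score = vals
    elif direction == "abs":
        score = np.abs(vals)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    uniq = np.unique(score)
    if len(uniq) > max_thresholds:
        qs = np.linspace(0, 1, max_thresholds)
        cuts = np.unique(np.quantile(uniq, qs))
    else:
        cuts = uniq
    # descending cutoffs; positive call: score >= cutoff
    cuts = cuts[::-1]
    order = np.argsort(score, kind="mergesort")
    s_sorted = score[order]
    l_sorted = labels[order]
    cum_pos = np.concatenate([[0], np.cumsum(l_sorted[::-1])])
    cum_all = np.arange(len(s_sorted) + 1)
    # number of scores >= cut
    k = len(s_sorted) - np.searchsorted(s_sorted, cuts, side="left")
    tp = cum_pos[k]
    fp = cum_all[k] - tp
    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    thresholds = np.concatenate([[np.inf], cuts, [-np.inf]])
    auc = float(np.trapezoid(tpr, fpr))
    if direction == "low_abnormal":  # report cutoffs on the Z scale
        thresholds = -thresholds
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                     subject_id=subject_id, modality=modality,
                     direction=direction, n_lesion=n_pos,
                     n_background=n_neg)


def average_roc_at_fixed_fpr(rocs, fpr_grid=None):
    """Vertical ROC averaging: interpolate every curve's TPR at shared FPR
    values and average.  Returns (fpr_grid, mean_tpr)."""
    rocs = [r for r in rocs if r.valid]
    if not rocs:
        raise ValueError("no valid ROC curves to average")
    if fpr_grid is None:
        fpr_grid = np.linspace(0, 1, 101)
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    tprs = np.stack([np.interp(fpr_grid, r.fpr, r.tpr) for r in rocs])
    return fpr_grid, tprs.mean(axis=0)


def friedman_test(auc_matrix, max_exact=400_000):
    """Friedman rank test over a complete subjects-x-methods matrix.

    chi2_F = 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with average
    ranks within subjects.  The p-value comes from exact enumeration of all
    per-subject rank permutations when that costs at most ``max_exact``
    evaluations, otherwise from the chi-square approximation with k-1 df.
    """
    a = np.asarray(auc_matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("auc_matrix must be 2-D (subjects x methods)")
    n, k = a.shape
    if k < 3:
        raise ValueError("Friedman test needs k >= 3 methods; "
                         "use the Wilcoxon signed-rank test for two")
    if not np.all(np.isfinite(a)):
        raise ValueError("auc_matrix must be complete")

    def stat(rows_ranked):
        rbar = rows_ranked.mean(axis=0)
        return 12.0 * n / (k * (k + 1)) * np.sum(
            (rbar - (k + 1) / 2.0) ** 2)

    ranks = scipy.stats.rankdata(a, axis=1)
    chi2 = float(stat(ranks))
    df = k - 1
    import math
    n_perm = math.factorial(k) ** n
    if n_perm <= max_exact:
        perms = [np.array(p) for p in
                 itertools.permutations(range(k))]
        count = 0
        total = 0
        for combo in itertools.product(range(len(perms)), repeat=n):
            permuted = np.stack([ranks[i, perms[j]]
                                 for i, j in enumerate(combo)])
            total += 1
            if stat(permuted) >= chi2 - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(scipy.stats.chi2.sf(chi2, df))
    return chi2, df, p


def wilcoxon_signed_rank(x, y, max_exact=25):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; W is the positive-rank sum.  For at most
    ``max_exact`` non-zero pairs the exact null distribution is computed by
    dynamic programming over (doubled, tie-averaged) ranks; beyond that a
    normal approximation with tie correction is used.

    Returns (w_statistic, p_two_sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= max_exact:
        # doubled ranks are integers even under average-rank ties
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in r2:
            new = dp.copy()
            new[r:] += dp[:-r]
            dp = new
        dp /= 2.0 ** n
        w2 = int(round(2 * w_pos))
        p_le = dp[:w2 + 1].sum()
        p_ge = dp[w2:].sum()
        p = min(1.0, 2 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        counts = pd.Series(ranks).value_counts().to_numpy()
        tie_term = np.sum(counts ** 3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        zstat = (w_pos - mean) / np.sqrt(var)
        p = float(min(1.0, 2 * scipy.stats.norm.sf(abs(zstat))))
    return w_pos, p


def holm_correct(p_raw):
    """Bonferroni-Holm step-down adjusted p-values (input order kept)."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_methods(auc_table, method_names=None) -> AucComparison:
    """Friedman omnibus, all pairwise Wilcoxon tests (Holm-corrected) and
    per-method summary statistics of a subjects-x-methods AUC table.

    Subjects with any missing AUC are excluded (and reported), mirroring
    restriction of the comparison to fully acquired subjects.
    """
    if isinstance(auc_table, pd.DataFrame):
        df = auc_table.copy()
    else:
        a = np.asarray(auc_table, dtype=float)
        names = method_names or [f"m{j}" for j in range(a.shape[1])]
        df = pd.DataFrame(a, columns=names)
    complete = df.dropna()
    excluded = tuple(df.index.difference(complete.index))
    if excluded:
        warnings.warn(f"excluding {len(excluded)} subjects with missing AUCs")
    a = complete.to_numpy()
    chi2, dof, p_f = friedman_test(a)
    rows = []
    cols = list(complete.columns)
    for i, j in itertools.combinations(range(len(cols)), 2):
        w, p = wilcoxon_signed_rank(a[:, i], a[:, j])
        rows.append({"method_a": cols[i], "method_b": cols[j],
                     "w_statistic": w, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_correct(pairwise["p_raw"].to_numpy())
    summary = pd.DataFrame({
        "method": cols,
        "mean_auc": a.mean(axis=0), "sd_auc": a.std(axis=0, ddof=1),
        "min_auc": a.min(axis=0), "max_auc": a.max(axis=0),
        "n_subjects": len(a)})
    return AucComparison(auc=complete, friedman_chi2=chi2, friedman_df=dof,
                         friedman_p=p_f, pairwise=pairwise, summary=summary,
                         excluded_subjects=excluded)
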