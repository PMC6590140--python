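"""Cohort-level statistics: normative maps, Z-maps, voxelwise inter-method
Spearman correlation, tissue histograms, ROI summaries and group tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .lesion_roc import holm_correct

__all__ = [
    "CohortStats",
    "ZMap",
    "CorrelationMap",
    "cohort_mean_sd",
    "zmap",
    "voxelwise_spearman",
    "spearman_critical_value",
    "tissue_histograms",
    "roi_summary",
    "mann_whitney_group_test",
    "group_difference",
]


@dataclass
class CohortStats:
    mean: np.ndarray
    sd: np.ndarray
    n_subjects: int
    modality: str = ""


@dataclass
class ZMap:
    z: np.ndarray
    modality: str = ""
    subject_id: str = ""


@dataclass
class CorrelationMap:
    rho: np.ndarray
    pair: tuple = ("", "")
    n: int = 0


def _stack(maps):
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim < 2:
        raise ValueError("need a stack of volumes")
    return arr


def cohort_mean_sd(maps, mask=None, modality="") -> CohortStats:
    """Voxelwise arithmetic mean and sample SD (n-1) over subjects.

    Voxels where any subject is invalid (NaN) or outside ``mask`` are
    NaN-masked in both outputs.
    """
    arr = _stack(maps)
    if len(arr) < 2:
        raise ValueError("need at least two subjects")
    valid = np.all(np.isfinite(arr), axis=0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape[1:]:
            raise ValueError("mask grid does not match the maps")
        valid &= mask
    mean = np.where(valid, arr.mean(axis=0), np.nan)
    sd = np.where(valid, arr.std(axis=0, ddof=1), np.nan)
    return CohortStats(mean=mean, sd=sd, n_subjects=len(arr),
                       modality=modality)


def zmap(subject_map, stats: CohortStats, subject_id="") -> ZMap:
    """Z-normalize a subject map to the control mean/SD; undefined where
    the control SD is zero or either input is masked."""
    m = np.asarray(subject_map, dtype=float)
    if m.shape != stats.mean.shape:
        raise ValueError("subject map grid does not match cohort stats")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - stats.mean) / stats.sd
    z[~np.isfinite(z)] = np.nan
    return ZMap(z=z, modality=stats.modality, subject_id=subject_id)


def voxelwise_spearman(maps_a, maps_b, mask=None) -> CorrelationMap:
    """Spearman rank correlation across subjects at every voxel.

    Average ranks handle ties; voxels that are constant across subjects in
    either input (or invalid in any subject) are NaN-masked.
    """
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape != b.shape:
        raise ValueError("the two map stacks must match")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    valid = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    flat_a = a.reshape(n, -1)[:, valid.ravel()]
    flat_b = b.reshape(n, -1)[:, valid.ravel()]
    ra = scipy.stats.rankdata(flat_a, axis=0)
    rb = scipy.stats.rankdata(flat_b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt(np.sum(ra ** 2, axis=0) * np.sum(rb ** 2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_flat = np.sum(ra * rb, axis=0) / denom
    rho = np.full(a.shape[1:], np.nan)
    rho.ravel()[valid.ravel()] = rho_flat
    return CorrelationMap(rho=rho, n=n)


def spearman_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |rho| at level ``alpha``.

    Uses the t approximation ``t = rho sqrt((n-2)/(1-rho^2))`` with n-2 df;
    for n <= 8 the exact permutation null is enumerated instead (the two
    agree to ~1e-3 at n around 40).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n <= 8:
        base = np.arange(1, n + 1, dtype=float)
        rhos = []
        for perm in itertools.permutations(base):
            r = scipy.stats.pearsonr(base, np.array(perm)).statistic
            rhos.append(abs(np.round(r, 12)))
        rhos = np.sort(rhos)
        total = len(rhos)
        # smallest attainable |rho| whose two-tailed tail prob <= alpha
        for r in np.unique(rhos):
            tail = np.sum(rhos >= r - 1e-12) / total
            if tail <= alpha:
                return float(r)
        return 1.0
    t_crit = scipy.stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit ** 2))


def tissue_histograms(corr: CorrelationMap, tissue_masks: dict,
                      bins=40, value_range=(-1.0, 1.0)) -> pd.DataFrame:
    """Unit-area histograms of the correlation map per tissue class.

    Returns a tidy frame (tissue, bin_left, bin_right, density, n_voxels).
    Masks must be disjoint.
    """
    total = np.zeros_like(next(iter(tissue_masks.values())), dtype=int)
    for m in tissue_masks.values():
        total += np.asarray(m, dtype=bool)
    if total.max() > 1:
        raise ValueError("tissue masks must be disjoint")
    edges = np.linspace(*value_range, bins + 1)
    rows = []
    for name, m in tissue_masks.items():
        vals = corr.rho[np.asarray(m, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"tissue mask '{name}' has no valid voxels")
            dens = np.zeros(bins)
        else:
            dens, _ = np.histogram(vals, bins=edges, density=True)
        for i in range(bins):
            rows.append({"tissue": name, "bin_left": edges[i],
                         "bin_right": edges[i + 1], "density": dens[i],
                         "n_voxels": len(vals)})
    return pd.DataFrame(rows)


def roi_summary(maps: dict, roi_masks: dict, lesion_mask, perilesion_mask,
                group: str, subject_id: str = "") -> pd.DataFrame:
    """Per-subject ROI means with lesion and perilesional tissue excluded.

    For every region in ``roi_masks`` the mean is taken over
    ``roi & ~lesion & ~perilesion`` (for patients this makes the WM row a
    normal-appearing-WM summary by construction); additional ``lesion`` and
    ``perilesion`` rows summarize those compartments themselves.  Regions
    emptied by the exclusion yield a flagged row with NaN mean.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    perilesion_mask = np.asarray(perilesion_mask, dtype=bool)
    exclude = lesion_mask | perilesion_mask
    rows = []
    regions = {name: np.asarray(m, dtype=bool) & ~exclude
               for name, m in roi_masks.items()}
    regions["lesion"] = lesion_mask
    regions["perilesion"] = perilesion_mask
    for modality, vol in maps.items():
        vol = np.asarray(vol, dtype=float)
        for region, m in regions.items():
            vals = vol[m]
            vals = vals[np.isfinite(vals)]
            empty = len(vals) == 0
            rows.append({"subject_id": subject_id, "group": group,
                         "region": region, "modality": modality,
                         "mean": np.nan if empty else float(vals.mean()),
                         "n_voxels": int(len(vals)), "empty": bool(empty)})
    return pd.DataFrame(rows)


def mann_whitney_group_test(control, patient):
    """Two-sided Mann-Whitney U; all-tied samples yield p = 1.

    Returns (u_statistic, p_value).
    """
    control = np.asarray(control, dtype=float)
    patient = np.asarray(patient, dtype=float)
    if np.ptp(np.concatenate([control, patient])) == 0:
        return len(control) * len(patient) / 2, 1.0
    res = scipy.stats.mannwhitneyu(control, patient,
                                   alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def group_difference(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Mann-Whitney U control-vs-patient per (region, modality),
    Bonferroni-Holm corrected across regions within each modality."""
    out = []
    for modality, sub in roi_table.groupby("modality", sort=False):
        entries = []
        for region, rsub in sub.groupby("region", sort=False):
            ctl = rsub.loc[(rsub.group == "control") & ~rsub["empty"],
                           "mean"].to_numpy()
            pat = rsub.loc[(rsub.group == "patient") & ~rsub["empty"],
                           "mean"].to_numpy()
            if len(ctl) < 3 or len(pat) < 3:
                continue
            stat, p = mann_whitney_group_test(ctl, pat)
            entries.append({"modality": modality, "region": region,
                            "n_control": len(ctl), "n_patient": len(pat),
                            "u_statistic": stat, "p_raw": p})
        if not entries:
            continue
        adj = holm_correct([e["p_raw"] for e in entries])
        for e, pa in zip(entries, adj):
            e["p_adjusted"] = pa
            out.append(e)
    return pd.DataFrame(out)
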