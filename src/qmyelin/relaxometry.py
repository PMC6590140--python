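"""Voxelwise inversion of the forward models.

Produces the four quantitative maps:

* ``mwf_g`` — myelin water fraction from the multi-echo T2 spectrum
  (regularized NNLS with an EPG design matrix and refocusing-angle search),
* ``qt1`` and ``b1`` — DESPOT1-HIFI joint T1/M0/flip-scale fit,
* ``t2``/``b0`` — DESPOT2-FM fit of the phase-cycled bSSFP series,
* ``mwf_d`` — two-pool stochastic region contraction (SRC),
* ``mtr`` — magnetization transfer ratio in percent.

Single-voxel operations carry the algorithmic contracts; ``*_volume``
variants are vectorized implementations of the same algorithms used by
:func:`fit_subject` for whole-image work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .signals import (
    GraseProtocol,
    McDespotProtocol,
    MtProtocol,
    TwoPoolParams,
    epg_cpmg_decay,
    irspgr_signal,
    spgr_signal,
)
from ._fastsrc import mcdespot_signals_fast

__all__ = [
    "T2Grid",
    "T2Spectrum",
    "RegConfig",
    "SrcConfig",
    "QuantitativeMapSet",
    "epg_basis",
    "fit_t2_spectrum",
    "mwf_from_spectrum",
    "fit_despot1_hifi",
    "fit_despot2_fm",
    "fit_mcdespot_src",
    "compute_mtr",
    "fit_subject",
]

MASKED = np.nan  # sentinel for voxels where a fit is undefined


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class T2Grid:
    """Logarithmically spaced T2 analysis grid (ms); ``custom_points``
    overrides the geometric spacing (useful for exact-recovery tests)."""

    count: int = 40
    t2_min: float = 15.0
    t2_max: float = 2000.0
    custom_points: tuple | None = None

    def __post_init__(self) -> None:
        if self.custom_points is not None:
            pts = np.asarray(self.custom_points, dtype=float)
            if np.any(np.diff(pts) <= 0) or np.any(pts <= 0):
                raise ValueError("custom points must be positive increasing")
            object.__setattr__(self, "count", len(pts))
        elif self.count < 2 or self.t2_min <= 0 or self.t2_max <= self.t2_min:
            raise ValueError("invalid T2 grid")

    @property
    def points(self) -> np.ndarray:
        if self.custom_points is not None:
            return np.asarray(self.custom_points, dtype=float)
        return np.geomspace(self.t2_min, self.t2_max, self.count)


@dataclass
class T2Spectrum:
    weights: np.ndarray
    refocus_estimate: float
    residual_norm: float
    mu: float = 0.0


@dataclass(frozen=True)
class RegConfig:
    """NNLS regularization: ``tikhonov`` inflates the data-term chi-square
    into ``[chi2_min, chi2_max]`` times the unregularized value."""

    mode: str = "tikhonov"
    chi2_min: float = 1.02
    chi2_max: float = 1.025
    mu_tol: float = 1e-3
    epg_t1: float = 1000.0  # assumed T1 inside the EPG basis

    def __post_init__(self) -> None:
        if self.mode not in ("none", "tikhonov"):
            raise ValueError("mode must be 'none' or 'tikhonov'")
        if not 1.0 <= self.chi2_min <= self.chi2_max:
            raise ValueError("need 1 <= chi2_min <= chi2_max")


_DEFAULT_SRC_BOUNDS = {
    "f_m": (0.0, 0.35),
    "t1_m": (200.0, 700.0),
    "t1_f": (700.0, 2500.0),
    "t2_m": (5.0, 40.0),
    "t2_f": (40.0, 150.0),
    "k_mf": (0.5, 40.0),
}
_SRC_FIELDS = tuple(_DEFAULT_SRC_BOUNDS)


#: narrower physiological search box used for whole-volume work, where the
#: weakly identified nuisance directions of the two-pool model would
#: otherwise dominate the estimator variance
TIGHT_SRC_BOUNDS = {
    "f_m": (0.0, 0.35),
    "t1_m": (300.0, 500.0),
    "t1_f": (700.0, 2000.0),
    "t2_m": (10.0, 30.0),
    "t2_f": (50.0, 120.0),
    "k_mf": (5.0, 20.0),
}


@dataclass(frozen=True)
class SrcConfig:
    """Stochastic-region-contraction search box and sampling schedule.

    ``estimator`` selects how the final estimate is formed: ``"best"``
    returns the best-scoring sample (optionally polished), ``"mean"``
    returns a misfit-weighted mean of the final sample cloud, which
    marginalizes the shallow valley of the two-pool likelihood and has
    much lower variance on noisy data.
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_SRC_BOUNDS))
    n_samples: int = 5000
    n_retain: int = 50
    n_iterations: int = 6
    contraction_tol: float = 1e-3
    expand: float = 0.01
    estimator: str = "best"

    def __post_init__(self) -> None:
        if self.n_retain >= self.n_samples:
            raise ValueError("n_retain must be < n_samples")
        if self.estimator not in ("best", "mean"):
            raise ValueError("estimator must be 'best' or 'mean'")
        for k, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound {k}: lower > upper")


@dataclass
class QuantitativeMapSet:
    """Fitted maps on the acquisition grid.  ``maps[name]`` is a float
    volume with NaN at masked voxels, ``validity[name]`` the matching
    boolean mask, and ``absent`` lists modalities that were not acquired."""

    maps: dict
    validity: dict
    affine: np.ndarray | None = None
    absent: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


# --------------------------------------------------------------------------
# GRASE: regularized NNLS with EPG basis
# --------------------------------------------------------------------------

def epg_basis(protocol: GraseProtocol, grid: T2Grid, beta: float,
              t1: float = 1000.0) -> np.ndarray:
    """EPG design matrix: column j is the decay of grid point T2_j."""
    pts = grid.points
    a = np.empty((protocol.etl, grid.count))
    for j, t2 in enumerate(pts):
        a[:, j] = epg_cpmg_decay(t2, t1, protocol, beta)
    return a


class _EpgBasisCache:
    """Design matrices precomputed on a 1-degree beta grid (shared across
    voxels and subjects; depends only on protocol/grid/assumed T1)."""

    def __init__(self, protocol, grid, t1=1000.0, beta_lo=90, beta_hi=180):
        self.betas = np.arange(beta_lo, beta_hi + 1, 1.0)
        self.matrices = [epg_basis(protocol, grid, b, t1) for b in self.betas]


def _nnls(a, y):
    x, rnorm = scipy.optimize.nnls(a, y)
    return x, rnorm


def _tikhonov_nnls(a, y, reg: RegConfig):
    """Augmented NNLS with sqrt(mu)*I rows; mu found by bisection so the
    data-term chi2 lands inside [chi2_min, chi2_max] x unregularized chi2."""
    n = a.shape[1]
    x0, r0 = _nnls(a, y)
    chi0 = r0 ** 2
    if chi0 == 0:
        return x0, r0, 0.0
    target_lo = reg.chi2_min * chi0
    target_hi = reg.chi2_max * chi0
    y_aug = np.concatenate([y, np.zeros(n)])

    def solve(mu):
        a_aug = np.vstack([a, np.sqrt(mu) * np.eye(n)])
        x, _ = _nnls(a_aug, y_aug)
        chi = float(np.sum((a @ x - y) ** 2))
        return x, chi

    lo, hi = 1e-10, 1e-10
    chi_hi = chi0
    for _ in range(60):  # grow upper bracket
        hi *= 10.0
        _, chi_hi = solve(hi)
        if chi_hi > target_hi:
            break
    else:
        warnings.warn("Tikhonov mu search did not bracket; "
                      "returning unregularized solution")
        return x0, r0, 0.0
    for _ in range(80):  # bisect in log(mu)
        mid = np.sqrt(lo * hi)
        x, chi = solve(mid)
        if target_lo <= chi <= target_hi:
            return x, np.sqrt(chi), mid
        if chi > target_hi:
            hi = mid
        else:
            lo = mid
        if hi / lo < 1 + reg.mu_tol:
            break
    warnings.warn("Tikhonov mu bisection did not converge; "
                  "returning unregularized solution")
    return x0, r0, 0.0


def fit_t2_spectrum(decay, protocol: GraseProtocol, grid: T2Grid = T2Grid(),
                    reg: RegConfig = RegConfig(),
                    beta_range=(90.0, 180.0)) -> T2Spectrum:
    """Fit a non-negative T2 spectrum to one echo train.

    The refocusing angle beta is estimated first by golden-section search of
    the unregularized NNLS residual over ``beta_range`` (ties broken toward
    180 degrees), then the spectrum is solved at the estimate, optionally
    with Tikhonov regularization.
    """
    y = np.asarray(decay, dtype=float)
    if y.shape != (protocol.etl,):
        raise ValueError("decay length must equal the echo train length")
    if not np.any(y > 0):
        raise ValueError("all-zero decay cannot be fitted")

    def resid(beta):
        a = epg_basis(protocol, grid, beta, reg.epg_t1)
        _, r = _nnls(a, y)
        return r

    res = scipy.optimize.minimize_scalar(
        resid, bounds=beta_range, method="bounded",
        options={"xatol": 0.05})
    beta_hat = float(res.x)
    # tie-break toward 180: accept the nominal angle when indistinguishable
    if resid(beta_range[1]) <= res.fun * (1 + 1e-9):
        beta_hat = float(beta_range[1])

    a = epg_basis(protocol, grid, beta_hat, reg.epg_t1)
    if reg.mode == "tikhonov":
        x, rnorm, mu = _tikhonov_nnls(a, y, reg)
    else:
        x, rnorm = _nnls(a, y)
        mu = 0.0
    return T2Spectrum(weights=x, refocus_estimate=beta_hat,
                      residual_norm=float(rnorm), mu=mu)


def mwf_from_spectrum(spectrum, grid: T2Grid = T2Grid(),
                      window=(10.0, 40.0)) -> float:
    """Myelin water fraction: spectral weight inside ``window`` (inclusive)
    over total weight.  Returns NaN for an all-zero spectrum."""
    w = spectrum.weights if isinstance(spectrum, T2Spectrum) else np.asarray(
        spectrum, dtype=float)
    pts = grid.points
    total = w.sum()
    if total <= 0:
        return MASKED
    inside = (pts >= window[0]) & (pts <= window[1])
    return float(w[inside].sum() / total)


# --------------------------------------------------------------------------
# DESPOT1-HIFI
# --------------------------------------------------------------------------

def _despot1_linear(spgr, alphas_eff_rad, tr):
    """Linearized DESPOT1: regress S/sin(a) on S/tan(a); slope = E1."""
    yv = spgr / np.sin(alphas_eff_rad)
    xv = spgr / np.tan(alphas_eff_rad)
    xm = xv.mean(axis=-1, keepdims=True)
    ym = yv.mean(axis=-1, keepdims=True)
    sxx = ((xv - xm) ** 2).sum(axis=-1)
    sxy = ((xv - xm) * (yv - ym)).sum(axis=-1)
    slope = sxy / sxx
    intercept = (ym - slope[..., None] * xm)[..., 0]
    return slope, intercept


def fit_despot1_hifi(spgr, irspgr, protocol: McDespotProtocol = McDespotProtocol(),
                     kappa_bounds=(0.3, 2.0)):
    """Joint (t1, m0, kappa) fit of the SPGR series plus the IR-SPGR scan.

    A 1-D bounded search over the flip-angle scale kappa nests the exact
    linearized DESPOT1 solve; the objective is the summed squared residual
    of both forward models.

    Returns
    -------
    (t1_ms, m0, kappa) or (nan, nan, nan) for an infeasible voxel.
    """
    spgr = np.asarray(spgr, dtype=float)
    alphas = np.asarray(protocol.spgr_alphas, dtype=float)
    if spgr.shape != alphas.shape or len(alphas) < 2:
        raise ValueError("need one SPGR signal per flip angle (>= 2)")

    def inner(kappa):
        a_eff = np.deg2rad(alphas * kappa)
        slope, intercept = _despot1_linear(spgr, a_eff, protocol.spgr_tr)
        if not 0 < slope < 1:
            return np.inf, (MASKED, MASKED)
        t1 = -protocol.spgr_tr / np.log(slope)
        m0 = intercept / (1 - slope)
        model = spgr_signal(m0, t1, alphas, protocol.spgr_tr, kappa)
        model_ir = irspgr_signal(m0, t1, protocol, kappa)
        cost = np.sum((model - spgr) ** 2) + (model_ir - irspgr) ** 2
        return cost, (t1, m0)

    res = scipy.optimize.minimize_scalar(
        lambda k: inner(k)[0], bounds=kappa_bounds, method="bounded",
        options={"xatol": 1e-7})
    kappa = float(res.x)
    cost, (t1, m0) = inner(kappa)
    if not np.isfinite(cost):
        return MASKED, MASKED, MASKED
    return float(t1), float(m0), kappa


# --------------------------------------------------------------------------
# DESPOT2-FM
# --------------------------------------------------------------------------

def bssfp_signal_vec(m0, t1, t2, alpha_eff_deg, tr, delta_f0, phase_cycle):
    """Vectorized single-pool bSSFP magnitude (TE = TR/2); explicit 3x3
    cofactor solve of the steady-state system.  Broadcasts all inputs."""
    a = np.deg2rad(alpha_eff_deg)
    th = 2 * np.pi * delta_f0 * (tr * 1e-3) + np.deg2rad(phase_cycle)
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    ca, sa = np.cos(a), np.sin(a)
    ct, st = np.cos(th), np.sin(th)
    # A = D Rz Rx ; rows of sysmat = I - A
    m00 = 1 - e2 * ct
    m01 = e2 * st * ca
    m02 = e2 * st * sa
    m10 = -e2 * st
    m11 = 1 - e2 * ct * ca
    m12 = -e2 * ct * sa
    m20 = np.zeros(np.broadcast(a, th, e1).shape)
    m21 = e1 * sa + m20
    m22 = 1 - e1 * ca
    c2 = (1 - e1) * m0
    det = (m00 * (m11 * m22 - m12 * m21)
           - m01 * (m10 * m22 - m12 * m20)
           + m02 * (m10 * m21 - m11 * m20))
    # Cramer: only c2 is nonzero
    mx = c2 * (m01 * m12 - m02 * m11) / det
    my = -c2 * (m00 * m12 - m02 * m10) / det
    mz = c2 * (m00 * m11 - m01 * m10) / det
    ypost = my * ca + mz * sa
    return np.hypot(mx, ypost) * np.exp(-0.5 * tr / t2)


def fit_despot2_fm(bssfp, t1, kappa, protocol: McDespotProtocol = McDespotProtocol(),
                   m0_guess=None):
    """Fit (t2, delta_f0, m0) to both phase-cycled bSSFP series.

    ``bssfp`` has shape (n_phase_cycles, n_alphas).  Nonlinear least squares
    with multi-start over delta_f0 spanning the unaliased band
    ``(-1/(2 tr), +1/(2 tr))``; the principal-value estimate is returned.

    Returns (t2_ms, delta_f0_hz, m0) or NaNs when no start converges.
    """
    bssfp = np.asarray(bssfp, dtype=float)
    pcs = np.asarray(protocol.bssfp_phase_cycles, dtype=float)
    alphas = np.asarray(protocol.bssfp_alphas, dtype=float)
    if bssfp.shape != (len(pcs), len(alphas)):
        raise ValueError("bssfp must be (n_phase_cycles, n_alphas)")
    if not np.isfinite(t1) or t1 <= 0:
        return MASKED, MASKED, MASKED
    tr = protocol.bssfp_tr
    half_band = 1000.0 / (2 * tr)  # Hz
    y = bssfp.ravel()
    if m0_guess is None:
        m0_guess = float(y.max() * 3)

    def resid(p):
        m0, t2, df0 = p
        model = np.stack(
            [bssfp_signal_vec(m0, t1, t2, alphas * kappa, tr, df0, pc)
             for pc in pcs]).ravel()
        return model - y

    best = None
    for df0_start in np.linspace(-0.8 * half_band, 0.8 * half_band, 5):
        try:
            sol = scipy.optimize.least_squares(
                resid, x0=[m0_guess, min(80.0, 0.5 * t1), df0_start],
                bounds=([0, 1.0, -half_band], [np.inf, t1, half_band]),
                xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return MASKED, MASKED, MASKED
    m0, t2, df0 = best.x
    return float(t2), float(df0), float(m0)


# --------------------------------------------------------------------------
# SRC (stochastic region contraction) for the two-pool model
# --------------------------------------------------------------------------

_SPGR_BLOCK = slice(0, 7)
_BSSFP_BLOCK = slice(7, 21)
_IR_INDEX = 21


def _normalize_blocks(table):
    """Remove the m0 scale: divide the SPGR+IR block and the bSSFP block by
    their respective means.  ``table`` is (..., 22)."""
    out = np.empty_like(table)
    spgr_ir = np.concatenate(
        [table[..., _SPGR_BLOCK], table[..., _IR_INDEX:_IR_INDEX + 1]],
        axis=-1)
    mean_a = spgr_ir.mean(axis=-1, keepdims=True)
    mean_b = table[..., _BSSFP_BLOCK].mean(axis=-1, keepdims=True)
    out[..., _SPGR_BLOCK] = table[..., _SPGR_BLOCK] / mean_a
    out[..., _IR_INDEX] = table[..., _IR_INDEX] / mean_a[..., 0]
    out[..., _BSSFP_BLOCK] = table[..., _BSSFP_BLOCK] / mean_b
    return out


def _src_score(samples, data_norm, kappa, delta_f0, protocol):
    """Sum-of-squares misfit of normalized signal blocks for each sample row.

    ``samples`` is (n, 6) in the order of ``_SRC_FIELDS``."""
    n = samples.shape[0]
    p = {k: samples[:, i] for i, k in enumerate(_SRC_FIELDS)}
    p["delta_f0"] = np.full(n, delta_f0)
    p["b1_scale"] = np.full(n, kappa)
    table = mcdespot_signals_fast(p, protocol)
    model_norm = _normalize_blocks(table)
    return np.sum((model_norm - data_norm) ** 2, axis=-1)


def fit_mcdespot_src(signals, kappa, rng, src: SrcConfig = SrcConfig(),
                     protocol: McDespotProtocol = McDespotProtocol(),
                     delta_f0=0.0, polish=True, box_history=None):
    """Two-pool parameter estimate by stochastic region contraction.

    Each iteration draws uniform samples inside the current box, keeps the
    ``n_retain`` best-scoring (normalized-block SSE), and contracts the box
    to their extent expanded by ``expand`` of the width.  The best sample is
    optionally refined with a Nelder-Mead polish.

    Returns
    -------
    (params: TwoPoolParams with f_m = MWF-D, score: float)
    """
    y = np.asarray(signals, dtype=float)
    if y.shape != (protocol.n_signals,):
        raise ValueError("expected the full mcDESPOT signal set")
    data_norm = _normalize_blocks(y[None, :])[0]

    lo = np.array([src.bounds[k][0] for k in _SRC_FIELDS])
    hi = np.array([src.bounds[k][1] for k in _SRC_FIELDS])
    if np.all(lo == hi):
        best = lo.copy()
        score = float(_src_score(best[None, :], data_norm, kappa, delta_f0,
                                 protocol)[0])
        return _src_params(best, kappa, delta_f0), score

    box_lo, box_hi = lo.copy(), hi.copy()
    best_x, best_score = None, np.inf
    for _ in range(src.n_iterations):
        if box_history is not None:
            box_history.append((box_lo.copy(), box_hi.copy()))
        samples = box_lo + rng.random((src.n_samples, 6)) * (box_hi - box_lo)
        scores = _src_score(samples, data_norm, kappa, delta_f0, protocol)
        order = np.argpartition(scores, src.n_retain)[:src.n_retain]
        retained = samples[order]
        imin = order[np.argmin(scores[order])]
        if scores[imin] < best_score:
            best_score = float(scores[imin])
            best_x = samples[imin].copy()
        width = box_hi - box_lo
        box_lo = np.maximum(lo, retained.min(axis=0) - src.expand * width)
        box_hi = np.minimum(hi, retained.max(axis=0) + src.expand * width)
        if np.all(box_hi - box_lo < src.contraction_tol * (hi - lo)):
            break

    if polish:
        def resid(x):
            p = {k: np.array([x[i]]) for i, k in enumerate(_SRC_FIELDS)}
            p["delta_f0"] = np.array([delta_f0])
            p["b1_scale"] = np.array([kappa])
            return _normalize_blocks(
                mcdespot_signals_fast(p, protocol))[0] - data_norm
        eps = 1e-9 * (hi - lo)
        try:
            sol = scipy.optimize.least_squares(
                resid, np.clip(best_x, lo + eps, hi - eps),
                bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            s_pol = float(2 * sol.cost)
            if s_pol <= best_score:
                best_x, best_score = sol.x, s_pol
        except Exception:  # pragma: no cover - polish is best-effort
            pass
    return _src_params(best_x, kappa, delta_f0), best_score


def _src_params(x, kappa, delta_f0) -> TwoPoolParams:
    d = dict(zip(_SRC_FIELDS, x))
    # keep the pool ordering constraints valid at the box edges
    d["t2_m"] = min(d["t2_m"], d["t2_f"] - 1e-9)
    d["t1_m"] = min(d["t1_m"], d["t1_f"] - 1e-9)
    d["f_m"] = min(max(d["f_m"], 0.0), 1 - 1e-9)
    return TwoPoolParams(m0=1.0, delta_f0=delta_f0, b1_scale=kappa, **d)


# --------------------------------------------------------------------------
# MTR
# --------------------------------------------------------------------------

def compute_mtr(m0_img, ms_img, background_threshold=0.0):
    """MTR map in percent: ``(M0 - Ms)/M0 * 100``; voxels with
    ``M0 <= background_threshold`` are NaN-masked."""
    m0_img = np.asarray(m0_img, dtype=float)
    ms_img = np.asarray(ms_img, dtype=float)
    if m0_img.shape != ms_img.shape:
        raise ValueError("M0 and Ms images must share a shape")
    out = np.full(m0_img.shape, MASKED)
    ok = m0_img > background_threshold
    out[ok] = (m0_img[ok] - ms_img[ok]) / m0_img[ok] * 100.0
    return out


# --------------------------------------------------------------------------
# volume-level fitters (vectorized variants of the ops above)
# --------------------------------------------------------------------------

def fit_despot1_volume(spgr, irspgr, protocol, kappa_bounds=(0.3, 2.0),
                       n_golden=40):
    """Vectorized DESPOT1-HIFI: simultaneous golden-section over kappa for
    every voxel.  ``spgr`` is (V, n_alphas), ``irspgr`` (V,)."""
    spgr = np.asarray(spgr, dtype=float)
    irspgr = np.asarray(irspgr, dtype=float)
    alphas = np.asarray(protocol.spgr_alphas, dtype=float)
    v = spgr.shape[0]

    def cost(kappa):
        a_eff = np.deg2rad(alphas * kappa[:, None])
        slope, intercept = _despot1_linear(spgr, a_eff, protocol.spgr_tr)
        bad = ~((slope > 0) & (slope < 1))
        slope_c = np.clip(slope, 1e-12, 1 - 1e-12)
        t1 = -protocol.spgr_tr / np.log(slope_c)
        m0 = intercept / (1 - slope_c)
        model = spgr_signal(m0[:, None], t1[:, None], alphas[None, :],
                            protocol.spgr_tr, kappa[:, None])
        model_ir = irspgr_signal(m0, t1, protocol, kappa)
        c = np.sum((model - spgr) ** 2, axis=1) + (model_ir - irspgr) ** 2
        c[bad] = np.inf
        return c, t1, m0

    invphi = (np.sqrt(5.0) - 1) / 2
    a = np.full(v, kappa_bounds[0])
    b = np.full(v, kappa_bounds[1])
    for _ in range(n_golden):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = cost(x1)[0]
        f2 = cost(x2)[0]
        go_left = f1 < f2
        b = np.where(go_left, x2, b)
        a = np.where(go_left, a, x1)
    kappa = (a + b) / 2
    c, t1, m0 = cost(kappa)
    valid = np.isfinite(c) & (t1 > 0)
    t1[~valid] = MASKED
    m0[~valid] = MASKED
    kappa[~valid] = MASKED
    return t1, m0, kappa, valid


def fit_despot2_volume(bssfp, t1, kappa, protocol, n_iter=24,
                       df0_starts=(-0.5, 0.0, 0.5)):
    """Vectorized DESPOT2-FM: damped Gauss-Newton on (m0, t2, df0) for all
    voxels at once with multi-start over the off-resonance band.

    ``bssfp`` is (V, n_pc, n_alphas).
    """
    bssfp = np.asarray(bssfp, dtype=float)
    v = bssfp.shape[0]
    pcs = np.asarray(protocol.bssfp_phase_cycles, dtype=float)
    alphas = np.asarray(protocol.bssfp_alphas, dtype=float)
    tr = protocol.bssfp_tr
    half_band = 1000.0 / (2 * tr)
    y = bssfp.reshape(v, -1)
    t1c = np.where(np.isfinite(t1) & (t1 > 0), t1, 1000.0)
    kap = np.where(np.isfinite(kappa), kappa, 1.0)

    def model(m0, t2, df0):
        out = [bssfp_signal_vec(m0[:, None], t1c[:, None], t2[:, None],
                                alphas[None, :] * kap[:, None], tr,
                                df0[:, None], pc) for pc in pcs]
        return np.concatenate(out, axis=1)

    lo = np.array([0.0, 1.0, -half_band])
    best_cost = np.full(v, np.inf)
    best = np.zeros((v, 3))
    for frac in df0_starts:
        p = np.stack([y.max(axis=1) * 3,
                      np.minimum(80.0, 0.5 * t1c),
                      np.full(v, frac * half_band)], axis=1)
        for _ in range(n_iter):
            hi = np.stack([np.full(v, np.inf), t1c, np.full(v, half_band)],
                          axis=1)
            p = np.clip(p, lo, hi)
            r = model(p[:, 0], p[:, 1], p[:, 2]) - y
            jac = np.empty((v, y.shape[1], 3))
            for k in range(3):
                dp = np.zeros((v, 3))
                step = np.maximum(1e-6, 1e-6 * np.abs(p[:, k]))
                dp[:, k] = step
                pp = np.clip(p + dp, lo, hi)
                rk = model(pp[:, 0], pp[:, 1], pp[:, 2]) - y
                jac[:, :, k] = (rk - r) / (pp[:, k] - p[:, k] + 1e-300)[:, None]
            jtj = np.einsum("vik,vil->vkl", jac, jac)
            jtr = np.einsum("vik,vi->vk", jac, r)
            jtj += 1e-9 * np.eye(3) * np.maximum(
                1.0, np.trace(jtj, axis1=1, axis2=2))[:, None, None]
            try:
                step = np.linalg.solve(jtj, jtr[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                break
            p_new = np.clip(p - step, lo, hi)
            r_new = model(p_new[:, 0], p_new[:, 1], p_new[:, 2]) - y
            improved = np.sum(r_new ** 2, axis=1) <= np.sum(r ** 2, axis=1)
            p = np.where(improved[:, None], p_new, p)
        cost = np.sum((model(p[:, 0], p[:, 1], p[:, 2]) - y) ** 2, axis=1)
        better = cost < best_cost
        best[better] = p[better]
        best_cost[better] = cost[better]
    m0, t2, df0 = best[:, 0], best[:, 1], best[:, 2]
    valid = np.isfinite(best_cost) & (t2 > 0)
    t2 = np.where(valid, t2, MASKED)
    df0 = np.where(valid, df0, MASKED)
    m0 = np.where(valid, m0, MASKED)
    return t2, df0, m0, valid


def fit_src_volume(signals, kappa, delta_f0, rng,
                   src: SrcConfig = SrcConfig(),
                   protocol: McDespotProtocol = McDespotProtocol()):
    """Batched SRC over voxels: identical contraction schedule to
    :func:`fit_mcdespot_src` (without the final polish), with per-voxel
    boxes evaluated through the fast kernel in one flat batch per
    iteration.  ``signals`` is (V, 22).  Returns (mwf_d, params (V,6))."""
    y = np.asarray(signals, dtype=float)
    v, n_sig = y.shape
    data_norm = _normalize_blocks(y)
    kap = np.where(np.isfinite(kappa), kappa, 1.0)
    df0 = np.where(np.isfinite(delta_f0), delta_f0, 0.0)

    lo = np.array([src.bounds[k][0] for k in _SRC_FIELDS])
    hi = np.array([src.bounds[k][1] for k in _SRC_FIELDS])
    box_lo = np.tile(lo, (v, 1))
    box_hi = np.tile(hi, (v, 1))
    ns = src.n_samples
    best_x = np.tile((lo + hi) / 2, (v, 1))
    best_score = np.full(v, np.inf)

    for _ in range(src.n_iterations):
        u = rng.random((v, ns, 6))
        samples = box_lo[:, None, :] + u * (box_hi - box_lo)[:, None, :]
        flat = samples.reshape(v * ns, 6)
        p = {k: flat[:, i] for i, k in enumerate(_SRC_FIELDS)}
        p["delta_f0"] = np.repeat(df0, ns)
        p["b1_scale"] = np.repeat(kap, ns)
        table = mcdespot_signals_fast(p, protocol)
        model_norm = _normalize_blocks(table).reshape(v, ns, n_sig)
        scores = np.sum((model_norm - data_norm[:, None, :]) ** 2, axis=-1)
        order = np.argpartition(scores, src.n_retain, axis=1)[:, :src.n_retain]
        retained = np.take_along_axis(samples, order[:, :, None], axis=1)
        rscores = np.take_along_axis(scores, order, axis=1)
        ibest = np.argmin(rscores, axis=1)
        it_best = np.take_along_axis(
            retained, ibest[:, None, None], axis=1)[:, 0, :]
        it_score = np.take_along_axis(rscores, ibest[:, None], axis=1)[:, 0]
        upd = it_score < best_score
        best_x[upd] = it_best[upd]
        best_score[upd] = it_score[upd]
        width = box_hi - box_lo
        box_lo = np.maximum(lo, retained.min(axis=1) - src.expand * width)
        box_hi = np.minimum(hi, retained.max(axis=1) + src.expand * width)
        last_samples, last_scores = samples, scores
        if np.all(box_hi - box_lo < src.contraction_tol * (hi - lo)):
            break
    if src.estimator == "mean":
        # pseudo-posterior mean over the final sample cloud: weights
        # exp(-SSE / (2 sigma^2)) with sigma^2 set by the best misfit
        best = last_scores.min(axis=1, keepdims=True)
        sig2 = np.maximum(best / n_sig, 1e-12)
        w = np.exp(-(last_scores - best) / (2 * sig2))
        w /= w.sum(axis=1, keepdims=True)
        best_x = np.sum(w[:, :, None] * last_samples, axis=1)
    else:
        best_x = _lm_polish_volume(best_x, data_norm, kap, df0, protocol,
                                   lo, hi)
    return best_x[:, 0], best_x


def _lm_polish_volume(x, data_norm, kappa, delta_f0, protocol, lo, hi,
                      n_iter=12):
    """Batched damped Gauss-Newton refinement of SRC winners (all voxels at
    once, finite-difference jacobian, bound clipping)."""
    v = x.shape[0]
    x = np.clip(x, lo, hi)

    def resid(xm):
        p = {k: xm[:, i] for i, k in enumerate(_SRC_FIELDS)}
        p["delta_f0"] = delta_f0
        p["b1_scale"] = kappa
        return _normalize_blocks(mcdespot_signals_fast(p, protocol)) - data_norm

    lam = np.full(v, 1e-3)
    r = resid(x)
    cost = np.sum(r ** 2, axis=1)
    scale = hi - lo
    for _ in range(n_iter):
        jac = np.empty((v, r.shape[1], 6))
        for k in range(6):
            h = 1e-6 * scale[k]
            xp = x.copy()
            xp[:, k] = np.clip(x[:, k] + h, lo[k], hi[k])
            hk = xp[:, k] - x[:, k]
            hk[hk == 0] = h  # at the upper bound: step down instead
            xp[:, k] = np.clip(x[:, k] + hk, lo[k], hi[k])
            jac[:, :, k] = (resid(xp) - r) / hk[:, None]
        jtj = np.einsum("vik,vil->vkl", jac, jac)
        jtr = np.einsum("vik,vi->vk", jac, r)
        diag = np.maximum(np.einsum("vkk->vk", jtj), 1e-12)
        a = jtj + lam[:, None, None] * diag[:, None, :] * np.eye(6)
        try:
            step = np.linalg.solve(a, jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        x_new = np.clip(x - step, lo, hi)
        r_new = resid(x_new)
        c_new = np.sum(r_new ** 2, axis=1)
        improved = c_new < cost
        x[improved] = x_new[improved]
        r[improved] = r_new[improved]
        cost[improved] = c_new[improved]
        lam = np.where(improved, lam * 0.3, lam * 5.0)
    return x


def fit_grase_volume(decays, protocol, grid: T2Grid = T2Grid(),
                     reg: RegConfig = RegConfig(),
                     basis_cache: _EpgBasisCache | None = None,
                     window=(10.0, 40.0)):
    """Voxelwise T2-spectrum fits over a (V, etl) stack.

    Uses a shared 1-degree EPG basis cache; per voxel the refocusing angle
    is found by coarse grid search plus local 1-degree descent, then the
    (optionally regularized) spectrum is solved at that angle.
    Returns (mwf (V,), beta (V,), valid (V,)).
    """
    decays = np.asarray(decays, dtype=float)
    v = decays.shape[0]
    if basis_cache is None:
        basis_cache = _EpgBasisCache(protocol, grid, reg.epg_t1)
    mats = basis_cache.matrices
    nb = len(mats)
    coarse = list(range(0, nb, max(1, nb // 8))) + [nb - 1]
    coarse = sorted(set(coarse))

    mwf = np.full(v, MASKED)
    beta = np.full(v, MASKED)
    valid = np.zeros(v, dtype=bool)
    for i in range(v):
        y = decays[i]
        if not np.any(y > 0):
            continue
        res = {j: _nnls(mats[j], y)[1] for j in coarse}
        j = min(res, key=lambda k: (res[k], -k))
        while True:  # local descent on the 1-degree grid
            for jn in (j - 1, j + 1):
                if 0 <= jn < nb and jn not in res:
                    res[jn] = _nnls(mats[jn], y)[1]
            nbrs = [k for k in (j - 1, j, j + 1) if 0 <= k < nb]
            jbest = min(nbrs, key=lambda k: (res[k], -k))
            if jbest == j:
                break
            j = jbest
        if reg.mode == "tikhonov":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                x, _, _ = _tikhonov_nnls(mats[j], y, reg)
        else:
            x, _ = _nnls(mats[j], y)
        mwf[i] = mwf_from_spectrum(x, grid, window)
        beta[i] = basis_cache.betas[j]
        valid[i] = np.isfinite(mwf[i])
    return mwf, beta, valid


# --------------------------------------------------------------------------
# subject orchestration
# --------------------------------------------------------------------------

def fit_subject(acquisitions: dict, brain_mask, protocols: dict | None = None,
                grid: T2Grid = T2Grid(), reg: RegConfig = RegConfig(),
                src: SrcConfig = SrcConfig(), rng=None, affine=None,
                basis_cache=None) -> QuantitativeMapSet:
    """Fit every available modality of one subject inside ``brain_mask``.

    ``acquisitions`` maps modality names to arrays on a common grid:
    ``grase`` (..., etl), ``spgr`` (..., n_alpha), ``irspgr`` (...),
    ``bssfp`` (..., n_pc, n_alpha), ``mt`` (..., 2).  Missing entries yield
    maps flagged in ``absent`` rather than errors (some subjects lack an MT
    scan).
    """
    protocols = protocols or {}
    g_prot = protocols.get("grase", GraseProtocol())
    d_prot = protocols.get("mcdespot", McDespotProtocol())
    rng = np.random.default_rng(0) if rng is None else rng

    mask = np.asarray(brain_mask, dtype=bool)
    shape = mask.shape
    idx = np.nonzero(mask.ravel())[0]

    def blank():
        return np.full(shape, MASKED)

    maps: dict = {}
    validity: dict = {}
    absent = []

    def fill(name, flat_vals, flat_valid):
        m = blank()
        m.ravel()[idx] = np.where(flat_valid, flat_vals, MASKED)
        maps[name] = m
        vmask = np.zeros(shape, dtype=bool)
        vmask.ravel()[idx] = flat_valid
        validity[name] = vmask

    has_mcd = all(k in acquisitions for k in ("spgr", "irspgr", "bssfp"))
    if has_mcd:
        spgr = acquisitions["spgr"].reshape(-1, len(d_prot.spgr_alphas))[idx]
        irspgr = acquisitions["irspgr"].reshape(-1)[idx]
        npc = len(d_prot.bssfp_phase_cycles)
        nal = len(d_prot.bssfp_alphas)
        bssfp = acquisitions["bssfp"].reshape(-1, npc, nal)[idx]
        t1, m0, kappa, v1 = fit_despot1_volume(spgr, irspgr, d_prot)
        fill("qt1", t1, v1)
        fill("b1", kappa, v1)
        t2, df0, _, v2 = fit_despot2_volume(bssfp, t1, kappa, d_prot)
        fill("t2", t2, v1 & v2)
        fill("b0", df0, v1 & v2)
        sigs = np.concatenate(
            [spgr, bssfp.reshape(len(idx), -1), irspgr[:, None]], axis=1)
        mwf_d, _ = fit_src_volume(sigs, kappa, df0, rng, src, d_prot)
        fill("mwf_d", mwf_d, v1 & v2 & np.isfinite(mwf_d))
    else:
        absent += ["mwf_d", "qt1", "b1", "b0", "t2"]

    if "grase" in acquisitions:
        decays = acquisitions["grase"].reshape(-1, g_prot.etl)[idx]
        mwf_g, beta, vg = fit_grase_volume(decays, g_prot, grid, reg,
                                           basis_cache)
        fill("mwf_g", mwf_g, vg)
    else:
        absent.append("mwf_g")

    if "mt" in acquisitions:
        mt = acquisitions["mt"].reshape(-1, 2)[idx]
        mtr = compute_mtr(mt[:, 0], mt[:, 1])
        fill("mtr", mtr, np.isfinite(mtr))
    else:
        absent.append("mtr")

    return QuantitativeMapSet(maps=maps, validity=validity, affine=affine,
                              absent=tuple(absent),
                              provenance={"grase_protocol": vars(g_prot),
                                          "mcdespot_protocol": vars(d_prot)})
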