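"""Forward signal models for the four quantitative acquisitions.

Implements the physics that the voxelwise fitters in :mod:`qmyelin.relaxometry`
invert:

* extended-phase-graph (EPG) echo amplitudes for multi-echo CPMG trains,
* spoiled gradient echo (SPGR) and inversion-prepared SPGR steady states,
* balanced SSFP steady states with phase cycling,
* two-pool (myelin water / free water) exchange versions of the steady-state
  sequences,
* the magnetization-transfer saturation pair, and
* Rician magnitude noise.

All times are milliseconds, flip angles degrees, off-resonance Hz, exchange
rates 1/s unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GraseProtocol",
    "McDespotProtocol",
    "MtProtocol",
    "TwoPoolParams",
    "epg_cpmg_decay",
    "multicomponent_decay",
    "spgr_signal",
    "irspgr_signal",
    "bssfp_signal",
    "two_pool_spgr",
    "two_pool_bssfp",
    "two_pool_irspgr",
    "two_pool_signals",
    "mt_pair",
    "add_rician_noise",
]


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GraseProtocol:
    """Multi-echo CPMG readout: echo spacing ``te``, ``etl`` echoes."""

    te: float = 10.0
    etl: int = 32
    tr: float = 1000.0
    refocus_nominal: float = 180.0

    def __post_init__(self) -> None:
        if self.te <= 0:
            raise ValueError("te must be > 0")
        if self.etl < 2:
            raise ValueError("etl must be >= 2")
        if self.etl * self.te >= self.tr:
            raise ValueError("echo train must fit inside TR (etl*te < tr)")

    @property
    def echo_times(self) -> np.ndarray:
        return self.te * np.arange(1, self.etl + 1)


@dataclass(frozen=True)
class McDespotProtocol:
    """SPGR / IR-SPGR / phase-cycled bSSFP multi-flip-angle protocol.

    ``ir_tr_total`` is the effective repetition period of the
    inversion-prepared sequence (inversion to inversion); the readout train is
    collapsed into a single low-flip pulse at TI.
    """

    spgr_tr: float = 6.5
    spgr_alphas: tuple = (2.0, 3.0, 4.0, 6.0, 9.0, 13.0, 18.0)
    bssfp_tr: float = 5.8
    bssfp_alphas: tuple = (7.0, 11.0, 15.0, 19.0, 24.0, 30.0, 47.0)
    bssfp_phase_cycles: tuple = (0.0, 180.0)
    ir_ti: float = 450.0
    ir_alpha: float = 5.0
    ir_tr: float = 6.5
    ir_tr_total: float = 700.0
    inv_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spgr_tr", "bssfp_tr", "ir_ti", "ir_tr", "ir_tr_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for a in (*self.spgr_alphas, *self.bssfp_alphas, self.ir_alpha):
            if not 0 < a < 180:
                raise ValueError("flip angles must lie in (0, 180) degrees")
        if self.ir_tr_total <= self.ir_ti:
            raise ValueError("ir_tr_total must exceed ir_ti")

    @property
    def n_signals(self) -> int:
        return (len(self.spgr_alphas)
                + len(self.bssfp_alphas) * len(self.bssfp_phase_cycles) + 1)


@dataclass(frozen=True)
class MtProtocol:
    """Gradient-echo MT pair; the off-resonance pulse parameters are metadata
    only — saturation is parameterized directly by the ground-truth fraction."""

    offset: float = 1100.0
    tr: float = 85.0
    alpha: float = 18.0

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be > 0")


@dataclass(frozen=True)
class TwoPoolParams:
    """Myelin (m) / free (f) water pool parameters with exchange.

    ``k_mf`` is the myelin-to-free exchange rate in 1/s; the reverse rate
    follows from detailed balance, ``k_fm = k_mf * f_m / (1 - f_m)``.
    ``b1_scale`` multiplies every nominal flip angle.
    """

    m0: float = 1.0
    f_m: float = 0.15
    t1_m: float = 400.0
    t1_f: float = 1000.0
    t2_m: float = 20.0
    t2_f: float = 80.0
    k_mf: float = 9.0
    delta_f0: float = 0.0
    b1_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_m < 1:
            raise ValueError("f_m must lie in [0, 1)")
        if self.t2_m >= self.t2_f:
            raise ValueError("t2_m must be < t2_f")
        if self.t1_m >= self.t1_f:
            raise ValueError("t1_m must be < t1_f")
        if self.k_mf < 0:
            raise ValueError("k_mf must be >= 0")

    @property
    def k_fm(self) -> float:
        if self.f_m >= 1:  # pragma: no cover - excluded by validation
            raise ValueError
        return self.k_mf * self.f_m / (1.0 - self.f_m)


# --------------------------------------------------------------------------
# EPG / CPMG
# --------------------------------------------------------------------------

def epg_cpmg_decay(t2, t1, protocol: GraseProtocol, refocus_actual: float,
                   m0: float = 1.0) -> np.ndarray:
    """Echo amplitudes of a CPMG train with imperfect refocusing.

    Excitation is an ideal 90deg pulse about x; refocusing pulses of flip
    ``refocus_actual`` (degrees) are applied about y at the CPMG condition.
    Configuration states relax (T2 on transverse, T1 on longitudinal; no
    regrowth — TE << T1 is assumed) and dephase by one gradient order per
    half echo spacing.  Echo ``i`` is ``|F_0|`` at the i-th echo time.

    Parameters
    ----------
    t2, t1 : float
        Relaxation times in ms.
    refocus_actual : float
        Actual refocusing flip angle beta in degrees, in (0, 180].

    Returns
    -------
    ndarray, shape (etl,)
    """
    beta = float(refocus_actual)
    if not 0 < beta <= 180:
        raise ValueError("refocusing flip angle must lie in (0, 180] degrees")
    if t2 <= 0 or t1 <= 0:
        raise ValueError("relaxation times must be > 0")

    etl = protocol.etl
    tau = protocol.te / 2.0
    e2 = np.exp(-tau / t2)
    e1 = np.exp(-tau / t1)

    n = etl + 2  # highest dephasing order reachable
    fp = np.zeros(n, dtype=complex)
    fm = np.zeros(n, dtype=complex)
    z = np.zeros(n, dtype=complex)

    # 90x excitation: M0 z-hat -> -y-hat, so F0 = Mx + iMy = -i m0
    fp[0] = -1j * m0
    fm[0] = np.conj(fp[0])

    # refocusing rotation about y (phase pi/2 relative to excitation)
    b = np.deg2rad(beta)
    c2, s2, sb, cb = (np.cos(b / 2) ** 2, np.sin(b / 2) ** 2,
                      np.sin(b), np.cos(b))
    # EPG rotation operator entries for axis phase phi = +90 deg
    # F+' =  c2 F+  - s2 F-  + sb Z
    # F-' = -s2 F+  + c2 F-  + sb Z
    # Z'  = -sb/2 F+ - sb/2 F- + cb Z      (phases folded in; validated
    #                                       against an isochromat simulation)
    echoes = np.empty(etl)

    def _evolve() -> None:
        nonlocal fp, fm, z
        fp *= e2
        fm *= e2
        z *= e1
        # dephase: F_k -> F_{k+1}
        fp[1:] = fp[:-1]
        fp[0] = np.conj(fm[1])
        fm[:-1] = fm[1:]
        fm[-1] = 0.0

    for i in range(etl):
        _evolve()
        fp_new = c2 * fp - s2 * fm + sb * z
        fm_new = -s2 * fp + c2 * fm + sb * z
        z_new = -0.5 * sb * fp - 0.5 * sb * fm + cb * z
        fp, fm, z = fp_new, fm_new, z_new
        # F0/F-0 consistency after rotation
        fm[0] = np.conj(fp[0])
        _evolve()
        echoes[i] = abs(fp[0])
    return echoes


def multicomponent_decay(weights, t2_grid, t1, protocol: GraseProtocol,
                         refocus_actual: float) -> np.ndarray:
    """Linear combination of EPG decays: ``sum_j w_j * epg(T2_j)``."""
    weights = np.asarray(weights, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if weights.shape != t2_grid.shape:
        raise ValueError("weights and T2 grid must have the same length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    out = np.zeros(protocol.etl)
    for w, t2 in zip(weights, t2_grid):
        if w > 0:
            out += w * epg_cpmg_decay(t2, t1, protocol, refocus_actual)
    return out


# --------------------------------------------------------------------------
# single-pool steady states
# --------------------------------------------------------------------------

def spgr_signal(m0, t1, alpha, tr, b1_scale=1.0):
    """Ideally spoiled gradient-echo steady state.

    ``S = m0 sin(ka) (1 - E1) / (1 - cos(ka) E1)`` with ``E1 = exp(-tr/t1)``.
    Accepts array inputs (broadcast).
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be > 0")
    a = np.deg2rad(np.asarray(alpha, dtype=float) * b1_scale)
    e1 = np.exp(-np.asarray(tr, dtype=float) / t1)
    return m0 * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)


def irspgr_signal(m0, t1, protocol: McDespotProtocol, b1_scale=1.0,
                  inv_efficiency=None):
    """Steady-state magnitude of the inversion-prepared SPGR readout.

    One cycle: inversion (efficiency ``eps``), TI of recovery, a single
    readout pulse ``k*ir_alpha``, then recovery to the next inversion
    (``ir_tr_total - ir_ti``).  The closed form is the fixed point of that
    recursion; the signal is read immediately after the readout pulse.
    """
    eps = protocol.inv_efficiency if inv_efficiency is None else inv_efficiency
    if not 0 < eps <= 1:
        raise ValueError("inv_efficiency must lie in (0, 1]")
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be > 0")
    a = np.deg2rad(protocol.ir_alpha * np.asarray(b1_scale, dtype=float))
    e_ti = np.exp(-protocol.ir_ti / t1)
    tau = protocol.ir_tr_total - protocol.ir_ti
    e_tau = np.exp(-tau / t1)
    ca = np.cos(a)
    # fixed point of the pre-inversion longitudinal magnetization x:
    #   after TI:   z = m0 (1 - e_ti) - eps x e_ti
    #   after read: z -> z cos(a)
    #   next x:     x = m0 (1 - e_tau) + cos(a) z e_tau
    x = (m0 * (1 - e_tau) + ca * e_tau * m0 * (1 - e_ti)) / \
        (1 + ca * eps * e_ti * e_tau)
    z_ti = m0 * (1 - e_ti) - eps * x * e_ti
    return np.abs(np.sin(a) * z_ti)


def bssfp_signal(m0, t1, t2, alpha, tr, delta_f0=0.0, phase_cycle=180.0,
                 b1_scale=1.0, return_complex=False):
    """Balanced SSFP steady-state magnitude at TE = TR/2.

    The steady state is the fixed point of: rotation by ``k*alpha`` about x,
    then precession by ``theta = 2*pi*delta_f0*tr + phase_cycle`` with
    relaxation (E1, E2) and longitudinal regrowth over one TR.  Solved as a
    3x3 linear system.  Scalars only; the batched two-pool code path covers
    volume work.
    """
    if t2 > t1:
        raise ValueError("t2 must be <= t1")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("relaxation times must be > 0")
    a = np.deg2rad(alpha * b1_scale)
    theta = 2 * np.pi * delta_f0 * (tr * 1e-3) + np.deg2rad(phase_cycle)
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)

    rx = np.array([[1, 0, 0],
                   [0, np.cos(a), np.sin(a)],
                   [0, -np.sin(a), np.cos(a)]])
    rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                   [np.sin(theta), np.cos(theta), 0],
                   [0, 0, 1.0]])
    d = np.diag([e2, e2, e1])
    c = np.array([0.0, 0.0, (1 - e1) * m0])

    sysmat = np.eye(3) - d @ rz @ rx
    if abs(np.linalg.det(sysmat)) < 1e-300:
        raise np.linalg.LinAlgError("singular bSSFP steady state")
    m_pre = np.linalg.solve(sysmat, c)
    m_post = rx @ m_pre
    mxy = (m_post[0] + 1j * m_post[1]) * np.exp(-0.5 * tr / t2)
    # half-TR free precession: pure phase, magnitude unaffected
    if return_complex:
        mxy *= np.exp(1j * (np.pi * delta_f0 * tr * 1e-3))
        return mxy
    return abs(mxy)


# --------------------------------------------------------------------------
# batched 2x2 matrix exponential helpers (two-pool evolution)
# --------------------------------------------------------------------------

def _expm2(a):
    """Closed-form exp of (..., 2, 2) matrices via eigenvalues.

    Works for real or complex input; falls back to a symmetric-limit series
    when the eigenvalues coincide.
    """
    a = np.asarray(a)
    tr = a[..., 0, 0] + a[..., 1, 1]
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    disc = tr * tr / 4.0 - det
    s = np.sqrt(disc.astype(complex))
    l1 = tr / 2.0 + s
    l2 = tr / 2.0 - s
    e1 = np.exp(l1)
    e2 = np.exp(l2)
    diff = l1 - l2
    small = np.abs(diff) < 1e-9
    # exp(A) = e2 * (I*(1 - l2*phi) + phi*A), phi = (e1-e2)/(e1*... derived:
    # exp(A) = (e1 (A - l2 I) - e2 (A - l1 I)) / (l1 - l2)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(small, e1, (e1 - e2) / np.where(small, 1.0, diff))
        c0 = np.where(small, e1 * (1 - l1), (l1 * e2 - l2 * e1)
                      / np.where(small, 1.0, diff))
    out = c1[..., None, None] * a + c0[..., None, None] * np.eye(2)
    if np.isrealobj(a):
        return out.real
    return out


def _longitudinal_system(p, tr_ms):
    """Two-pool longitudinal evolution over ``tr_ms``: returns (E_L, c_L)
    with M(t+tr) = E_L M(t) + c_L.  All inputs broadcastable arrays."""
    r1m = 1.0 / p["t1_m"]
    r1f = 1.0 / p["t1_f"]
    kmf = p["k_mf"] * 1e-3  # 1/s -> 1/ms
    kfm = kmf * p["f_m"] / (1.0 - p["f_m"])
    m0m = p["m0"] * p["f_m"]
    m0f = p["m0"] * (1.0 - p["f_m"])

    shape = np.broadcast(r1m, r1f, kmf).shape
    a = np.empty(shape + (2, 2))
    a[..., 0, 0] = -(r1m + kmf)
    a[..., 0, 1] = kfm
    a[..., 1, 0] = kmf
    a[..., 1, 1] = -(r1f + kfm)
    b = np.empty(shape + (2,))
    b[..., 0] = m0m * r1m
    b[..., 1] = m0f * r1f

    el = _expm2(a * tr_ms)
    # c = (E - I) A^{-1} b
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    ainv_b = np.stack(
        [(a[..., 1, 1] * b[..., 0] - a[..., 0, 1] * b[..., 1]) / det,
         (a[..., 0, 0] * b[..., 1] - a[..., 1, 0] * b[..., 0]) / det],
        axis=-1)
    cl = np.einsum("...ij,...j->...i", el, ainv_b) - ainv_b
    return el, cl


def _transverse_propagator(p, dt_ms, omega_rad_per_ms):
    """Complex 2x2 propagator for (m+_myelin, m+_free) over ``dt_ms``."""
    r2m = 1.0 / p["t2_m"]
    r2f = 1.0 / p["t2_f"]
    kmf = p["k_mf"] * 1e-3
    kfm = kmf * p["f_m"] / (1.0 - p["f_m"])
    shape = np.broadcast(r2m, r2f, kmf, omega_rad_per_ms).shape
    a = np.zeros(shape + (2, 2), dtype=complex)
    a[..., 0, 0] = -(r2m + kmf) - 1j * omega_rad_per_ms
    a[..., 0, 1] = kfm
    a[..., 1, 0] = kmf
    a[..., 1, 1] = -(r2f + kfm) - 1j * omega_rad_per_ms
    return _expm2(a * dt_ms)


def _params_dict(params: TwoPoolParams) -> dict:
    return {f.name: np.asarray(getattr(params, f.name), dtype=float)
            for f in dataclasses.fields(TwoPoolParams)}


def two_pool_spgr(params, alpha, tr, _p=None):
    """Two-pool SPGR steady state (sum of pool transverse magnitudes).

    ``params`` may be a :class:`TwoPoolParams` or a dict of broadcastable
    arrays with the same field names (the batched code path).
    """
    p = _params_dict(params) if isinstance(params, TwoPoolParams) else params
    a = np.deg2rad(alpha * p["b1_scale"])
    el, cl = _longitudinal_system(p, tr) if _p is None else _p
    ca = np.cos(a)
    eye = np.eye(2)
    sysmat = eye - el * ca[..., None, None]
    m_pre = np.linalg.solve(sysmat, cl[..., None])[..., 0]
    return np.abs(np.sin(a) * (m_pre[..., 0] + m_pre[..., 1]))


def two_pool_bssfp(params, alpha, tr, phase_cycle):
    """Two-pool bSSFP steady-state magnitude at TE = TR/2.

    6-dimensional fixed point (x, y, z per pool) of instantaneous rotation
    about x followed by coupled relaxation/exchange/precession over TR, the
    phase-cycle increment folded into the effective precession rate.
    """
    p = _params_dict(params) if isinstance(params, TwoPoolParams) else params
    a = np.deg2rad(alpha * p["b1_scale"])
    w_phys = 2 * np.pi * p["delta_f0"] * 1e-3          # rad/ms
    w_eff = w_phys + np.deg2rad(phase_cycle) / tr

    et = _transverse_propagator(p, tr, w_eff)          # complex 2x2
    el, cl = _longitudinal_system(p, tr)

    shape = et.shape[:-2]
    # real 6x6 evolution: order (xm, xf, ym, yf, zm, zf)
    ev = np.zeros(shape + (6, 6))
    ev[..., 0:2, 0:2] = et.real
    ev[..., 0:2, 2:4] = -et.imag
    ev[..., 2:4, 0:2] = et.imag
    ev[..., 2:4, 2:4] = et.real
    ev[..., 4:6, 4:6] = el
    c = np.zeros(shape + (6,))
    c[..., 4:6] = cl

    # rotation about x by a: y' = y cos a + z sin a ; z' = -y sin a + z cos a
    ca, sa = np.cos(a), np.sin(a)
    rot = np.zeros(shape + (6, 6))
    rot[..., 0, 0] = rot[..., 1, 1] = 1.0
    rot[..., 2, 2] = rot[..., 3, 3] = ca
    rot[..., 2, 4] = rot[..., 3, 5] = sa
    rot[..., 4, 2] = rot[..., 5, 3] = -sa
    rot[..., 4, 4] = rot[..., 5, 5] = ca

    sysmat = np.eye(6) - np.einsum("...ij,...jk->...ik", ev, rot)
    m_pre = np.linalg.solve(sysmat, c[..., None])[..., 0]
    if not np.all(np.isfinite(m_pre)):
        raise FloatingPointError("non-finite bSSFP steady state")
    m_post = np.einsum("...ij,...j->...i", rot, m_pre)

    mp = np.empty(shape + (2,), dtype=complex)
    mp[..., 0] = m_post[..., 0] + 1j * m_post[..., 2]
    mp[..., 1] = m_post[..., 1] + 1j * m_post[..., 3]
    ete = _transverse_propagator(p, tr / 2.0, w_phys)
    m_te = np.einsum("...ij,...j->...i", ete, mp)
    return np.abs(m_te[..., 0] + m_te[..., 1])


def two_pool_irspgr(params, protocol: McDespotProtocol):
    """Two-pool inversion-prepared SPGR steady-state magnitude."""
    p = _params_dict(params) if isinstance(params, TwoPoolParams) else params
    eps = protocol.inv_efficiency
    a = np.deg2rad(protocol.ir_alpha * p["b1_scale"])
    el_ti, cl_ti = _longitudinal_system(p, protocol.ir_ti)
    tau = protocol.ir_tr_total - protocol.ir_ti
    el_tau, cl_tau = _longitudinal_system(p, tau)

    # x: pre-inversion 2-vector; cycle: x -> E_tau (cos(a) (E_ti (-eps x) + c_ti)) + c_tau
    ca = np.cos(a)
    m_cycle = -eps * ca[..., None, None] * np.einsum(
        "...ij,...jk->...ik", el_tau, el_ti)
    rhs = np.einsum("...ij,...j->...i", el_tau, ca[..., None] * cl_ti) + cl_tau
    x = np.linalg.solve(np.eye(2) - m_cycle, rhs[..., None])[..., 0]
    z_ti = np.einsum("...ij,...j->...i", el_ti, -eps * x) + cl_ti
    return np.abs(np.sin(a) * (z_ti[..., 0] + z_ti[..., 1]))


def _solve2(m, b):
    """Manual batched 2x2 solve (much faster than np.linalg.solve here)."""
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    x0 = (m[..., 1, 1] * b[..., 0] - m[..., 0, 1] * b[..., 1]) / det
    x1 = (m[..., 0, 0] * b[..., 1] - m[..., 1, 0] * b[..., 0]) / det
    return np.stack([x0, x1], axis=-1)


def two_pool_signals(params, protocol: McDespotProtocol) -> np.ndarray:
    """Full mcDESPOT signal set: SPGR per alpha, bSSFP per (phase cycle,
    alpha), then the IR-SPGR signal.  Broadcasts over batched parameter
    dicts; returns an array with signal index on the last axis.

    This is the hot path of the stochastic-region-contraction fitter, so the
    per-phase-cycle propagators are shared across flip angles and the small
    linear solves avoid generic LAPACK where a closed form exists.  Equality
    with the readable single-setting functions is covered by tests.
    """
    p = _params_dict(params) if isinstance(params, TwoPoolParams) else params
    shape = np.broadcast(p["f_m"], p["t1_f"], p["b1_scale"]).shape
    n_sig = protocol.n_signals
    out = np.empty(shape + (n_sig,))

    # --- SPGR block ------------------------------------------------------
    el, cl = _longitudinal_system(p, protocol.spgr_tr)
    for i, alpha in enumerate(protocol.spgr_alphas):
        a = np.deg2rad(alpha * p["b1_scale"])
        ca = np.cos(a)[..., None, None]
        m_pre = _solve2(np.eye(2) - ca * el, cl)
        out[..., i] = np.abs(np.sin(a) * (m_pre[..., 0] + m_pre[..., 1]))

    # --- bSSFP block -----------------------------------------------------
    tr = protocol.bssfp_tr
    el_b, cl_b = _longitudinal_system(p, tr)
    w_phys = 2 * np.pi * p["delta_f0"] * 1e-3
    ete = _transverse_propagator(p, tr / 2.0, w_phys)
    eye6 = np.eye(6)
    idx = len(protocol.spgr_alphas)
    for pc in protocol.bssfp_phase_cycles:
        w_eff = w_phys + np.deg2rad(pc) / tr
        et = _transverse_propagator(p, tr, w_eff)
        ev = np.zeros(shape + (6, 6))
        ev[..., 0:2, 0:2] = et.real
        ev[..., 0:2, 2:4] = -et.imag
        ev[..., 2:4, 0:2] = et.imag
        ev[..., 2:4, 2:4] = et.real
        ev[..., 4:6, 4:6] = el_b
        c = np.zeros(shape + (6,))
        c[..., 4:6] = cl_b
        for alpha in protocol.bssfp_alphas:
            a = np.deg2rad(alpha * p["b1_scale"])
            ca, sa = np.cos(a)[..., None, None], np.sin(a)[..., None, None]
            # ev @ rot(a) using the sparsity of the x-rotation
            sysmat = np.empty(shape + (6, 6))
            sysmat[..., :, 0:2] = -ev[..., :, 0:2]
            sysmat[..., :, 2:4] = -(ca * ev[..., :, 2:4]
                                    - sa * ev[..., :, 4:6])
            sysmat[..., :, 4:6] = -(sa * ev[..., :, 2:4]
                                    + ca * ev[..., :, 4:6])
            sysmat += eye6
            m_pre = np.linalg.solve(sysmat, c[..., None])[..., 0]
            ca1, sa1 = np.cos(a), np.sin(a)
            # after-pulse transverse components (x unchanged)
            ym = ca1 * m_pre[..., 2] + sa1 * m_pre[..., 4]
            yf = ca1 * m_pre[..., 3] + sa1 * m_pre[..., 5]
            mp_m = m_pre[..., 0] + 1j * ym
            mp_f = m_pre[..., 1] + 1j * yf
            s_m = ete[..., 0, 0] * mp_m + ete[..., 0, 1] * mp_f
            s_f = ete[..., 1, 0] * mp_m + ete[..., 1, 1] * mp_f
            out[..., idx] = np.abs(s_m + s_f)
            idx += 1

    # --- IR-SPGR ---------------------------------------------------------
    out[..., idx] = two_pool_irspgr(p, protocol)
    return out


# --------------------------------------------------------------------------
# magnetization transfer and noise
# --------------------------------------------------------------------------

def mt_pair(m0_map, mt_delta, t1, protocol: MtProtocol = MtProtocol(),
            b1_scale=1.0):
    """Forward MT pair: unsaturated image M0 (SPGR at the MT protocol
    settings) and saturated image Ms = M0 (1 - delta)."""
    delta = np.asarray(mt_delta, dtype=float)
    if np.any(delta < 0) or np.any(delta >= 1):
        raise ValueError("mt saturation fraction must lie in [0, 1)")
    m0_img = spgr_signal(m0_map, t1, protocol.alpha, protocol.tr, b1_scale)
    ms_img = m0_img * (1.0 - delta)
    return m0_img, ms_img


def add_rician_noise(signal, snr, rng, reference=None):
    """Magnitude of the signal plus complex Gaussian noise.

    sigma = reference / snr; ``reference`` defaults to the maximum of the
    (pre-noise) signal.
    """
    signal = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if np.isinf(snr):
        return signal.copy()
    ref = float(np.max(signal)) if reference is None else float(reference)
    sigma = ref / snr
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)
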