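"""Independent oracles used by the test suite.

Everything here is implemented from first principles (explicit rotation
matrices, brute-force iteration, exhaustive enumeration) and deliberately
shares no code with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg


def rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]], dtype=float)


def rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]], dtype=float)


def rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def isochromat_cpmg(t2, t1, te, etl, beta_deg, n_spins=4096):
    """Brute-force CPMG echo train: a fan of isochromats under ideal
    crushers (one full cycle of extra dephasing per half echo spacing),
    90deg excitation about x, refocusing about y, no regrowth."""
    tau = te / 2.0
    e2, e1 = np.exp(-tau / t2), np.exp(-tau / t1)
    phis = 2 * np.pi * np.arange(n_spins) / n_spins
    m = np.zeros((n_spins, 3))
    m[:, 2] = 1.0
    m = m @ rot_x(np.pi / 2).T
    rb = rot_y(np.deg2rad(beta_deg))

    def evolve(m):
        c, s = np.cos(phis), np.sin(phis)
        x = m[:, 0] * c - m[:, 1] * s
        y = m[:, 0] * s + m[:, 1] * c
        return np.column_stack([x * e2, y * e2, m[:, 2] * e1])

    echoes = []
    for _ in range(etl):
        m = evolve(m) @ rb.T
        m = evolve(m)
        echoes.append(abs(np.mean(m[:, 0] + 1j * m[:, 1])))
    return np.array(echoes)


def spgr_iterated(m0, t1, alpha_deg, tr, kappa=1.0, n=20000):
    """Steady state by brute-force iteration with perfect spoiling."""
    a = np.deg2rad(alpha_deg * kappa)
    e1 = np.exp(-tr / t1)
    mz = m0
    for _ in range(n):
        s = mz * np.sin(a)
        mz = m0 * (1 - e1) + mz * np.cos(a) * e1
    return s


def irspgr_iterated(m0, t1, ti, tr_total, alpha_deg, kappa=1.0, eff=1.0,
                    n=500):
    """Inversion-prepared recovery cycle iterated to steady state."""
    a = np.deg2rad(alpha_deg * kappa)
    e_ti = np.exp(-ti / t1)
    e_tau = np.exp(-(tr_total - ti) / t1)
    x = m0
    for _ in range(n):
        z = m0 * (1 - e_ti) - eff * x * e_ti
        sig = abs(np.sin(a) * z)
        x = m0 * (1 - e_tau) + z * np.cos(a) * e_tau
    return sig


def bssfp_iterated(m0, t1, t2, alpha_deg, tr, df0_hz=0.0, pc_deg=180.0,
                   kappa=1.0, n=20000):
    """bSSFP steady state by iterating rotation -> precession/relaxation."""
    a = np.deg2rad(alpha_deg * kappa)
    th = 2 * np.pi * df0_hz * tr * 1e-3 + np.deg2rad(pc_deg)
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    d = np.diag([e2, e2, e1])
    c = np.array([0, 0, (1 - e1) * m0])
    m = np.array([0.0, 0.0, m0])
    op = d @ rot_z(th) @ rot_x(a)
    for _ in range(n):
        m = op @ m + c
    mp = rot_x(a) @ m
    return abs(mp[0] + 1j * mp[1]) * np.exp(-0.5 * tr / t2)


def _two_pool_matrices(p, w_rad_ms):
    """Full 6x6 Bloch-McConnell generator in (x, y, z) x (m, f) ordering:
    state = (xm, xf, ym, yf, zm, zf)."""
    kmf = p["k_mf"] * 1e-3
    kfm = kmf * p["f_m"] / (1 - p["f_m"])
    r2m, r2f = 1 / p["t2_m"], 1 / p["t2_f"]
    r1m, r1f = 1 / p["t1_m"], 1 / p["t1_f"]
    ex = np.array([[-kmf, kfm], [kmf, -kfm]])
    a = np.zeros((6, 6))
    a[0:2, 0:2] = ex - np.diag([r2m, r2f])
    a[2:4, 2:4] = ex - np.diag([r2m, r2f])
    a[4:6, 4:6] = ex - np.diag([r1m, r1f])
    a[0:2, 2:4] += np.eye(2) * w_rad_ms
    a[2:4, 0:2] -= np.eye(2) * w_rad_ms
    b = np.array([0, 0, 0, 0,
                  p["m0"] * p["f_m"] * r1m, p["m0"] * (1 - p["f_m"]) * r1f])
    return a, b


def two_pool_bssfp_iterated(params, alpha_deg, tr, pc_deg, n=6000):
    """Two-pool bSSFP fixed point via scipy.linalg.expm and iteration."""
    p = {k: float(getattr(params, k)) for k in
         ("m0", "f_m", "t1_m", "t1_f", "t2_m", "t2_f", "k_mf",
          "delta_f0", "b1_scale")}
    w_eff = 2 * np.pi * p["delta_f0"] * 1e-3 + np.deg2rad(pc_deg) / tr
    a_mat, b = _two_pool_matrices(p, w_eff)
    e_tr = scipy.linalg.expm(a_mat * tr)
    c = e_tr @ np.linalg.solve(a_mat, b) - np.linalg.solve(a_mat, b)
    aa = np.deg2rad(alpha_deg * p["b1_scale"])
    rot = np.zeros((6, 6))
    rot[0:2, 0:2] = np.eye(2)
    rot[2:4, 2:4] = np.cos(aa) * np.eye(2)
    rot[2:4, 4:6] = np.sin(aa) * np.eye(2)
    rot[4:6, 2:4] = -np.sin(aa) * np.eye(2)
    rot[4:6, 4:6] = np.cos(aa) * np.eye(2)
    m = np.zeros(6)
    m[4] = p["m0"] * p["f_m"]
    m[5] = p["m0"] * (1 - p["f_m"])
    for _ in range(n):
        m = e_tr @ (rot @ m) + c
    m_post = rot @ m
    w_phys = 2 * np.pi * p["delta_f0"] * 1e-3
    a_te, _ = _two_pool_matrices(p, w_phys)
    m_te = scipy.linalg.expm(a_te * tr / 2.0) @ m_post
    return abs((m_te[0] + m_te[1]) + 1j * (m_te[2] + m_te[3]))


def two_pool_spgr_iterated(params, alpha_deg, tr, n=6000):
    p = {k: float(getattr(params, k)) for k in
         ("m0", "f_m", "t1_m", "t1_f", "t2_m", "t2_f", "k_mf", "b1_scale")}
    kmf = p["k_mf"] * 1e-3
    kfm = kmf * p["f_m"] / (1 - p["f_m"])
    r1m, r1f = 1 / p["t1_m"], 1 / p["t1_f"]
    a_mat = np.array([[-(r1m + kmf), kfm], [kmf, -(r1f + kfm)]])
    b = np.array([p["m0"] * p["f_m"] * r1m, p["m0"] * (1 - p["f_m"]) * r1f])
    e = scipy.linalg.expm(a_mat * tr)
    c = e @ np.linalg.solve(a_mat, b) - np.linalg.solve(a_mat, b)
    aa = np.deg2rad(alpha_deg * p["b1_scale"])
    mz = np.array([p["m0"] * p["f_m"], p["m0"] * (1 - p["f_m"])])
    for _ in range(n):
        mz = e @ (np.cos(aa) * mz) + c
    return abs(np.sin(aa) * mz.sum())


def streaming_mean_sd(stack):
    """Welford's online mean/SD (ddof=1) over the leading axis."""
    n = 0
    mean = np.zeros_like(stack[0], dtype=float)
    m2 = np.zeros_like(stack[0], dtype=float)
    for x in stack:
        n += 1
        delta = x - mean
        mean = mean + delta / n
        m2 = m2 + delta * (x - mean)
    return mean, np.sqrt(m2 / (n - 1))


def holm_brute_force(p_raw):
    """Step-down Holm by direct definition: adjusted p_(i) is the running
    max of (m - j + 1) p_(j) over j <= i in the sorted order."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = []
    for i in range(m):
        vals = [(m - j) * p[order[j]] for j in range(i + 1)]
        adj_sorted.append(min(1.0, max(vals)))
    out = np.empty(m)
    for i, idx in enumerate(order):
        out[idx] = adj_sorted[i]
    return out


def friedman_exact_enumeration(matrix):
    """Exact permutation p of the Friedman statistic by enumerating every
    combination of within-subject orderings."""
    import scipy.stats
    a = np.asarray(matrix, dtype=float)
    n, k = a.shape
    ranks = scipy.stats.rankdata(a, axis=1)

    def stat(r):
        rbar = r.mean(axis=0)
        return 12.0 * n / (k * (k + 1)) * np.sum(
            (rbar - (k + 1) / 2.0) ** 2)

    observed = stat(ranks)
    perms = [np.array(p) for p in itertools.permutations(range(k))]
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        r = np.stack([ranks[i][combo[i]] for i in range(n)])
        total += 1
        if stat(r) >= observed - 1e-12:
            hits += 1
    return observed, hits / total


def wilcoxon_exact_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    import scipy.stats
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))
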