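"""Forward simulation of the four acquisitions for a phantom subject.

Ground-truth parameter volumes are piecewise constant over tissue classes,
so signals are evaluated once per distinct parameter combination and
broadcast back to voxels before Rician noise is added.
"""

from __future__ import annotations

import numpy as np

from . import signals as sig
from .cohort import LABELS, SubjectGroundTruth

__all__ = ["simulate_acquisitions"]


def _unique_rows(param_stack):
    """(V, P) -> unique rows + inverse indices."""
    uniq, inverse = np.unique(param_stack, axis=0, return_inverse=True)
    return uniq, inverse


def simulate_acquisitions(subject: SubjectGroundTruth,
                          grase: sig.GraseProtocol = sig.GraseProtocol(),
                          mcdespot: sig.McDespotProtocol = sig.McDespotProtocol(),
                          mt: sig.MtProtocol = sig.MtProtocol(),
                          snr: dict | None = None,
                          rng=None,
                          modalities=("grase", "mcdespot", "mt")) -> dict:
    """Simulate noisy magnitude acquisitions on the subject's grid.

    Returns a dict with keys among ``grase`` (..., etl), ``spgr``
    (..., n_alpha), ``irspgr`` (...), ``bssfp`` (..., n_pc, n_alpha) and
    ``mt`` (..., 2).  ``snr`` maps sequence family to SNR (np.inf allowed);
    noise sigma is referenced to the mean WM first GRASE echo and to the
    maximum pre-noise signal for the other families.
    """
    snr = {**{"grase": np.inf, "mcdespot": np.inf, "mt": np.inf},
           **(snr or {})}
    rng = np.random.default_rng(0) if rng is None else rng
    shape = subject.labels.shape
    brain = subject.brain_mask.ravel()
    idx = np.nonzero(brain)[0]
    p = {k: v.ravel()[idx] for k, v in subject.params.items()}
    stack = np.column_stack([p[k] for k in sorted(p)])
    keys = sorted(p)
    uniq, inverse = _unique_rows(stack)
    u = {k: uniq[:, i] for i, k in enumerate(keys)}
    wm_flat = ((subject.labels == LABELS["wm"]).ravel())[idx]

    out = {}

    if "grase" in modalities:
        n_u = len(uniq)
        table = np.zeros((n_u, grase.etl))
        for i in range(n_u):
            table[i] = u["proton_density"][i] * sig.multicomponent_decay(
                [u["w_short"][i], 1 - u["w_short"][i]],
                [u["t2_short"][i], u["t2_long"][i]],
                u["t1"][i], grase, grase.refocus_nominal)
        flat = table[inverse]
        vol = np.zeros(shape + (grase.etl,))
        vol.reshape(-1, grase.etl)[idx] = flat
        ref = flat[wm_flat, 0].mean() if wm_flat.any() else flat[:, 0].mean()
        out["grase"] = sig.add_rician_noise(vol, snr["grase"], rng, ref)

    if "mcdespot" in modalities:
        params = {"m0": u["proton_density"], "f_m": np.clip(u["w_short"],
                                                            0, 0.999),
                  "t1_m": np.minimum(u["t1_myelin"], u["t1"] - 1e-6),
                  "t1_f": u["t1"],
                  "t2_m": np.minimum(u["t2_short"], u["t2_long"] - 1e-6),
                  "t2_f": u["t2_long"], "k_mf": u["k_mf"],
                  "delta_f0": np.zeros(len(uniq)),
                  "b1_scale": np.ones(len(uniq))}
        table = sig.two_pool_signals(params, mcdespot)
        flat = table[inverse]
        ref = flat.max()
        n_sp = len(mcdespot.spgr_alphas)
        n_al = len(mcdespot.bssfp_alphas)
        n_pc = len(mcdespot.bssfp_phase_cycles)
        full = np.zeros(shape + (mcdespot.n_signals,))
        full.reshape(-1, mcdespot.n_signals)[idx] = flat
        noisy = sig.add_rician_noise(full, snr["mcdespot"], rng, ref)
        out["spgr"] = noisy[..., :n_sp]
        out["bssfp"] = noisy[..., n_sp:n_sp + n_pc * n_al].reshape(
            shape + (n_pc, n_al))
        out["irspgr"] = noisy[..., -1]
    if "mt" in modalities:
        m0_img, ms_img = sig.mt_pair(u["proton_density"], u["mt_delta"],
                                     u["t1"], mt)
        pair = np.stack([m0_img[inverse], ms_img[inverse]], axis=-1)
        vol = np.zeros(shape + (2,))
        vol.reshape(-1, 2)[idx] = pair
        out["mt"] = sig.add_rician_noise(vol, snr["mt"], rng, pair.max())
    return out
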