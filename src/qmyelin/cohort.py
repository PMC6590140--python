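"""Synthetic co-registered brain cohort with ground-truth tissue parameters.

A parametric nested-ellipsoid head phantom stands in for atlas-derived
anatomy: a gray-matter shell encloses a white-matter core containing
subcortical nuclei and CSF ventricles.  Patients receive focal spherical WM
lesions with shifted relaxation/myelin parameters (count and load matched to
typical relapsing-remitting MS statistics), plus a perilesional rim obtained
by metric dilation.  All subjects share the voxel grid, so no registration
step is needed downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage

__all__ = [
    "LABELS",
    "PhantomGeometry",
    "TissueParams",
    "LesionModel",
    "SubjectGroundTruth",
    "CohortConfig",
    "default_tissues",
    "build_label_volume",
    "sample_subject",
    "place_lesions",
    "dilate_mask",
    "generate_cohort",
]

LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3,
          "subcortical": 4, "lesion": 5}

#: per-voxel ground-truth parameter volumes carried by a subject
PARAM_NAMES = ("t1", "t1_myelin", "t2_short", "t2_long", "w_short",
               "mt_delta", "proton_density", "k_mf")

MYELIN_WINDOW = (10.0, 40.0)


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomGeometry:
    """Nested-ellipsoid head geometry; all radii/offsets in mm from the grid
    center."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    brain_radii: tuple = (70.0, 78.0, 65.0)
    wm_radii: tuple = (54.0, 62.0, 48.0)
    subcortical_radii: tuple = (11.0, 15.0, 11.0)
    subcortical_offsets: tuple = ((-22.0, 0.0, 0.0), (22.0, 0.0, 0.0))
    ventricle_radii: tuple = (7.0, 18.0, 9.0)
    ventricle_offsets: tuple = ((-10.0, -4.0, 4.0), (10.0, -4.0, 4.0))

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be >= 16 per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be > 0")
        for name in ("brain_radii", "wm_radii", "subcortical_radii",
                     "ventricle_radii"):
            if any(r <= 0 for r in getattr(self, name)):
                raise ConfigurationError(f"{name} must all be > 0")
        fov = [s * v / 2 for s, v in zip(self.grid_shape, self.voxel_size)]
        if any(r > f for r, f in zip(self.brain_radii, fov)):
            raise ConfigurationError("brain exceeds the field of view")
        if any(w >= b for w, b in zip(self.wm_radii, self.brain_radii)):
            raise ConfigurationError("WM core must nest inside the brain")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.voxel_size, 1.0))
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2 * self.voxel_size
        return aff

    def coordinate_grids(self):
        """Physical mm coordinates of voxel centers, origin at grid center."""
        axes = [(np.arange(n) - (n - 1) / 2) * v
                for n, v in zip(self.grid_shape, self.voxel_size)]
        return np.meshgrid(*axes, indexing="ij")


def _inside_ellipsoid(grids, radii, offset=(0.0, 0.0, 0.0)):
    q = sum(((g - o) / r) ** 2 for g, r, o in zip(grids, radii, offset))
    return q <= 1.0


def build_label_volume(geometry: PhantomGeometry) -> np.ndarray:
    """Assign each voxel exactly one tissue label (no lesions yet)."""
    grids = geometry.coordinate_grids()
    labels = np.zeros(geometry.grid_shape, dtype=np.uint8)
    labels[_inside_ellipsoid(grids, geometry.brain_radii)] = LABELS["gm"]
    labels[_inside_ellipsoid(grids, geometry.wm_radii)] = LABELS["wm"]
    for off in geometry.subcortical_offsets:
        labels[_inside_ellipsoid(grids, geometry.subcortical_radii, off)] = \
            LABELS["subcortical"]
    for off in geometry.ventricle_offsets:
        labels[_inside_ellipsoid(grids, geometry.ventricle_radii, off)] = \
            LABELS["csf"]
    for name in ("csf", "gm", "wm", "subcortical"):
        if not np.any(labels == LABELS[name]):
            raise ConfigurationError(f"geometry produces no {name} voxels")
    return labels


# --------------------------------------------------------------------------
# tissue parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParams:
    """Ground-truth NMR parameters of one tissue class (3T-typical).

    ``t2_components`` is a tuple of (T2 ms, weight) with weights summing to
    one; the true myelin water fraction is the summed weight of components
    inside the 10-40 ms window.  ``cv`` is the between-subject fractional
    coefficient of variation applied per parameter.
    """

    name: str
    t1: float
    t2_components: tuple
    mt_delta: float
    proton_density: float = 1.0
    t1_myelin: float | None = None
    k_mf: float = 9.0
    cv: float = 0.05

    def __post_init__(self) -> None:
        if self.t1 <= 0 or any(t <= 0 for t, _ in self.t2_components):
            raise ConfigurationError("relaxation times must be > 0")
        if abs(sum(w for _, w in self.t2_components) - 1.0) > 1e-9:
            raise ConfigurationError("t2 component weights must sum to 1")
        if not 0 <= self.mt_delta < 1:
            raise ConfigurationError("mt_delta must lie in [0, 1)")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")

    @property
    def mwf_true(self) -> float:
        return sum(w for t, w in self.t2_components
                   if MYELIN_WINDOW[0] <= t <= MYELIN_WINDOW[1])

    @property
    def t1_myelin_effective(self) -> float:
        if self.t1_myelin is not None:
            return self.t1_myelin
        return float(np.clip(0.45 * self.t1, 250.0, 600.0))

    def short_long(self):
        """Collapse the component list to (t2_short, t2_long, w_short) with
        the myelin window defining 'short'."""
        short = [(t, w) for t, w in self.t2_components
                 if MYELIN_WINDOW[0] <= t <= MYELIN_WINDOW[1]]
        long_ = [(t, w) for t, w in self.t2_components
                 if not MYELIN_WINDOW[0] <= t <= MYELIN_WINDOW[1]]
        w_s = sum(w for _, w in short)
        t_s = (sum(t * w for t, w in short) / w_s) if w_s > 0 else 20.0
        w_l = sum(w for _, w in long_)
        t_l = (sum(t * w for t, w in long_) / w_l) if w_l > 0 else 80.0
        return t_s, t_l, w_s


def default_tissues() -> dict:
    """Literature-typical 3T parameter set (configurable stand-ins; the
    study publishes no ground truth)."""
    return {
        "wm": TissueParams("wm", t1=900.0,
                           t2_components=((20.0, 0.12), (80.0, 0.88)),
                           mt_delta=0.40),
        "gm": TissueParams("gm", t1=1300.0,
                           t2_components=((20.0, 0.03), (90.0, 0.97)),
                           mt_delta=0.30),
        "csf": TissueParams("csf", t1=4000.0,
                            t2_components=((2000.0, 1.0),),
                            mt_delta=0.02, k_mf=1.0),
        "subcortical": TissueParams("subcortical", t1=1100.0,
                                    t2_components=((20.0, 0.08), (85.0, 0.92)),
                                    mt_delta=0.35),
    }


# --------------------------------------------------------------------------
# lesions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionModel:
    """Focal WM lesion statistics and in-lesion parameter shifts.

    Lesion count per patient is negative-binomial (mean/dispersion) truncated
    to ``count_range``; radii are log-normal in mm.  Defaults reproduce a
    mean count of ~26.5 within a 3-71 range and a lesion load of ~0.5% of
    the WM volume on the default geometry.
    """

    count_mean: float = 26.5
    count_dispersion: float = 4.0
    count_range: tuple = (3, 71)
    radius_log_mean: float = float(np.log(2.58))
    radius_log_sd: float = 0.35
    perilesion_radius: float = 2.0
    mwf_scale: float = 0.4
    t1_scale: float = 1.3
    mt_delta_scale: float = 0.5
    long_t2_scale: float = 1.2
    water_scale: float = 1.1

    def __post_init__(self) -> None:
        if self.perilesion_radius <= 0:
            raise ConfigurationError("perilesion_radius must be > 0")
        if not 0 < self.mwf_scale <= 1 or not 0 < self.mt_delta_scale <= 1:
            raise ConfigurationError(
                "mwf/mt_delta lesion scales must lie in (0, 1]")
        if self.t1_scale < 1 or self.long_t2_scale < 1 or self.water_scale < 1:
            raise ConfigurationError(
                "t1/long-T2/water lesion scales must be >= 1")

    def draw_count(self, rng) -> int:
        p = self.count_dispersion / (self.count_dispersion + self.count_mean)
        lo, hi = self.count_range
        for _ in range(1000):
            c = rng.negative_binomial(self.count_dispersion, p)
            if lo <= c <= hi:
                return int(c)
        return int(np.clip(c, lo, hi))


@dataclass
class SubjectGroundTruth:
    subject_id: str
    group: str  # "control" | "patient"
    labels: np.ndarray
    params: dict  # name -> float volume, keys PARAM_NAMES
    lesion_mask: np.ndarray
    perilesion_mask: np.ndarray
    geometry: PhantomGeometry

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    @property
    def mwf_map(self) -> np.ndarray:
        return self.params["w_short"]

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def sample_subject(tissues: dict, labels: np.ndarray, group: str, rng,
                   subject_id: str = "subj",
                   geometry: PhantomGeometry | None = None
                   ) -> SubjectGroundTruth:
    """Realize per-voxel ground-truth parameters for one subject.

    Each tissue class receives one multiplicative log-normal deviation per
    parameter (between-subject variation, sd ``cv`` on the linear scale);
    voxels of a class share the subject's realization.
    """
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    shape = labels.shape
    params = {k: np.zeros(shape) for k in PARAM_NAMES}
    for name, tis in tissues.items():
        sel = labels == LABELS[name]
        if not np.any(sel):
            continue
        sigma = np.sqrt(np.log1p(tis.cv ** 2))

        def draw(mean):
            return mean * np.exp(rng.normal(0.0, sigma)) if sigma > 0 else mean

        t_s, t_l, w_s = tis.short_long()
        params["t1"][sel] = draw(tis.t1)
        params["t1_myelin"][sel] = draw(tis.t1_myelin_effective)
        params["t2_short"][sel] = draw(t_s)
        params["t2_long"][sel] = draw(t_l)
        params["w_short"][sel] = min(draw(w_s), 0.95)
        params["mt_delta"][sel] = min(draw(tis.mt_delta), 0.95)
        params["proton_density"][sel] = draw(tis.proton_density)
        params["k_mf"][sel] = tis.k_mf
    empty = np.zeros(shape, dtype=bool)
    return SubjectGroundTruth(subject_id=subject_id, group=group,
                              labels=labels.copy(), params=params,
                              lesion_mask=empty, perilesion_mask=empty.copy(),
                              geometry=geometry or PhantomGeometry(
                                  grid_shape=shape))


def dilate_mask(mask, radius: float, voxel_size) -> np.ndarray:
    """Metric dilation: include every voxel whose center lies within
    ``radius`` mm of some mask-voxel center (anisotropy honored)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dist = scipy.ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return dist <= radius


def place_lesions(subject: SubjectGroundTruth, lesions: LesionModel, rng,
                  count: int | None = None) -> SubjectGroundTruth:
    """Insert spherical WM lesions and shift in-lesion parameters.

    Lesion support never leaves the original WM compartment; parameters in
    lesion voxels get the model's multiplicative shifts (myelin and MT
    saturation down; T1, long T2 and water content up).  The perilesional
    mask is the ``perilesion_radius`` metric dilation minus the lesion.
    """
    if subject.group != "patient":
        raise ValueError("lesions are placed on patients only")
    geom = subject.geometry
    labels = subject.labels.copy()
    params = {k: v.copy() for k, v in subject.params.items()}
    n = lesions.draw_count(rng) if count is None else count
    lesion_mask = np.zeros(labels.shape, dtype=bool)
    if n > 0:
        wm = labels == LABELS["wm"]
        wm_idx = np.array(np.nonzero(wm)).T
        if len(wm_idx) == 0:
            raise ConfigurationError("no WM voxels available for lesions")
        grids = geom.coordinate_grids()
        coords = np.stack(grids, axis=-1)
        placed = 0
        for _ in range(20 * n):
            if placed == n:
                break
            center = wm_idx[rng.integers(len(wm_idx))]
            if lesion_mask[tuple(center)]:
                continue  # keep lesion seeds distinct
            radius = float(np.exp(rng.normal(lesions.radius_log_mean,
                                             lesions.radius_log_sd)))
            c_mm = coords[tuple(center)]
            d2 = np.sum((coords - c_mm) ** 2, axis=-1)
            ball = (d2 <= radius ** 2) & wm
            ball[tuple(center)] = True  # sub-voxel lesions keep their seed
            lesion_mask |= ball
            placed += 1
        if placed < n:
            raise ConfigurationError(
                "could not place the requested lesion count inside WM")
        labels[lesion_mask] = LABELS["lesion"]
        params["w_short"][lesion_mask] *= lesions.mwf_scale
        params["t1"][lesion_mask] *= lesions.t1_scale
        params["t1_myelin"][lesion_mask] *= lesions.t1_scale
        params["mt_delta"][lesion_mask] *= lesions.mt_delta_scale
        params["t2_long"][lesion_mask] *= lesions.long_t2_scale
        params["proton_density"][lesion_mask] *= lesions.water_scale
        peri = dilate_mask(lesion_mask, lesions.perilesion_radius,
                           geom.voxel_size) & ~lesion_mask
    else:
        peri = np.zeros(labels.shape, dtype=bool)
    return replace(subject, labels=labels, params=params,
                   lesion_mask=lesion_mask, perilesion_mask=peri)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    n_controls: int = 38
    n_patients: int = 24
    seed: int = 0
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    tissues: dict = field(default_factory=default_tissues)
    lesions: LesionModel = field(default_factory=LesionModel)
    snr: dict = field(default_factory=lambda: {
        "grase": 100.0, "mcdespot": 150.0, "mt": 100.0})

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ConfigurationError(
                "need at least 2 controls for a defined SD")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")


def iter_cohort(config: CohortConfig):
    """Yield (subject, rng) ground truths; deterministic under the seed."""
    labels = build_label_volume(config.geometry)
    seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_controls + config.n_patients)
    i = 0
    for c in range(config.n_controls):
        rng = np.random.default_rng(seeds[i]); i += 1
        yield sample_subject(config.tissues, labels, "control", rng,
                             f"ctl{c + 1:03d}", config.geometry), rng
    for p in range(config.n_patients):
        rng = np.random.default_rng(seeds[i]); i += 1
        subj = sample_subject(config.tissues, labels, "patient", rng,
                              f"pat{p + 1:03d}", config.geometry)
        yield place_lesions(subj, config.lesions, rng), rng


def generate_cohort(config: CohortConfig, out_dir) -> dict:
    """Write per-subject ground-truth volumes, masks and a manifest.

    Returns the manifest dict.  Layout: ``<out>/<subject_id>/truth_*.nii``
    plus ``<out>/manifest.json``.
    """
    from . import volio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = config.geometry.affine
    manifest = {"seed": config.seed, "n_controls": config.n_controls,
                "n_patients": config.n_patients, "subjects": []}
    for subject, _ in iter_cohort(config):
        sdir = out / subject.subject_id
        sdir.mkdir(exist_ok=True)
        volio.write_volume(volio.VolumeRecord(
            subject.labels.astype(np.uint8), aff, units="label"),
            sdir / "truth_labels.nii")
        for name, vol in subject.params.items():
            volio.write_volume(volio.VolumeRecord(vol, aff, units="ms" if
                               "t1" in name or "t2" in name else "a.u."),
                               sdir / f"truth_{name}.nii")
        for name, m in (("lesion", subject.lesion_mask),
                        ("perilesion", subject.perilesion_mask)):
            volio.write_volume(volio.VolumeRecord(
                m.astype(np.uint8), aff, units="mask"),
                sdir / f"mask_{name}.nii")
        manifest["subjects"].append({
            "id": subject.subject_id, "group": subject.group,
            "n_lesion_voxels": int(subject.lesion_mask.sum())})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
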