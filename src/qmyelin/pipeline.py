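"""Pipeline driver: simulate -> fit -> zmap -> corrmap -> roi -> roc ->
compare, with on-disk artifacts, resumability and structured logging.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volio
from .cohort import (CohortConfig, LABELS, LesionModel, PhantomGeometry,
                     TissueParams, default_tissues, iter_cohort)
from .forward import simulate_acquisitions
from .lesion_roc import (DEFAULT_DIRECTIONS, average_roc_at_fixed_fpr,
                         compare_methods, roc_curve)
from .popstats import (cohort_mean_sd, group_difference, roi_summary,
                       tissue_histograms, voxelwise_spearman, zmap)
from .relaxometry import (RegConfig, SrcConfig, T2Grid, fit_subject,
                          _EpgBasisCache)
from .signals import GraseProtocol, McDespotProtocol, MtProtocol

__all__ = ["RunConfig", "run_pipeline", "load_config", "PIPELINE_STAGES",
           "PipelineError"]

PIPELINE_STAGES = ("simulate", "fit", "zmap", "corrmap", "roi", "roc",
                   "compare")
MODALITIES = ("mwf_g", "mwf_d", "qt1", "mtr")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grase: GraseProtocol = field(default_factory=GraseProtocol)
    mcdespot: McDespotProtocol = field(default_factory=McDespotProtocol)
    mt: MtProtocol = field(default_factory=MtProtocol)
    reg: RegConfig = field(default_factory=RegConfig)
    src: SrcConfig = field(default_factory=SrcConfig)
    t2_grid: T2Grid = field(default_factory=T2Grid)
    directions: dict = field(
        default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    out_dir: str = "qmyelin_out"
    stages: tuple = PIPELINE_STAGES
    persist_acquisitions: bool = True
    missing_mt: tuple = ()  # subject ids simulated/fitted without MT


def _build(cls, d, **extra):
    known = {f.name for f in dataclasses.fields(cls)}
    kw = {k: v for k, v in d.items() if k in known}
    kw.update(extra)
    return cls(**kw)


def load_config(path=None, overrides=None) -> RunConfig:
    """Build a RunConfig from a YAML file plus optional override dict."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})
    ch = dict(raw.get("cohort", {}))
    if "geometry" in ch:
        geo = dict(ch["geometry"])
        for key in ("grid_shape", "voxel_size"):
            if key in geo:
                geo[key] = tuple(geo[key])
        ch["geometry"] = _build(PhantomGeometry, geo)
    if "tissues" in ch:
        tissues = {}
        for name, td in ch["tissues"].items():
            td = dict(td)
            if "t2_components" in td:
                td["t2_components"] = tuple(
                    tuple(c) for c in td["t2_components"])
            tissues[name] = _build(TissueParams, td, name=name)
        base = default_tissues()
        base.update(tissues)
        ch["tissues"] = base
    if "lesions" in ch:
        ld = dict(ch["lesions"])
        if "count_range" in ld:
            ld["count_range"] = tuple(ld["count_range"])
        ch["lesions"] = _build(LesionModel, ld)
    cohort = _build(CohortConfig, ch)
    kw = {"cohort": cohort}
    for key, cls in (("grase", GraseProtocol), ("mcdespot", McDespotProtocol),
                     ("mt", MtProtocol), ("reg", RegConfig),
                     ("src", SrcConfig), ("t2_grid", T2Grid)):
        if key in raw:
            sub = dict(raw[key])
            if key == "src" and "bounds" in sub:
                sub["bounds"] = {k: tuple(v)
                                 for k, v in sub["bounds"].items()}
            kw[key] = _build(cls, sub)
    for key in ("directions", "out_dir", "persist_acquisitions"):
        if key in raw:
            kw[key] = raw[key]
    if "stages" in raw:
        kw["stages"] = tuple(raw["stages"])
    if "missing_mt" in raw:
        kw["missing_mt"] = tuple(raw["missing_mt"])
    return RunConfig(**kw)


# --------------------------------------------------------------------------
# artifact helpers
# --------------------------------------------------------------------------

def _log(out: Path, stage: str, **fields):
    rec = {"t": round(time.time(), 3), "stage": stage, **fields}
    with open(out / "log.jsonl", "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _write(data, affine, path, units="", dtype=np.float32):
    volio.write_volume(volio.VolumeRecord(
        np.asarray(data, dtype=dtype), affine, units=units), path)


def _read(path):
    return np.asarray(volio.read_volume(path).data, dtype=float)


def _subject_ids(out: Path):
    man = json.loads((out / "manifest.json").read_text())
    return man["subjects"]


def _require(path: Path, producer: str):
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' stage first")
    return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path):
    aff = cfg.cohort.geometry.affine
    manifest = {"seed": cfg.cohort.seed, "subjects": []}
    snr = cfg.cohort.snr
    for subject, rng in iter_cohort(cfg.cohort):
        sdir = out / "subjects" / subject.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        _write(subject.labels, aff, sdir / "truth_labels.nii", "label",
               np.uint8)
        _write(subject.lesion_mask, aff, sdir / "mask_lesion.nii", "mask",
               np.uint8)
        _write(subject.perilesion_mask, aff, sdir / "mask_perilesion.nii",
               "mask", np.uint8)
        for name, vol in subject.params.items():
            _write(vol, aff, sdir / f"truth_{name}.nii")
        modalities = ["grase", "mcdespot"]
        if subject.subject_id not in cfg.missing_mt:
            modalities.append("mt")
        acq = simulate_acquisitions(subject, cfg.grase, cfg.mcdespot, cfg.mt,
                                    snr=snr, rng=rng,
                                    modalities=tuple(modalities))
        if cfg.persist_acquisitions:
            for key, vol in acq.items():
                _write(vol, aff, sdir / f"acq_{key}.nii")
        manifest["subjects"].append(
            {"id": subject.subject_id, "group": subject.group,
             "has_mt": "mt" in acq,
             "n_lesion_voxels": int(subject.lesion_mask.sum())})
        _log(out, "simulate", subject=subject.subject_id,
             lesion_voxels=int(subject.lesion_mask.sum()))
        yield subject, acq
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _fit_one(cfg: RunConfig, out: Path, subject_id: str, index: int,
             acq: dict, labels, basis_cache):
    aff = cfg.cohort.geometry.affine
    brain = labels != LABELS["background"]
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.cohort.seed, 7919, index)))
    ms = fit_subject(acq, brain, {"grase": cfg.grase,
                                  "mcdespot": cfg.mcdespot},
                     grid=cfg.t2_grid, reg=cfg.reg, src=cfg.src, rng=rng,
                     affine=aff, basis_cache=basis_cache)
    mdir = out / "maps" / subject_id
    mdir.mkdir(parents=True, exist_ok=True)
    for name, vol in ms.maps.items():
        _write(vol, aff, mdir / f"{name}.nii")
        _write(ms.validity[name], aff, mdir / f"valid_{name}.nii", "mask",
               np.uint8)
    (mdir / "absent.json").write_text(json.dumps(sorted(ms.absent)))
    _log(out, "fit", subject=subject_id, absent=sorted(ms.absent))


def _stage_fit(cfg: RunConfig, out: Path, stream=None):
    basis_cache = _EpgBasisCache(cfg.grase, cfg.t2_grid, cfg.reg.epg_t1)
    if stream is not None:  # simulate ran in this invocation: reuse memory
        for index, (subject, acq) in enumerate(stream):
            _fit_one(cfg, out, subject.subject_id, index, acq,
                     subject.labels, basis_cache)
        return
    _require(out / "manifest.json", "simulate")
    for index, rec in enumerate(_subject_ids(out)):
        sid = rec["id"]
        sdir = out / "subjects" / sid
        labels = _read(_require(sdir / "truth_labels.nii", "simulate"))
        acq = {}
        for key in ("grase", "spgr", "irspgr", "bssfp", "mt"):
            path = sdir / f"acq_{key}.nii"
            if path.exists():
                acq[key] = _read(path)
        if not acq:
            raise PipelineError(
                f"no acquisitions for {sid}; rerun 'simulate' with "
                "persist_acquisitions enabled")
        _fit_one(cfg, out, sid, index, acq, labels, basis_cache)


def _load_maps(out: Path, which=MODALITIES):
    """{subject_id: {modality: volume}} plus group lookup."""
    recs = _subject_ids(_requiredir(out))
    maps = {}
    groups = {}
    for rec in recs:
        sid = rec["id"]
        mdir = out / "maps" / sid
        _require(mdir / "mwf_g.nii", "fit")
        absent = set(json.loads((mdir / "absent.json").read_text()))
        maps[sid] = {m: _read(mdir / f"{m}.nii") for m in which
                     if m not in absent and (mdir / f"{m}.nii").exists()}
        groups[sid] = rec["group"]
    return maps, groups


def _requiredir(out: Path) -> Path:
    _require(out / "manifest.json", "simulate")
    return out


def _stage_zmap(cfg: RunConfig, out: Path):
    aff = cfg.cohort.geometry.affine
    maps, groups = _load_maps(out)
    controls = [s for s, g in groups.items() if g == "control"]
    patients = [s for s, g in groups.items() if g == "patient"]
    (out / "stats").mkdir(exist_ok=True)
    for mod in MODALITIES:
        stack = [maps[s][mod] for s in controls if mod in maps[s]]
        if len(stack) < 2:
            continue
        st = cohort_mean_sd(stack, modality=mod)
        _write(st.mean, aff, out / "stats" / f"mean_{mod}.nii")
        _write(st.sd, aff, out / "stats" / f"sd_{mod}.nii")
        for sid in patients:
            if mod not in maps[sid]:
                continue
            zdir = out / "zmaps" / sid
            zdir.mkdir(parents=True, exist_ok=True)
            zm = zmap(maps[sid][mod], st, sid)
            _write(zm.z, aff, zdir / f"{mod}_z.nii")
    _log(out, "zmap", n_controls=len(controls), n_patients=len(patients))


def _stage_corrmap(cfg: RunConfig, out: Path):
    import itertools
    aff = cfg.cohort.geometry.affine
    maps, groups = _load_maps(out)
    controls = [s for s, g in groups.items() if g == "control"]
    labels = _read(out / "subjects" / controls[0] / "truth_labels.nii")
    (out / "corr").mkdir(exist_ok=True)
    hist_frames = []
    tissue_masks = {name: labels == LABELS[name]
                    for name in ("wm", "gm", "subcortical")}
    for a, b in itertools.combinations(MODALITIES, 2):
        subs = [s for s in controls if a in maps[s] and b in maps[s]]
        if len(subs) < 4:
            continue
        corr = voxelwise_spearman([maps[s][a] for s in subs],
                                  [maps[s][b] for s in subs])
        corr.pair = (a, b)
        _write(corr.rho, aff, out / "corr" / f"rho_{a}_{b}.nii")
        hf = tissue_histograms(corr, tissue_masks)
        hf.insert(0, "pair", f"{a}_{b}")
        hist_frames.append(hf)
    if hist_frames:
        pd.concat(hist_frames, ignore_index=True).to_csv(
            out / "corr" / "tissue_histograms.tsv", sep="\t", index=False)
    _log(out, "corrmap", n_controls=len(controls))


def _stage_roi(cfg: RunConfig, out: Path):
    maps, groups = _load_maps(out)
    frames = []
    for sid, mm in maps.items():
        sdir = out / "subjects" / sid
        labels = _read(sdir / "truth_labels.nii")
        lesion = _read(sdir / "mask_lesion.nii").astype(bool)
        peri = _read(sdir / "mask_perilesion.nii").astype(bool)
        rois = {"wm": (labels == LABELS["wm"]) | lesion,
                "gm": labels == LABELS["gm"],
                "subcortical": labels == LABELS["subcortical"],
                "csf": labels == LABELS["csf"]}
        frames.append(roi_summary(mm, rois, lesion, peri, groups[sid], sid))
    table = pd.concat(frames, ignore_index=True)
    (out / "tables").mkdir(exist_ok=True)
    table.to_csv(out / "tables" / "roi_summary.tsv", sep="\t", index=False)
    diffs = group_difference(table)
    diffs.to_csv(out / "tables" / "group_difference.tsv", sep="\t",
                 index=False)
    _log(out, "roi", n_rows=len(table))


def _stage_roc(cfg: RunConfig, out: Path):
    maps, groups = _load_maps(out)
    patients = [s for s, g in groups.items() if g == "patient"]
    (out / "roc").mkdir(exist_ok=True)
    rows = []
    curves = {m: [] for m in MODALITIES}
    for sid in patients:
        sdir = out / "subjects" / sid
        labels = _read(sdir / "truth_labels.nii")
        lesion = _read(sdir / "mask_lesion.nii").astype(bool)
        peri = _read(sdir / "mask_perilesion.nii").astype(bool)
        brain = labels != LABELS["background"]
        row = {"subject_id": sid}
        for mod in MODALITIES:
            zpath = out / "zmaps" / sid / f"{mod}_z.nii"
            if not zpath.exists():
                row[mod] = np.nan
                continue
            z = _read(zpath)
            analysis = brain & ~peri & np.isfinite(z)
            res = roc_curve(z, lesion & analysis, analysis,
                            cfg.directions.get(mod, "low_abnormal"),
                            subject_id=sid, modality=mod)
            row[mod] = res.auc
            if res.valid:
                curves[mod].append(res)
                pd.DataFrame({"threshold": res.thresholds, "fpr": res.fpr,
                              "tpr": res.tpr}).to_csv(
                    out / "roc" / f"{sid}_{mod}_roc.tsv", sep="\t",
                    index=False)
        rows.append(row)
    auc = pd.DataFrame(rows).set_index("subject_id")
    auc.to_csv(out / "roc" / "auc_table.tsv", sep="\t")
    grid = np.linspace(0, 1, 101)
    for mod, cs in curves.items():
        if cs:
            g, t = average_roc_at_fixed_fpr(cs, grid)
            pd.DataFrame({"fpr": g, "mean_tpr": t}).to_csv(
                out / "roc" / f"mean_roc_{mod}.tsv", sep="\t", index=False)
    _log(out, "roc", n_patients=len(patients))


def _stage_compare(cfg: RunConfig, out: Path):
    path = _require(out / "roc" / "auc_table.tsv", "roc")
    auc = pd.read_csv(path, sep="\t", index_col=0)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        cmp_res = compare_methods(auc)
    cmp_res.summary.to_csv(out / "roc" / "auc_summary.tsv", sep="\t",
                           index=False)
    cmp_res.pairwise.to_csv(out / "roc" / "pairwise_tests.tsv", sep="\t",
                            index=False)
    result = {"friedman_chi2": cmp_res.friedman_chi2,
              "friedman_df": cmp_res.friedman_df,
              "friedman_p": cmp_res.friedman_p,
              "excluded_subjects": list(cmp_res.excluded_subjects)}
    (out / "roc" / "comparison.json").write_text(
        json.dumps(result, indent=2, sort_keys=True))
    _log(out, "compare", **{k: v for k, v in result.items()
                            if k != "excluded_subjects"})
    return cmp_res


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; artifacts land under ``cfg.out_dir``.

    Stages must be contiguous in pipeline order; later stages resume from
    artifacts written by earlier invocations.
    """
    stages = tuple(cfg.stages)
    order = [PIPELINE_STAGES.index(s) for s in stages]
    if sorted(order) != order or any(b - a != 1 for a, b in
                                     zip(order, order[1:])):
        raise PipelineError(
            f"stages must be contiguous and in order {PIPELINE_STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(
        _config_dict(cfg), indent=2, sort_keys=True, default=str))

    if "simulate" in stages and "fit" in stages:
        _stage_fit(cfg, out, stream=_stage_simulate(cfg, out))
    else:
        if "simulate" in stages:
            for _ in _stage_simulate(cfg, out):
                pass
        if "fit" in stages:
            _stage_fit(cfg, out)
    for name, fn in (("zmap", _stage_zmap), ("corrmap", _stage_corrmap),
                     ("roi", _stage_roi), ("roc", _stage_roc),
                     ("compare", _stage_compare)):
        if name in stages:
            fn(cfg, out)
    return out


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj
    return enc(cfg)
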