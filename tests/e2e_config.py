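"""Configuration of the end-to-end directional-reproduction cohort:
38 controls + 24 patients on a 32^3 grid, lesion load well under 1% of WM,
default lesion effect signs (myelin/MT down, T1 up)."""

import numpy as np

from qmyelin.cohort import CohortConfig, LesionModel, PhantomGeometry
from qmyelin.pipeline import RunConfig
from qmyelin.relaxometry import RegConfig, SrcConfig, TIGHT_SRC_BOUNDS


def e2e_run_config(out_dir: str, seed: int = 20) -> RunConfig:
    geometry = PhantomGeometry(
        grid_shape=(32, 32, 32), voxel_size=(4.0, 4.0, 4.0),
        brain_radii=(28.0, 31.0, 25.0), wm_radii=(20.0, 23.0, 17.0),
        subcortical_radii=(4.5, 6.0, 4.5),
        subcortical_offsets=((-9.0, 0.0, 0.0), (9.0, 0.0, 0.0)),
        ventricle_radii=(3.0, 7.0, 4.0),
        ventricle_offsets=((-4.5, -2.0, 1.0), (4.5, -2.0, 1.0)))
    lesions = LesionModel(count_mean=3.5, count_dispersion=8.0,
                          count_range=(3, 9),
                          radius_log_mean=float(np.log(1.6)),
                          radius_log_sd=0.25)
    cohort = CohortConfig(n_controls=38, n_patients=24, seed=seed,
                          geometry=geometry, lesions=lesions,
                          snr={"grase": 250.0, "mcdespot": 200.0,
                               "mt": 150.0})
    return RunConfig(
        cohort=cohort,
        reg=RegConfig(mode="none"),
        src=SrcConfig(bounds=TIGHT_SRC_BOUNDS, n_samples=160, n_retain=20,
                      n_iterations=4, estimator="mean"),
        out_dir=out_dir,
        persist_acquisitions=False)
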