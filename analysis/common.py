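"""Shared study configuration for the numbered analysis scripts.

One synthetic study (seed 1) flows through every step: scripts regenerate the
inputs they need deterministically from this spec instead of passing large
image files around.  Tables land under results/, bulky intermediates under
scratch/.
"""

from pathlib import Path

from dbmcov import CohortSpec, default_truth

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 1
ANALYSIS_DPI = 90.0  # peri-symptom-onset timepoint for the covariance analysis
FWHM_MM = 0.085
K_LIST = (2, 4, 6, 8, 10)
N_SPLITS = 5
Q_LEVEL = 0.01


def study_spec() -> CohortSpec:
    return CohortSpec(
        n_per_cell=12,
        timepoints_dpi=(-7, 30, 90, 120),
        grid_shape=(20, 20, 20),
        voxel_size_mm=(0.1, 0.1, 0.1),
        seed=SEED,
    )


def study_truth(spec: CohortSpec):
    return default_truth(spec, k0=6)


def outdir(step: str) -> Path:
    d = RESULTS / step
    d.mkdir(parents=True, exist_ok=True)
    return d
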