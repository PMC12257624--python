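import numpy as np
import pytest
from hypothesis import settings

from aortaselect.imaging import scan_directory
from aortaselect.phantom import PhantomSpec, generate_cohort, generate_phantom, standard_cohort
from aortaselect.pipeline import PipelineConfig, run_pipeline
from aortaselect.segmentation import BackendConfig

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def good_phantom():
    """A default arterial-phase phantom: volume plus ground truth."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One study per category, written as NIfTI+sidecar; returns (dir, bundle)."""
    out = tmp_path_factory.mktemp("small_cohort")
    spec = standard_cohort(
        master_seed=5, n_good=2, n_paired=1, n_coronal=1, n_scout=1,
        n_nolungs=1, n_nobrachio=1, n_noncontrast=1, n_trunc_cranial=1,
        n_trunc_lateral=1, n_thick=1, n_thrombus_low=1, n_thrombus_high=1,
    )
    bundle = generate_cohort(spec, out, dialect="nifti_sidecar")
    return out, bundle


@pytest.fixture(scope="session")
def small_cohort_run(small_cohort):
    """The selection pipeline run once over the small mixed cohort."""
    out, bundle = small_cohort
    scan = scan_directory(out, dialect="nifti_sidecar")
    config = PipelineConfig(
        backend=BackendConfig(
            backend_id="oracle",
            oracle_masks={uid: gt.masks for uid, gt in bundle.items()},
        )
    )
    manifest, attrition = run_pipeline(scan, config)
    return scan, config, manifest, attrition


@pytest.fixture(scope="session")
def standard_cohort_dir(tmp_path_factory):
    """The full 72-study mixed cohort on disk (shared by the heavier tests)."""
    out = tmp_path_factory.mktemp("standard_cohort")
    spec = standard_cohort(master_seed=0)
    bundle = generate_cohort(spec, out, dialect="nifti_sidecar")
    return out, spec, bundle


def random_mask_and_volume(rng, max_side=12):
    """A random small HU volume with a random boolean mask (test helper)."""
    from aortaselect.geometry import ImageVolume, VolumeGeometry
    from aortaselect.segmentation import LabelMask

    size = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    geom = VolumeGeometry(
        origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0),
        direction=np.eye(3), size=size,
    )
    vox = rng.normal(100.0, 300.0, size=size)
    mask = rng.random(size) < 0.3
    return ImageVolume(geom, vox), LabelMask("aorta", geom, mask)
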