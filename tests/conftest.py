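import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import fibroscore as fs


@pytest.fixture(scope="session")
def small_image() -> fs.BiopsyImage:
    """A 512x512 render at 2 um/px, mid severity; holds many 100px patches."""
    return fs.render_biopsy(
        severity=0.5, microns_per_pixel=2.0, height_px=512, width_px=512,
        seed=42, biopsy_id="fixture-biopsy",
    )


@pytest.fixture(scope="session")
def small_cohort() -> list[fs.SyntheticSubject]:
    spec = fs.CohortSpec(n_subjects=6, visit_weeks=(0, 24, 52), seed=11)
    return fs.simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_backend() -> fs.TextureFeatureExtractor:
    return fs.texture_backend(n_features=64, seed=0)


def severity_qif_dataset(
    n_subjects: int,
    n_patches: int = 12,
    n_features: int = 256,
    image_px: int = 512,
    seed: int = 0,
):
    """Render one biopsy per subject across a severity sweep and extract QIFs.

    mRSS is the noiseless monotone link round(51*severity).  Returns
    (qifs, mrss_totals, subject_of, severities).
    """
    backend = fs.texture_backend(n_features=n_features, seed=seed)
    qifs, mrss, subject_of, severities = [], {}, {}, {}
    for i in range(n_subjects):
        sev = i / max(n_subjects - 1, 1)
        sid = f"S{i:03d}"
        bid = f"{sid}-w000"
        image = fs.render_biopsy(
            severity=sev, microns_per_pixel=2.0, height_px=image_px,
            width_px=image_px, seed=1000 + i, biopsy_id=bid,
        )
        pset = fs.sample_patches(image, n=n_patches, patch_area_mm2=0.04, seed=i)
        qifs.append(fs.extract_features(pset, backend))
        mrss[bid] = float(round(51 * sev))
        subject_of[bid] = sid
        severities[bid] = sev
    return qifs, mrss, subject_of, severities
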