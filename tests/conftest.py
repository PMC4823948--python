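import numpy as np
import pytest

import icd_profiler as icd


@pytest.fixture(scope="session")
def calr_field():
    """A standard CALR-GFP field with 50% responders, plus ground truth."""
    spec = icd.FieldSpec(n_cells=80, assay="CALR_GFP", responder_fraction=0.5, seed=3)
    return icd.generate_field(spec)


@pytest.fixture(scope="session")
def calr_segmented(calr_field):
    """Segmentation products (mask, rois, records) for the standard field."""
    img, truth = calr_field
    mask = icd.segment_nuclei(img.channels["hoechst"])
    mask, _ = icd.filter_debris(mask)
    rois = icd.build_cytoplasm_rois(mask)
    records, qc = icd.measure_field(img, rois, "CALR_GFP")
    return mask, rois, records, qc


@pytest.fixture(scope="session")
def tissue_default():
    """Default synthetic HE tissue (25% necrotic disc, 40 leukocytes)."""
    spec = icd.TissueSpec(seed=5)
    return icd.generate_he_tissue(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
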