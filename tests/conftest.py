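"""Shared fixtures: rendered fields with segmentations, and a reduced
synthetic cohort run through the whole profiling spine."""

from __future__ import annotations

import warnings

import pytest

from ecmorph.profiles import profile_cohort
from ecmorph.segmentation import detect_nuclei, propagate_cells
from ecmorph.synthetic import (
    LayoutConfig,
    default_latent_spec,
    default_phenotype,
    generate_feature_table,
    generate_study_layout,
    render_field,
)


@pytest.fixture(scope="session")
def hc_field():
    """One healthy-phenotype field at default SNR with its ground truth."""
    return render_field(default_phenotype("HC"), seed=11)


@pytest.fixture(scope="session")
def hc_segmented(hc_field):
    image, truth = hc_field
    nuclei = detect_nuclei(image)
    cells = propagate_cells(nuclei, image)
    return image, truth, nuclei, cells


@pytest.fixture(scope="session")
def small_cohort_table():
    """Reduced plasma-exposure cohort (6 samples/group) as a feature table."""
    layout = generate_study_layout(LayoutConfig(6, 6, 6), seed=5)
    spec = default_latent_spec(seed=0)
    table = generate_feature_table(spec, cells_per_well=60, layout=layout, seed=5)
    return table, spec


@pytest.fixture(scope="session")
def small_cohort_run(small_cohort_table):
    table, spec = small_cohort_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = profile_cohort(table, n_max=16)
    return result, spec
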