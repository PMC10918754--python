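"""Shared fixtures: small synthetic cohorts and helper constructors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import brainvar as bv

SMALL_SIZES = {"CEN": 10, "DMN": 14, "SN": 8, "LN": 8, "DA": 8,
               "unassigned": 12}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A fast cohort: 60 ROIs, 120 timepoints, 100 subjects."""
    return bv.CohortSpec(n_subjects=100, n_rois=60, network_sizes=SMALL_SIZES,
                         n_timepoints=120, seed=42)


@pytest.fixture
def tiny_timeseries(rng):
    """A 5-ROI, 40-timepoint random series."""
    data = rng.standard_normal((5, 40))
    return bv.RoiTimeSeries(subject_id="sub-x", data=data,
                            roi_labels=[f"r{i}" for i in range(5)], tr=1.4)


def variability_from_truth(spec, truth):
    """Adjusted-summary table on the generative-target pathway."""
    from brainvar.cohort import emulated_measured_variability

    return emulated_measured_variability(spec, truth)
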