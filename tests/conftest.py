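"""Shared fixtures: small synthetic cohorts and on-disk cohort layouts."""

from __future__ import annotations

import numpy as np
import pytest

from semspace.synthetic_data import default_spec, generate_cohort


def small_spec(language="en", seed=0, n_nc=15, n_pad=15, **group_knobs):
    """Scaled-down cohort spec for fast tests (same structure, fewer
    subjects, shorter transcripts)."""
    group = {"n": n_nc, "words_mean": 24.0, "words_sd": 6.0}
    nc = {**group, **{k[3:]: v for k, v in group_knobs.items() if k.startswith("nc_")}}
    pad = {
        **group,
        "n": n_pad,
        **{k[4:]: v for k, v in group_knobs.items() if k.startswith("pad_")},
    }
    return default_spec(language, seed=seed, nc=nc, pad=pad)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cohort_on_disk(tmp_path):
    """A tiny cohort written in the pipeline's input formats."""
    from semspace.synthetic_data import write_cohort

    cohort = generate_cohort(small_spec(seed=5, n_nc=6, n_pad=6))
    paths = write_cohort(cohort, tmp_path / "cohort")
    return cohort, paths
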