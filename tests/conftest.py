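"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from ecg2ppg import preprocess as pp
from ecg2ppg import signalsim as ss


@pytest.fixture(scope="session")
def af_record():
    """One clean 60-s AF record with ground-truth beat times in meta."""
    return ss.make_record(ss.RhythmSpec(rhythm="AF", mean_hr=90.0, seed=7),
                          ss.MorphologySpec(), 60.0)


@pytest.fixture(scope="session")
def sr_record():
    return ss.make_record(ss.RhythmSpec(rhythm="SR", mean_hr=70.0, seed=3),
                          ss.MorphologySpec(), 60.0)


@pytest.fixture(scope="session")
def small_cohort():
    """10 records, half AF, 60 s each."""
    return ss.make_cohort(10, 0.5, 60.0, seed=42)


@pytest.fixture(scope="session")
def paired_store(small_cohort):
    """Paired (ECG, PPG) 30-s segments from the AF half of the cohort."""
    stores = [pp.segment_annotated(r, "AF", 30.0, channels="both")
              for r in small_cohort if r.rhythm_label == "AF"]
    return pp.SegmentStore.concat(stores)


def make_ppg_pool(n_records: int, rhythm: str, seed: int, origin: str = "real",
                  morph: ss.MorphologySpec | None = None) -> pp.SegmentStore:
    """PPG-only pool of 15-s slices from 30-s parents (helper, not a fixture)."""
    recs = ss.make_cohort(n_records, 1.0 if rhythm == "AF" else 0.0, 30.0,
                          seed=seed, morph=morph)
    parents = pp.SegmentStore.concat(
        [pp.segment_annotated(r, rhythm, 30.0, channels="ppg", origin=origin)
         for r in recs])
    return pp.slice_segments(parents)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no cross-test state)."""
    return np.random.default_rng(12345)
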