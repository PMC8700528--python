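import numpy as np
import pytest

from cvmstage.landmark_io import LANDMARK_NAMES, AnnotationRecord, Landmark
from cvmstage.staging import CVMStage
from cvmstage.synthetic import SyntheticParams, generate_dataset, sample_case


def make_record(coords: dict[str, tuple[float, float]], image_id: str = "img",
                **kwargs) -> AnnotationRecord:
    rec = AnnotationRecord(image_id=image_id, **kwargs)
    for name, (x, y) in coords.items():
        rec.add(Landmark(name, x, y))
    return rec


@pytest.fixture
def full_record() -> AnnotationRecord:
    """A hand-laid stageable record: flat borders, square-ish bodies."""
    coords = {
        "R1": (10.0, 10.0), "R2": (10.0, 50.0),   # 40 px apart -> 0.25 mm/px
        "C2la": (20.0, 60.0), "C2m": (45.0, 60.0), "C2lp": (70.0, 60.0),
        "C3ua": (20.0, 80.0), "C3up": (60.0, 80.0),
        "C3la": (20.0, 120.0), "C3m": (40.0, 120.0), "C3lp": (60.0, 120.0),
        "C4ua": (20.0, 140.0), "C4up": (60.0, 140.0),
        "C4la": (20.0, 180.0), "C4m": (40.0, 180.0), "C4lp": (60.0, 180.0),
    }
    return make_record(coords)


@pytest.fixture(scope="session")
def clean_cases_per_stage():
    """One zero-jitter unrendered case per stage, deterministic."""
    rng = np.random.default_rng(42)
    return {s: sample_case(s, rng, render=False) for s in CVMStage}


@pytest.fixture(scope="session")
def small_rendered_dataset():
    """A small rendered dataset shared across detector tests."""
    cases, manifest = generate_dataset(
        {s: 4 for s in CVMStage}, seed=7, params=SyntheticParams()
    )
    return cases, manifest
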