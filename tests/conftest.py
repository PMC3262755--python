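import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rasprt.registry import ReportingPeriod, default_schema
from rasprt.simulate import GenerationSegment, SimulationScenario

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


class ConstantModel:
    """Stub risk model predicting the same probability for every case."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict(self, frame):
        return np.full(len(frame), self.p)


class ConstantModels:
    """Model lookup returning the same constant-probability model for every month."""

    def __init__(self, p: float):
        self.model = ConstantModel(p)

    def get(self, month):
        return self.model


@pytest.fixture
def constant_models():
    return ConstantModels


def single_year_scenario(
    n_hospitals: int = 14,
    cases_per_hospital: int = 600,
    mortality: float = 0.02,
    year: int = 2004,
    seed: int = 7734,
) -> SimulationScenario:
    """One calendar-year scenario with even hospital volumes."""
    hospitals = tuple(f"H{i:02d}" for i in range(1, n_hospitals + 1))
    period = ReportingPeriod(f"CY{year}", dt.date(year, 1, 1), dt.date(year, 12, 31))
    segment = GenerationSegment(
        f"CY{year}", period.start, period.end,
        n_hospitals * cases_per_hospital, hospitals, mortality,
    )
    return SimulationScenario(periods=(period,), segments=(segment,), seed=seed)


@pytest.fixture
def one_year_scenario():
    return single_year_scenario()


def stream_frame(outcomes, p=None, hospital="H01", start=dt.date(2004, 2, 1)):
    """A minimal case-stream DataFrame (one case per day) for SPRT unit tests."""
    n = len(outcomes)
    dates = pd.date_range(start, periods=n, freq="D")
    return pd.DataFrame(
        {
            "case_id": [f"C{i:04d}" for i in range(n)],
            "hospital_id": hospital,
            "procedure_date": dates,
            "outcome": list(outcomes),
        }
    )


@pytest.fixture
def schema():
    return default_schema()
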