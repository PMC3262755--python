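"""Shared scenario builders for the example scripts."""

import datetime as dt

from rasprt import ReportingPeriod
from rasprt.simulate import GenerationSegment, SimulationScenario


def small_two_year_scenario(n_hospitals: int = 6, cases_per_hospital_year: int = 400,
                            seed: int = 0) -> SimulationScenario:
    hospitals = tuple(f"H{i:02d}" for i in range(1, n_hospitals + 1))
    periods = (
        ReportingPeriod("CY2004", dt.date(2004, 1, 1), dt.date(2004, 12, 31)),
        ReportingPeriod("CY2005", dt.date(2005, 1, 1), dt.date(2005, 12, 31)),
    )
    volume = n_hospitals * cases_per_hospital_year
    segments = tuple(
        GenerationSegment(p.label, p.start, p.end, volume, hospitals, 0.02) for p in periods
    )
    return SimulationScenario(periods=periods, segments=segments, seed=seed)
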