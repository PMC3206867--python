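"""Packaged fixture curves and the default physiology model.

The knot tables shipped under ``ebcm/data`` are synthetic stand-ins shaped
like the real trends: body weight rising through age 20 (average of
male/female chart-style tables), beta cell density falling with age, and
pancreas volume rising — so that total beta cell mass rises quickly in
early childhood and then plateaus.  They are scaled so that, with the
default demand parameter alpha = 499 BCM-units/kg, EBCM falls from about
0.85 in infancy to 0.398 at age 20.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .curves import (
    AgeCurve,
    AgeKnots,
    average_growth_chart,
    bcm_total_curve,
    fit_cubic_spline,
)
from .physiology import PhysiologyModel

__all__ = ["load_knots", "fixture_knots", "fixture_curves", "default_model"]

#: alpha fitted to recent-onset autopsy records (BCM-units per kg)
DEFAULT_ALPHA = 499.0

_FIXTURES = (
    "weight_male",
    "weight_female",
    "beta_cell_density",
    "pancreas_volume",
)


def load_knots(path) -> AgeKnots:
    """Read an ``age_years,value`` CSV knot table."""
    df = pd.read_csv(path)
    missing = {"age_years", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"knot table {path} missing columns: {sorted(missing)}")
    return AgeKnots(df["age_years"].to_numpy(float), df["value"].to_numpy(float))


def fixture_knots(name: str) -> AgeKnots:
    """Load one packaged fixture table by name (e.g. ``"weight_male"``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    ref = resources.files("ebcm").joinpath(f"data/{name}.csv")
    with resources.as_file(ref) as path:
        return load_knots(path)


def fixture_curves() -> tuple[AgeCurve, AgeCurve]:
    """Build the (weight, total-BCM) curve pair from the packaged fixtures."""
    weight = fit_cubic_spline(
        average_growth_chart(fixture_knots("weight_male"), fixture_knots("weight_female"))
    )
    density = fit_cubic_spline(fixture_knots("beta_cell_density"))
    volume = fit_cubic_spline(fixture_knots("pancreas_volume"))
    return weight, bcm_total_curve(density, volume)


def default_model(alpha: float = DEFAULT_ALPHA, **kwargs) -> PhysiologyModel:
    """Default :class:`PhysiologyModel` on the packaged fixture curves."""
    weight, bcm = fixture_curves()
    return PhysiologyModel(alpha=alpha, weight_curve=weight, bcm_curve=bcm, **kwargs)
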