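"""Synthetic CMM-style dimensional metrology and comparison statistics.

Printed scaffolds are checked against the optimized design by measuring, on
a coordinate measuring machine, the strand spacing d_fil (center to center),
the strand diameter D, and the inter-layer overlap depth.  This module
generates synthetic measurement sets with a normal error model and computes
the comparison statistics used to judge a build: sample mean, sample SD
(n-1 denominator), percent deviation of the mean from nominal, SD as a
percent of nominal, and whether the nominal falls inside the
[mean - SD, mean + SD] band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSet",
    "ComparisonReport",
    "summarize",
    "overlap_fraction_estimate",
    "synthesize_measurements",
    "measurement_table",
]


@dataclass(frozen=True)
class MeasurementSet:
    """One measured quantity on one fabricated sample.

    ``quantity`` is one of ``d_fil``, ``D`` or ``overlap``; values in um.
    """

    nominal_um: float
    values_um: tuple[float, ...]
    sample_id: str = "sample-0"
    quantity: str = "d_fil"
    D_um: float | None = None    # strand diameter context (overlap sets)

    def __post_init__(self) -> None:
        if self.nominal_um <= 0:
            raise ValueError("nominal must be positive")
        if any(v <= 0 for v in self.values_um):
            raise ValueError("measurements must be positive")
        if self.quantity not in ("d_fil", "D", "overlap"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def n(self) -> int:
        return len(self.values_um)


@dataclass(frozen=True)
class ComparisonReport:
    """Summary statistics of a measurement set against its nominal."""

    mean_um: float
    sd_um: float
    percent_deviation: float     # |nominal - mean| / nominal * 100
    sd_percent: float            # sd / nominal * 100
    within_band: bool            # nominal in [mean - sd, mean + sd]
    n: int


def summarize(mset: MeasurementSet) -> ComparisonReport:
    """Mean, sample SD and percent deviations of a measurement set.

    Requires n >= 2 (the SD uses the n-1 denominator).
    """
    if mset.n < 2:
        raise ValueError("need at least 2 measurements for a sample SD")
    x = np.asarray(mset.values_um, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    dev = abs(mset.nominal_um - mean) / mset.nominal_um * 100.0
    return ComparisonReport(
        mean_um=mean,
        sd_um=sd,
        percent_deviation=dev,
        sd_percent=sd / mset.nominal_um * 100.0,
        within_band=(mean - sd) <= mset.nominal_um <= (mean + sd),
        n=mset.n,
    )


def overlap_fraction_estimate(
    sets: Sequence[MeasurementSet], D_um: float | None = None
) -> tuple[float, float]:
    """Pooled (mean, SD) of the overlap depth as a fraction of D.

    Each measurement is normalized by the strand diameter of its own set
    (``set.D_um``) before pooling, so sets printed with different diameters
    pool on a common dimensionless scale; a function-level ``D_um`` serves
    as fallback for sets that carry none.
    """
    if not sets:
        raise ValueError("no measurement sets")
    fractions = []
    for s in sets:
        if s.quantity != "overlap":
            raise ValueError("overlap_fraction_estimate expects overlap sets")
        D = s.D_um if s.D_um is not None else D_um
        if D is None or D <= 0:
            raise ValueError("strand diameter D_um required to normalize")
        fractions.extend(v / D for v in s.values_um)
    arr = np.asarray(fractions)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def synthesize_measurements(
    nominal_um: float,
    bias: float = 0.0,
    sd_um: float = 0.0,
    n: int = 10,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample-0",
    quantity: str = "d_fil",
) -> MeasurementSet:
    """Draw a synthetic CMM measurement set.

    Values are normal with mean ``nominal * (1 + bias)`` and standard
    deviation ``sd_um``; reproducible under ``seed`` (an int or a Generator
    for stream sharing).  Defaults to the n = 10 repeats of routine
    strand-dimension checks.
    """
    if sd_um < 0:
        raise ValueError("sd must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = rng.normal(nominal_um * (1.0 + bias), sd_um, size=n)
    vals = np.clip(vals, 1e-9, None)  # CMM lengths are positive
    return MeasurementSet(
        nominal_um=nominal_um,
        values_um=tuple(float(v) for v in vals),
        sample_id=sample_id,
        quantity=quantity,
    )


def measurement_table(sets: Sequence[MeasurementSet]) -> pd.DataFrame:
    """Long-format table (sample_id, quantity, nominal_um, value_um)."""
    rows = [
        {"sample_id": s.sample_id, "quantity": s.quantity,
         "nominal_um": s.nominal_um, "value_um": v}
        for s in sets
        for v in s.values_um
    ]
    return pd.DataFrame(rows)
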