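"""Analytics over cage time series and survival assays.

Covers the observables tracked in the cage study: drive-carrier and
drive-allele frequency trajectories from RFP larval screening, short-lag
autocovariance of the frequency fluctuations, suppression calling,
resistance-allele (R2) bookkeeping against a detection threshold, and
Kaplan–Meier survival with the geometric daily-survival bridge used to
calibrate the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cage_sim import ObservedCageSeries
from .genetics import PAIR_LABELS, PAIR_N_D, Allele

__all__ = [
    "FrequencySeries",
    "SurvivalData",
    "carrier_frequency_series",
    "allele_frequency_series",
    "fluctuation_autocovariance",
    "r2_fraction_among_nondrive",
    "km_survival",
    "calibrate_daily_survival",
]


@dataclass(frozen=True)
class FrequencySeries:
    """A fraction observed at successive collection days, with denominators."""

    days: np.ndarray
    values: np.ndarray
    denominators: np.ndarray
    estimated: bool = False  # True when inferred rather than counted

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        if (np.diff(days) <= 0).any():
            raise ValueError("days must be strictly increasing")
        vals = np.asarray(self.values, dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("frequencies outside [0, 1]")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "denominators", np.asarray(self.denominators))


@dataclass(frozen=True)
class SurvivalData:
    """Per-individual survival assay records.

    ``table`` columns: ``time`` (days, > 0), ``event`` (1 = death observed,
    0 = censored), plus optional ``genotype``, ``sex``, ``cage`` labels.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["time"] <= 0).any():
            raise ValueError("survival times must be positive")


def _sorted_records(series: ObservedCageSeries) -> pd.DataFrame:
    return series.records.sort_values("day")


def carrier_frequency_series(series: ObservedCageSeries) -> FrequencySeries:
    """RFP-positive fraction among screened larvae, per collection.

    Collections with zero screened larvae carry no information and are
    dropped; it is an error if every collection has a zero denominator.
    """
    df = _sorted_records(series)
    keep = df["larvae_screened"] > 0
    if not keep.any():
        raise ValueError("no collection screened any larvae")
    df = df[keep]
    return FrequencySeries(
        df["day"].to_numpy(),
        (df["rfp_positive"] / df["larvae_screened"]).to_numpy(),
        df["larvae_screened"].to_numpy(),
    )


def allele_frequency_series(series: ObservedCageSeries,
                            estimate_from_carriers: bool = False) -> FrequencySeries:
    """Drive-allele frequency per collection.

    Uses true genotype counts (``n_WW`` .. ``n_RR`` columns) when present.
    Otherwise, with ``estimate_from_carriers``, inverts the carrier fraction
    ``c`` under random mating — solving ``1 - (1 - q)**2 = c`` for the allele
    frequency ``q`` — and flags the series as estimated.
    """
    df = _sorted_records(series)
    cols = [f"n_{lab}" for lab in PAIR_LABELS]
    if all(c in df.columns for c in cols):
        counts = df[cols].to_numpy()
        total = counts.sum(axis=1)
        keep = total > 0
        if not keep.any():
            raise ValueError("no genotyped collections")
        n_d = counts[keep] @ PAIR_N_D
        return FrequencySeries(df["day"].to_numpy()[keep],
                               n_d / (2 * total[keep]), total[keep])
    if not estimate_from_carriers:
        raise ValueError("no genotype counts; pass estimate_from_carriers=True")
    carr = carrier_frequency_series(series)
    q = 1.0 - np.sqrt(1.0 - carr.values)
    return FrequencySeries(carr.days, q, carr.denominators, estimated=True)


def fluctuation_autocovariance(f: FrequencySeries,
                               max_lag_collections: int) -> dict[int, float]:
    """Sample autocovariance of the detrended series at lags 1..max_lag.

    Detrending is by first differencing, which removes the sigmoidal invasion
    trend that would otherwise dominate the covariance; at two collections a
    week a two-week time lag is lag 4.  The estimator subtracts the overall
    mean of the differenced series and divides by its length (the standard
    biased sample autocovariance).
    """
    x = np.diff(np.asarray(f.values, dtype=float))
    n = x.size
    if n < max_lag_collections + 4:
        raise ValueError("series too short for the requested maximum lag")
    xc = x - x.mean()
    return {lag: float(xc[:-lag] @ xc[lag:]) / n
            for lag in range(1, max_lag_collections + 1)}


def r2_fraction_among_nondrive(
    allele_counts: Mapping[Union[str, Allele], float],
    detection_threshold: float = 0.0025,
) -> tuple[float, bool]:
    """R2 alleles as a fraction of all non-drive alleles, with detection flag.

    The threshold (default 0.25%, the amplicon-sequencing error floor used to
    call putative resistant alleles) marks fractions worth reporting.  At
    drive fixation there are no non-drive alleles and the fraction is
    undefined.
    """
    lookup = {"W": Allele.W, "D": Allele.D, "R": Allele.R2, "R2": Allele.R2}
    tall = {Allele.W: 0.0, Allele.D: 0.0, Allele.R2: 0.0}
    for k, v in allele_counts.items():
        if v < 0:
            raise ValueError("negative allele count")
        tall[lookup[k] if isinstance(k, str) else Allele(k)] += v
    nondrive = tall[Allele.W] + tall[Allele.R2]
    if nondrive == 0:
        raise ValueError("no non-drive alleles (drive fixation): "
                         "fraction undefined")
    frac = float(tall[Allele.R2] / nondrive)
    return frac, bool(frac >= detection_threshold)


def km_survival(data: SurvivalData) -> tuple[pd.Series, float]:
    """Kaplan–Meier survivorship and median survival time.

    Returns the product-limit estimate S(t) indexed by event/censoring times
    and the median (smallest time with S(t) <= 0.5; ``inf`` when the curve
    never reaches a half).  With no censoring the estimate equals the
    empirical survival function.
    """
    if not (data.table["event"] == 1).any():
        raise ValueError("no observed deaths; survival curve undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(data.table["time"], event_observed=data.table["event"])
    curve = kmf.survival_function_["KM_estimate"]
    return curve, float(kmf.median_survival_time_)


def calibrate_daily_survival(median_days: float) -> float:
    """Constant daily survival whose geometric lifetime has the given median.

    The simple bridge from an observed median adult lifespan to the
    simulator's geometric survival mode: s = 0.5 ** (1 / median).
    """
    if median_days < 1:
        raise ValueError("median lifespan must be >= 1 day")
    return 0.5 ** (1.0 / median_days)
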