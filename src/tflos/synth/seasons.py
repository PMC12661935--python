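"""Seeded synthetic flowering seasons.

A season is modeled as three lagged unimodal (Gaussian-shaped) count
curves: buds lead the blooming curve by ``bud_lead`` days, withered flowers
follow it by ``wither_lag`` days, and amplitudes follow the 57/25/18 class
prevalence (bud 2.28x, withered 0.72x the blooming peak).  Daily counts are
negative-binomially dispersed around the curve (variance mu + d*mu^2 for
dispersion d); ``noise_dispersion=0`` is exactly noiseless
(counts = round(mu)), which the exact tests rely on.

Stage labels come from the cumulative noiseless blooming curve: a day is
IFS until cumulative bloom reaches 10% of the season total, EFS to 40%,
MFS to 60%, LFS to 90% and TFS after.  Because the cumulative curve is
non-decreasing, stages form contiguous, non-regressing blocks in time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from ..records import STAGES, CountRecord

#: cumulative-bloom fractions at which the stage advances
STAGE_BOUNDARIES = (0.10, 0.40, 0.60, 0.90)

#: amplitude of the bud / withered curve relative to the blooming peak
BUD_AMPLITUDE_RATIO = 0.57 / 0.25
WITHER_AMPLITUDE_RATIO = 0.18 / 0.25


@dataclass(frozen=True)
class SeasonSpec:
    """Parameters of one accession-season."""
    accession_id: str = "ACC1"
    season_start: dt.date = dt.date(2023, 10, 1)
    season_length: int = 70
    peak_day: int = 35
    peak_amplitude: float = 40.0
    bud_lead: int = 10
    wither_lag: int = 10
    noise_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.season_length <= 0 or self.peak_amplitude <= 0:
            raise ValueError("season_length and peak_amplitude must be positive")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")


def _curve(day, peak_day, amplitude, sigma):
    return amplitude * np.exp(-0.5 * ((day - peak_day) / sigma) ** 2)


def expected_counts(spec: SeasonSpec, day: float) -> tuple:
    """Noiseless (bud, blooming, withered) curve values at a day offset."""
    sigma = spec.season_length / 6.0
    bloom = _curve(day, spec.peak_day, spec.peak_amplitude, sigma)
    bud = _curve(day, spec.peak_day - spec.bud_lead,
                 spec.peak_amplitude * BUD_AMPLITUDE_RATIO, sigma)
    wither = _curve(day, spec.peak_day + spec.wither_lag,
                    spec.peak_amplitude * WITHER_AMPLITUDE_RATIO, sigma)
    return bud, bloom, wither


def stage_of_day(spec: SeasonSpec, day: float) -> str:
    """Stage label from the cumulative noiseless blooming curve."""
    days = np.arange(spec.season_length + 1, dtype=np.float64)
    bloom = _curve(days, spec.peak_day, spec.peak_amplitude,
                   spec.season_length / 6.0)
    cum = np.cumsum(bloom)
    total = cum[-1]
    frac = cum[min(max(int(np.floor(day)), 0), spec.season_length)] / total
    for stage, bound in zip(STAGES, STAGE_BOUNDARIES):
        if frac < bound:
            return stage
    return STAGES[-1]


def _draw_count(rng, mu, dispersion) -> int:
    if mu <= 0:
        return 0
    if dispersion == 0:
        return int(round(mu))
    r = 1.0 / dispersion                      # NB size: var = mu + d*mu^2
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def generate_season(spec: SeasonSpec, sampling_dates) -> list:
    """Draw one CountRecord per sampling date (repeat a date for replicates).

    Dates must fall inside ``[season_start, season_start + season_length]``.
    An empty date list yields an empty series.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    records = []
    for i, date in enumerate(sampling_dates):
        day = (date - spec.season_start).days
        if not 0 <= day <= spec.season_length:
            raise ValueError(f"{date} outside the season window of "
                             f"{spec.accession_id}")
        mu_bud, mu_bloom, mu_wither = expected_counts(spec, day)
        records.append(CountRecord(
            image_id=f"{spec.accession_id}_{date.isoformat()}_{i}",
            n_bud=_draw_count(rng, mu_bud, spec.noise_dispersion),
            n_bloom=_draw_count(rng, mu_bloom, spec.noise_dispersion),
            n_wither=_draw_count(rng, mu_wither, spec.noise_dispersion),
            date=date.isoformat(),
            accession=spec.accession_id,
            stage=stage_of_day(spec, day),
        ))
    return records


def sampling_schedule(spec: SeasonSpec, every: int = 2, replicates: int = 3) -> list:
    """Regular sampling dates across the season, each repeated `replicates` times."""
    dates = []
    for off in range(0, spec.season_length + 1, every):
        d = spec.season_start + dt.timedelta(days=off)
        dates.extend([d] * replicates)
    return dates
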