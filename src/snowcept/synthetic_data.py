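"""Synthetic snowfall campaigns, trough networks and observations.

The generators emulate the statistical regime of a two-winter snow-trough
campaign in a boreal mixed-conifer stand: 17 storms whose water equivalent
has mean 10.3 mm with coefficient of variation 1.01, storm intensity with
mean 4.41 mm/day and CV 1.14, fresh-snow density near 81 kg/m3, storm-day
air temperature between about -30 and -1 degC, and a 28-trough network with
canopy density 0.25-0.72 and winter effective LAI 0.6-4.4.

Storm SWE and intensity are drawn from lognormals because both are positive
and heavily right-skewed at CV ~ 1; the lognormal is moment-matched:

    sigma2 = ln(1 + cv**2),   mu = ln(mean) - sigma2 / 2

so the generated sample mean and CV converge to the configured values.
Observations are generated forward through the exponential interception
model plus truncated Gaussian noise, keeping the water balance physical
(0 <= i <= p_c), which makes known-truth parameter-recovery tests possible.

One master seed fans out to independent substreams (events / stand / noise)
via ``numpy.random.SeedSequence.spawn``, so each stage regenerates
identically on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .interception_model import InterceptionParams, intercept
from .observations import EventTroughObservation, SnowfallEvent, TroughPoint

__all__ = [
    "EventGeneratorConfig",
    "StandGeneratorConfig",
    "lognormal_params",
    "generate_events",
    "generate_stand",
    "generate_observations",
    "generate_campaign",
]


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with given mean and CV."""
    if mean <= 0:
        raise InputError("mean must be positive")
    if cv <= 0:
        raise InputError("coefficient of variation must be positive")
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class EventGeneratorConfig:
    """Snowfall-event generator settings (defaults: the observed regime)."""

    n_events: int = 17
    mean_swe: float = 10.3
    cv_swe: float = 1.01
    mean_intensity: float = 4.41
    cv_intensity: float = 1.14
    density_mean: float = 81.0
    density_sd: float = 10.0
    temp_range: tuple[float, float] = (-30.1, -0.6)
    min_duration_days: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise InputError("n_events must be >= 0")
        for name in ("mean_swe", "cv_swe", "mean_intensity", "cv_intensity"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.density_mean <= 20:
            raise InputError("density_mean must exceed the 20 kg/m3 floor")
        if self.temp_range[0] > self.temp_range[1]:
            raise InputError("temp_range must be (low, high)")


@dataclass(frozen=True)
class StandGeneratorConfig:
    """Trough-network generator settings (defaults: observed stand ranges)."""

    n_troughs: int = 28
    canopy_density_range: tuple[float, float] = (0.25, 0.72)
    lai_range: tuple[float, float] = (0.6, 4.4)
    density_lai_correlation: float = 0.5
    dbh_range: tuple[float, float] = (8.0, 70.0)
    tree_height_range: tuple[float, float] = (6.0, 34.0)
    canopy_height_frac: tuple[float, float] = (0.5, 0.85)
    canopy_width_range: tuple[float, float] = (2.5, 12.0)
    slope_range: tuple[float, float] = (0.0, 56.0)
    max_stems: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_troughs < 0:
            raise InputError("n_troughs must be >= 0")
        lo, hi = self.canopy_density_range
        if not (0.2 <= lo < hi <= 0.8):
            raise InputError("canopy density range must lie within [0.2, 0.8]")
        if self.lai_range[0] < 0 or self.lai_range[0] >= self.lai_range[1]:
            raise InputError("invalid LAI range")
        if not -1 < self.density_lai_correlation < 1:
            raise InputError("density-LAI correlation must be in (-1, 1)")


def _winter_dates(n: int, rng: np.random.Generator) -> list[str]:
    # spread storms over two Nov-Apr winters, ordered within the campaign
    starts = np.sort(rng.integers(0, 2 * 151, size=n))
    out = []
    base_years = (2013, 2014)
    for day in starts:
        winter, offset = divmod(int(day), 151)
        month_days = [(11, 30), (12, 31), (1, 31), (2, 28), (3, 31)]
        y = base_years[winter]
        for month, ndays in month_days:
            if offset < ndays:
                if month < 11:
                    y += 1
                out.append(f"{y:04d}-{month:02d}-{offset + 1:02d}")
                break
            offset -= ndays
    return out


def generate_events(cfg: EventGeneratorConfig) -> list[SnowfallEvent]:
    """Draw a synthetic storm series; identical seed, identical list.

    SWE and intensity are independent moment-matched lognormals; intensity
    is resampled (truncated) until the implied duration swe/intensity is at
    least ``min_duration_days``.  Fresh-snow density is Gaussian truncated
    above 20 kg/m3; storm-day temperature is uniform over ``temp_range``.
    """
    if cfg.n_events == 0:
        return []
    rng = np.random.default_rng(cfg.seed)
    mu_s, sd_s = lognormal_params(cfg.mean_swe, cfg.cv_swe)
    mu_i, sd_i = lognormal_params(cfg.mean_intensity, cfg.cv_intensity)

    swe = rng.lognormal(mu_s, sd_s, size=cfg.n_events)
    intensity = np.empty(cfg.n_events)
    for j in range(cfg.n_events):
        cap = swe[j] / cfg.min_duration_days
        val = rng.lognormal(mu_i, sd_i)
        while val > cap:
            val = rng.lognormal(mu_i, sd_i)
        intensity[j] = val
    density = rng.normal(cfg.density_mean, cfg.density_sd, size=cfg.n_events)
    while np.any(density <= 20.0):
        bad = density <= 20.0
        density[bad] = rng.normal(cfg.density_mean, cfg.density_sd, size=int(bad.sum()))
    temp = rng.uniform(cfg.temp_range[0], cfg.temp_range[1], size=cfg.n_events)
    dates = _winter_dates(cfg.n_events, rng)

    # store the intensity implied by the rounded duration so that a CSV
    # round trip (which re-derives intensity from swe and duration) is exact
    duration = swe / intensity
    return [
        SnowfallEvent(
            event_id=f"E{j + 1:02d}",
            date=dates[j],
            swe=float(swe[j]),
            duration=float(duration[j]),
            intensity=float(swe[j] / duration[j]),
            fresh_snow_density=float(density[j]),
            air_temp=float(temp[j]),
        )
        for j in range(cfg.n_events)
    ]


def generate_stand(cfg: StandGeneratorConfig) -> list[TroughPoint]:
    """Draw a synthetic trough network.

    Canopy density and LAI share a latent Gaussian factor whose loading is
    ``density_lai_correlation``; both are then mapped through their uniform
    ranges by the probability integral transform, so marginals stay within
    the configured bounds while the rank correlation tracks the knob.
    Remaining attributes are independent uniforms over observed ranges;
    canopy height is a fraction of tree height.
    """
    from scipy.stats import norm

    if cfg.n_troughs == 0:
        return []
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.density_lai_correlation
    # loading sqrt(|rho|) on the shared factor gives corr(z_cc, z_lai) = rho;
    # the sign flips the LAI loading for negative correlations
    load = np.sqrt(abs(rho))
    resid = np.sqrt(1 - abs(rho))
    z_shared = rng.standard_normal(cfg.n_troughs)
    z_cc = load * z_shared + resid * rng.standard_normal(cfg.n_troughs)
    z_lai = np.sign(rho) * load * z_shared + resid * rng.standard_normal(cfg.n_troughs)
    u_cc = norm.cdf(z_cc)
    u_lai = norm.cdf(z_lai)

    def _unif(u, lo, hi):
        return lo + (hi - lo) * u

    cc = _unif(u_cc, *cfg.canopy_density_range)
    lai = _unif(u_lai, *cfg.lai_range)
    dbh = rng.uniform(*cfg.dbh_range, size=cfg.n_troughs)
    th = rng.uniform(*cfg.tree_height_range, size=cfg.n_troughs)
    ch = th * rng.uniform(*cfg.canopy_height_frac, size=cfg.n_troughs)
    cw = rng.uniform(*cfg.canopy_width_range, size=cfg.n_troughs)
    slope = rng.uniform(*cfg.slope_range, size=cfg.n_troughs)
    stems = rng.integers(1, cfg.max_stems + 1, size=cfg.n_troughs)
    ba = np.pi * (dbh / 2.0) ** 2 / 25.0 * rng.uniform(0.5, 1.5, size=cfg.n_troughs)

    return [
        TroughPoint(
            trough_id=f"T{j + 1:02d}",
            canopy_density=float(cc[j]),
            lai=float(lai[j]),
            dbh=float(dbh[j]),
            basal_area=float(ba[j]),
            canopy_height=float(ch[j]),
            canopy_width=float(cw[j]),
            tree_height=float(th[j]),
            slope=float(slope[j]),
            n_conifer_stems=int(stems[j]),
        )
        for j in range(cfg.n_troughs)
    ]


def generate_observations(
    events: Sequence[SnowfallEvent],
    troughs: Sequence[TroughPoint],
    params: InterceptionParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[EventTroughObservation]:
    """Forward-model observations for every (event, trough) pair.

    Interception is the model prediction plus Gaussian noise truncated to
    [0, p_c] (resampling), so throughfall T = p_c - i stays non-negative and
    the water balance holds record by record.  ``noise_sd = 0`` puts every
    observation exactly on the model surface.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for e in events:
        for t in troughs:
            i_true = intercept(params, t.lai, t.canopy_density, e.swe)
            i_obs = i_true
            if noise_sd > 0 and e.swe > 0:
                i_obs = i_true + rng.normal(0.0, noise_sd)
                while not 0.0 <= i_obs <= e.swe:
                    i_obs = i_true + rng.normal(0.0, noise_sd)
            out.append(
                EventTroughObservation(
                    event_id=e.event_id,
                    trough_id=t.trough_id,
                    throughfall=float(e.swe - i_obs),
                    interception=float(i_obs),
                    negative_interception=False,
                )
            )
    return out


@dataclass(frozen=True)
class SyntheticCampaign:
    events: list[SnowfallEvent]
    troughs: list[TroughPoint]
    observations: list[EventTroughObservation]
    seeds: dict = field(default_factory=dict)


def generate_campaign(
    master_seed: int = 0,
    event_cfg: Optional[EventGeneratorConfig] = None,
    stand_cfg: Optional[StandGeneratorConfig] = None,
    params: Optional[InterceptionParams] = None,
    noise_sd: float = 0.1,
) -> SyntheticCampaign:
    """Full campaign from one master seed.

    The master seed spawns independent substreams for events, stand and
    observation noise; configs passed in have their seeds overridden by the
    spawned ones so the three stages never share a stream.
    """
    import dataclasses

    ss = np.random.SeedSequence(master_seed)
    s_events, s_stand, s_noise = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    event_cfg = dataclasses.replace(event_cfg or EventGeneratorConfig(), seed=s_events)
    stand_cfg = dataclasses.replace(stand_cfg or StandGeneratorConfig(), seed=s_stand)
    params = params or InterceptionParams.revised()
    events = generate_events(event_cfg)
    troughs = generate_stand(stand_cfg)
    obs = generate_observations(events, troughs, params, noise_sd=noise_sd, seed=s_noise)
    return SyntheticCampaign(
        events=events,
        troughs=troughs,
        observations=obs,
        seeds={"master": master_seed, "events": s_events, "stand": s_stand, "noise": s_noise},
    )
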