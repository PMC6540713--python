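"""Field observations and the water balance of canopy snow interception.

A snow-trough campaign measures, for each storm, the snowfall water
equivalent (SWE) at open reference troughs and the through-canopy snowfall
(throughfall) at troughs beneath the stand.  Interception is the water-balance
residual ``i = P_c - T`` for the event snowfall ``P_c`` and throughfall ``T``;
sublimation and evaporation of the intercepted load are deliberately ignored,
so the residual can occasionally be negative when unloading delivers more
snow beneath the canopy than fell in the open.

This module holds the domain records (trough measurements, snowfall events,
stand attributes at each trough, per-event per-trough observations) and the
arithmetic that turns raw measurements into SWE, interception, efficiency,
stand-level means and campaign totals, plus the magnitude/intensity
classification used to stratify events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Optional, Sequence

from .errors import InputError

__all__ = [
    "TroughMeasurement",
    "SnowfallEvent",
    "TroughPoint",
    "EventTroughObservation",
    "StandEventSummary",
    "CampaignSummary",
    "MAGNITUDE_CLASSES",
    "INTENSITY_CLASSES",
    "compute_swe",
    "compute_interception",
    "interception_efficiency",
    "throughfall_ratio",
    "classify_magnitude",
    "classify_intensity",
    "aggregate_stand",
    "campaign_summary",
]

#: Snowfall-magnitude class labels, ordered small to large.  Bins are
#: [0, 10) mm, [10, 20] mm and (20, inf) mm of event SWE.
MAGNITUDE_CLASSES = ("<10", "10–20", ">20")

#: Intensity class labels; the split is at 5.0 mm/day.
INTENSITY_CLASSES = ("low", "high")

INTENSITY_THRESHOLD_MM_PER_DAY = 5.0


@dataclass(frozen=True)
class TroughMeasurement:
    """Raw depth/density readings from one snow trough after one storm.

    Depths are steel-ruler readings in mm (four per trough at 0.2-m
    intervals in the field protocol); ``core_densities`` are fresh-snow
    densities from weighed snow cores in g/cm3 (three cores in the
    protocol); ``water_density`` is in g/cm3 and is 1.0 for liquid water.
    """

    trough_id: str
    depths: Sequence[float]
    core_densities: Sequence[float]
    water_density: float = 1.0

    def __post_init__(self) -> None:
        if len(self.depths) == 0:
            raise InputError(f"trough {self.trough_id}: no depth readings")
        if len(self.core_densities) == 0:
            raise InputError(f"trough {self.trough_id}: no density cores")
        if any(d < 0 for d in self.depths):
            raise InputError(f"trough {self.trough_id}: negative snow depth")
        if any(not 0 < rho <= 1 for rho in self.core_densities):
            raise InputError(
                f"trough {self.trough_id}: core density outside (0, 1] g/cm3"
            )
        if self.water_density <= 0:
            raise InputError("water density must be positive")


@dataclass(frozen=True)
class SnowfallEvent:
    """One storm: open-site SWE, duration and derived intensity.

    ``swe`` is the open-site snowfall water equivalent P_c in mm;
    ``intensity`` must equal ``swe / duration`` (mm/day) within rounding.
    ``fresh_snow_density`` is in kg/m3.
    """

    event_id: str
    swe: float
    duration: float
    intensity: float
    fresh_snow_density: float
    date: Optional[str] = None
    air_temp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.swe < 0:
            raise InputError(f"event {self.event_id}: negative SWE")
        if self.duration <= 0:
            raise InputError(f"event {self.event_id}: non-positive duration")
        if self.fresh_snow_density <= 0:
            raise InputError(f"event {self.event_id}: non-positive snow density")
        implied = self.swe / self.duration
        # allow the rounding slack of values printed to 2 decimals
        if abs(self.intensity - implied) > max(0.02, 0.01 * implied):
            raise InputError(
                f"event {self.event_id}: intensity {self.intensity} inconsistent "
                f"with swe/duration = {implied:.3f}"
            )


@dataclass(frozen=True)
class TroughPoint:
    """Stand structure around one beneath-canopy trough (5-m radius means).

    ``canopy_density`` is stored as a fraction in [0, 1] (field tables print
    percent; loaders convert).  ``slope`` is kept as the printed covariate
    without a unit commitment.  ``suspect_dimension_swap`` marks rows where
    canopy width exceeds tree height, the signature of a width/height column
    swap in the printed source table; values are kept as printed.
    """

    trough_id: str
    canopy_density: float
    lai: float
    dbh: float
    basal_area: float
    canopy_height: float
    canopy_width: float
    tree_height: float
    slope: float
    n_conifer_stems: int
    avg_throughfall: Optional[float] = None
    avg_interception: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.canopy_density <= 1:
            raise InputError(
                f"trough {self.trough_id}: canopy density {self.canopy_density} "
                "not a fraction in [0, 1] (percent input? divide by 100)"
            )
        if self.lai < 0:
            raise InputError(f"trough {self.trough_id}: negative LAI")
        if self.n_conifer_stems < 0 or self.n_conifer_stems != int(self.n_conifer_stems):
            raise InputError(f"trough {self.trough_id}: stem count must be a non-negative integer")

    @property
    def canopy_density_pct(self) -> float:
        return 100.0 * self.canopy_density

    @property
    def suspect_dimension_swap(self) -> bool:
        return self.canopy_width > self.tree_height


@dataclass(frozen=True)
class EventTroughObservation:
    """Throughfall and derived interception for one event at one trough."""

    event_id: str
    trough_id: str
    throughfall: float
    interception: float
    negative_interception: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.throughfall < 0:
            raise InputError(
                f"event {self.event_id} trough {self.trough_id}: negative throughfall"
            )


@dataclass(frozen=True)
class StandEventSummary:
    """Stand-scale means for one event across contributing troughs."""

    event_id: str
    mean_throughfall: float
    mean_interception: float
    efficiency_pct: Optional[float]
    n_troughs: int


@dataclass(frozen=True)
class CampaignSummary:
    """Cumulative water balance of a whole observation campaign."""

    n_events: int
    total_snowfall: float
    total_throughfall: float
    total_interception: float
    throughfall_share_pct: Optional[float]
    interception_share_pct: Optional[float]
    max_interception: Optional[float] = None
    max_interception_event: Optional[str] = None
    min_interception: Optional[float] = None
    min_interception_event: Optional[str] = None


def compute_swe(m: TroughMeasurement) -> float:
    """Snow water equivalent (mm) of one trough measurement.

    SWE = mean depth x mean fresh-snow density / water density, i.e. the
    depth of liquid water the sampled snow layer would melt to.  Depths in
    mm and densities in g/cm3 give SWE directly in mm.
    """
    mean_depth = fmean(m.depths)
    mean_density = fmean(m.core_densities)
    return mean_depth * mean_density / m.water_density


def compute_interception(event_swe: float, throughfall: float) -> float:
    """Water-balance interception i = P_c - T (mm).

    Negative results are returned as-is: throughfall can exceed open-site
    snowfall when canopy unloading adds previously intercepted snow, and
    the balance ignores sublimation.  Callers that need the quality flag
    should build an :class:`EventTroughObservation` via :func:`observe`.
    """
    if event_swe < 0:
        raise InputError("event SWE must be >= 0")
    if throughfall < 0:
        raise InputError("throughfall must be >= 0")
    return event_swe - throughfall


def observe(event: SnowfallEvent, trough_id: str, throughfall: float) -> EventTroughObservation:
    """Build a flagged observation from an event and a throughfall reading."""
    i = compute_interception(event.swe, throughfall)
    return EventTroughObservation(
        event_id=event.event_id,
        trough_id=trough_id,
        throughfall=throughfall,
        interception=i,
        negative_interception=i < 0,
    )


def interception_efficiency(interception: float, event_swe: float) -> float:
    """Interception as a percentage of event snowfall."""
    if event_swe <= 0:
        raise InputError("interception efficiency undefined for zero snowfall")
    return 100.0 * interception / event_swe


def throughfall_ratio(throughfall: float, event_swe: float) -> float:
    """Throughfall as a percentage of event snowfall.

    Complements :func:`interception_efficiency`: the two sum to 100% exactly
    whenever interception is the water-balance residual.
    """
    if event_swe <= 0:
        raise InputError("throughfall ratio undefined for zero snowfall")
    return 100.0 * throughfall / event_swe


def classify_magnitude(event_swe: float) -> str:
    """Magnitude class of an event: "<10", "10-20" or ">20" mm.

    Left-closed bins: [0, 10), [10, 20], (20, inf).
    """
    if event_swe < 0:
        raise InputError("event SWE must be >= 0")
    if event_swe < 10.0:
        return MAGNITUDE_CLASSES[0]
    if event_swe <= 20.0:
        return MAGNITUDE_CLASSES[1]
    return MAGNITUDE_CLASSES[2]


def classify_intensity(intensity: float) -> str:
    """Intensity class of an event, split at 5.0 mm/day.

    The field convention reports frequencies below 4.9 and above 5 mm/day;
    the unassigned sliver (4.9, 5.0) is closed at 5.0, with [0, 5) low.
    """
    if intensity < 0:
        raise InputError("intensity must be >= 0")
    if intensity < INTENSITY_THRESHOLD_MM_PER_DAY:
        return INTENSITY_CLASSES[0]
    return INTENSITY_CLASSES[1]


def aggregate_stand(
    observations: Iterable[EventTroughObservation],
    event: Optional[SnowfallEvent] = None,
) -> StandEventSummary:
    """Stand-scale means of one event's observations across troughs.

    The arithmetic mean over troughs represents the whole stand.  Efficiency
    is computed from the mean interception and the event SWE when the event
    is supplied (and its SWE is positive), else left as None.
    """
    obs = list(observations)
    if not obs:
        raise InputError("no observations to aggregate")
    event_ids = {o.event_id for o in obs}
    if len(event_ids) != 1:
        raise InputError(f"observations span multiple events: {sorted(event_ids)}")
    (event_id,) = event_ids
    if event is not None and event.event_id != event_id:
        raise InputError(f"event {event.event_id} does not match observations ({event_id})")
    mean_t = fmean(o.throughfall for o in obs)
    mean_i = fmean(o.interception for o in obs)
    eff = None
    if event is not None and event.swe > 0:
        eff = interception_efficiency(mean_i, event.swe)
    return StandEventSummary(
        event_id=event_id,
        mean_throughfall=mean_t,
        mean_interception=mean_i,
        efficiency_pct=eff,
        n_troughs=len(obs),
    )


def campaign_summary(
    events: Sequence[SnowfallEvent],
    observations: Iterable[EventTroughObservation],
) -> CampaignSummary:
    """Cumulative totals and shares over a whole campaign.

    Per-event stand means (via :func:`aggregate_stand`) are summed into
    campaign totals of snowfall, throughfall and interception; shares are
    percentages of total snowfall.  Events with no observations contribute
    snowfall only.  Returns all-zero totals for an empty campaign.
    """
    by_event: dict[str, list[EventTroughObservation]] = {}
    for o in observations:
        by_event.setdefault(o.event_id, []).append(o)
    known = {e.event_id for e in events}
    orphans = set(by_event) - known
    if orphans:
        raise InputError(f"observations reference unknown events: {sorted(orphans)}")

    total_p = sum(e.swe for e in events)
    total_t = 0.0
    total_i = 0.0
    max_i: Optional[float] = None
    max_id: Optional[str] = None
    min_i: Optional[float] = None
    min_id: Optional[str] = None
    for e in events:
        obs = by_event.get(e.event_id)
        if not obs:
            continue
        s = aggregate_stand(obs, e)
        total_t += s.mean_throughfall
        total_i += s.mean_interception
        if max_i is None or s.mean_interception > max_i:
            max_i, max_id = s.mean_interception, e.event_id
        if min_i is None or s.mean_interception < min_i:
            min_i, min_id = s.mean_interception, e.event_id

    t_share = 100.0 * total_t / total_p if total_p > 0 else None
    i_share = 100.0 * total_i / total_p if total_p > 0 else None
    return CampaignSummary(
        n_events=len(events),
        total_snowfall=total_p,
        total_throughfall=total_t,
        total_interception=total_i,
        throughfall_share_pct=t_share,
        interception_share_pct=i_share,
        max_interception=max_i,
        max_interception_event=max_id,
        min_interception=min_i,
        min_interception_event=min_id,
    )
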