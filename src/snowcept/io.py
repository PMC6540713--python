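"""CSV schemas, the packaged trough-table fixture, and run configuration.

Three file schemas tie the pipeline together (comma-separated, header row,
UTF-8, "." decimal, no thousands separators):

``events.csv``
    event_id, date, swe_mm, duration_days, density_kgm3, temp_c
``troughs.csv``
    trough_id, avg_throughfall_mm, avg_interception_mm, n_stems,
    canopy_density_pct, lai, dbh_cm, ba, canopy_height_m, canopy_width_m,
    tree_height_m, slope
``observations.csv``
    event_id, trough_id, throughfall_mm

Canopy density is printed in percent in trough tables and converted to a
fraction once, here at the boundary; the percent value remains available via
``TroughPoint.canopy_density_pct`` for the statistics that use the printed
scale.  Floats are written with ``repr`` precision so write-then-read is an
identity on the domain types, except that the percent<->fraction conversion
of canopy density can perturb its last binary digit (x*100/100 is not an
exact float identity).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import InputError, SchemaError
from .observations import EventTroughObservation, SnowfallEvent, TroughPoint, observe

__all__ = [
    "EVENT_COLUMNS",
    "TROUGH_COLUMNS",
    "OBSERVATION_COLUMNS",
    "load_events",
    "write_events",
    "load_troughs",
    "write_troughs",
    "load_observations",
    "write_observations",
    "load_table2",
    "table2_path",
    "RunConfig",
    "run_pipeline",
]

EVENT_COLUMNS = ("event_id", "date", "swe_mm", "duration_days", "density_kgm3", "temp_c")
TROUGH_COLUMNS = (
    "trough_id",
    "avg_throughfall_mm",
    "avg_interception_mm",
    "n_stems",
    "canopy_density_pct",
    "lai",
    "dbh_cm",
    "ba",
    "canopy_height_m",
    "canopy_width_m",
    "tree_height_m",
    "slope",
)
OBSERVATION_COLUMNS = ("event_id", "trough_id", "throughfall_mm")

PathLike = Union[str, Path]


def _open_reader(path: PathLike, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        fh.close()
        raise SchemaError(f"{path}: missing column(s) {missing}; header was {header}")
    return reader, fh

def _num(row: dict, col: str, path: PathLike, lineno: int, optional: bool = False):
    raw = (row.get(col) or "").strip()
    if raw == "":
        if optional:
            return None
        raise SchemaError(f"{path}, line {lineno}: empty value in column {col!r}")
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"{path}, line {lineno}: non-numeric value {raw!r} in column {col!r}"
        ) from None


def load_events(path: PathLike) -> list[SnowfallEvent]:
    """Read an events.csv into :class:`SnowfallEvent` records."""
    reader, fh = _open_reader(path, EVENT_COLUMNS)
    out = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            swe = _num(row, "swe_mm", path, lineno)
            dur = _num(row, "duration_days", path, lineno)
            if dur <= 0:
                raise SchemaError(f"{path}, line {lineno}: non-positive duration")
            out.append(
                SnowfallEvent(
                    event_id=row["event_id"].strip(),
                    date=(row.get("date") or "").strip() or None,
                    swe=swe,
                    duration=dur,
                    intensity=swe / dur,
                    fresh_snow_density=_num(row, "density_kgm3", path, lineno),
                    air_temp=_num(row, "temp_c", path, lineno, optional=True),
                )
            )
    return out


def write_events(path: PathLike, events: Sequence[SnowfallEvent]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow(
                [
                    e.event_id,
                    e.date or "",
                    repr(e.swe),
                    repr(e.duration),
                    repr(e.fresh_snow_density),
                    "" if e.air_temp is None else repr(e.air_temp),
                ]
            )


def load_troughs(path: PathLike) -> list[TroughPoint]:
    """Read a troughs.csv (trough-table schema) into :class:`TroughPoint` records.

    Canopy density percent is converted to a fraction; the campaign-average
    throughfall/interception columns ride along when present.
    """
    reader, fh = _open_reader(path, TROUGH_COLUMNS)
    out = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            stems = _num(row, "n_stems", path, lineno)
            if stems != int(stems):
                raise SchemaError(f"{path}, line {lineno}: fractional stem count")
            try:
                out.append(
                    TroughPoint(
                        trough_id=row["trough_id"].strip(),
                        canopy_density=_num(row, "canopy_density_pct", path, lineno) / 100.0,
                        lai=_num(row, "lai", path, lineno),
                        dbh=_num(row, "dbh_cm", path, lineno),
                        basal_area=_num(row, "ba", path, lineno),
                        canopy_height=_num(row, "canopy_height_m", path, lineno),
                        canopy_width=_num(row, "canopy_width_m", path, lineno),
                        tree_height=_num(row, "tree_height_m", path, lineno),
                        slope=_num(row, "slope", path, lineno),
                        n_conifer_stems=int(stems),
                        avg_throughfall=_num(row, "avg_throughfall_mm", path, lineno, optional=True),
                        avg_interception=_num(row, "avg_interception_mm", path, lineno, optional=True),
                    )
                )
            except InputError as err:
                raise SchemaError(f"{path}, line {lineno}: {err}") from err
    return out


def write_troughs(path: PathLike, troughs: Sequence[TroughPoint]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TROUGH_COLUMNS)
        for t in troughs:
            w.writerow(
                [
                    t.trough_id,
                    "" if t.avg_throughfall is None else repr(t.avg_throughfall),
                    "" if t.avg_interception is None else repr(t.avg_interception),
                    t.n_conifer_stems,
                    repr(t.canopy_density_pct),
                    repr(t.lai),
                    repr(t.dbh),
                    repr(t.basal_area),
                    repr(t.canopy_height),
                    repr(t.canopy_width),
                    repr(t.tree_height),
                    repr(t.slope),
                ]
            )


def load_observations(
    path: PathLike, events: Sequence[SnowfallEvent]
) -> list[EventTroughObservation]:
    """Read an observations.csv against its event list.

    Interception is derived through the water balance (event SWE minus
    throughfall) and negative residuals are flagged; an observation whose
    event id is absent from the event list raises with its line number.
    """
    reader, fh = _open_reader(path, OBSERVATION_COLUMNS)
    by_id = {e.event_id: e for e in events}
    out = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            eid = row["event_id"].strip()
            tf = _num(row, "throughfall_mm", path, lineno)
            if eid not in by_id:
                raise SchemaError(f"{path}, line {lineno}: unknown event id {eid!r}")
            out.append(observe(by_id[eid], row["trough_id"].strip(), tf))
    return out


def write_observations(path: PathLike, observations: Sequence[EventTroughObservation]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(OBSERVATION_COLUMNS)
        for o in observations:
            w.writerow([o.event_id, o.trough_id, repr(o.throughfall)])


def table2_path() -> Path:
    """Path of the packaged 56-trough stand table."""
    return Path(resources.files("snowcept") / "data" / "table2_troughs.csv")


def load_table2() -> list[TroughPoint]:
    """The packaged 56-point trough table as :class:`TroughPoint` records."""
    return load_troughs(table2_path())


# --------------------------------------------------------------------------
# run configuration and pipeline


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    troughs: Optional[str] = None  # None -> packaged fixture
    events: Optional[str] = None
    observations: Optional[str] = None
    out_dir: str = "results"
    seed: int = 0
    unload_coeff: float = 0.68
    snow_load_coeff_kgm2: float = 6.3
    fresh_snow_density_kgm3: float = 81.0
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig, log=None) -> dict:
    """Observations -> model -> statistics over the configured inputs.

    Always computes the stand-structure statistics (correlations of
    campaign-average throughfall/interception with canopy metrics, the
    interception~canopy-density line, stepwise selection) from the trough
    table.  When events and per-trough observations are supplied, also
    computes the per-event water balance, campaign totals and the
    interception-model simulation with both historical and recalibrated
    parameters.  Results land in ``out_dir`` as ``pipeline_results.json``
    (floats at fixed 6-decimal precision, so identical config + seed gives
    byte-identical output) and a human-readable ``report.txt``.
    """
    import numpy as np

    from . import interception_model as im
    from . import stand_stats as ss
    from .observations import aggregate_stand, campaign_summary

    def say(msg):
        if log is not None:
            log(msg)

    troughs = load_troughs(cfg.troughs) if cfg.troughs else load_table2()
    say(f"stage troughs: {len(troughs)} sampling points")
    results: dict = {"config": dataclasses.asdict(cfg), "n_troughs": len(troughs)}

    tf = [t.avg_throughfall for t in troughs]
    ic = [t.avg_interception for t in troughs]
    have_avgs = all(v is not None for v in tf) and all(v is not None for v in ic)
    if have_avgs:
        import pandas as pd

        metric_cols = {
            "dbh_cm": [t.dbh for t in troughs],
            "canopy_density_pct": [t.canopy_density_pct for t in troughs],
            "tree_height_m": [t.tree_height for t in troughs],
            "ba": [t.basal_area for t in troughs],
            "canopy_height_m": [t.canopy_height for t in troughs],
            "canopy_width_m": [t.canopy_width for t in troughs],
            "lai": [t.lai for t in troughs],
            "slope": [t.slope for t in troughs],
        }
        corr = {}
        for name, vals in metric_cols.items():
            corr[name] = {
                "throughfall": dataclasses.asdict(ss.pearson(tf, vals, ("throughfall", name))),
                "interception": dataclasses.asdict(ss.pearson(ic, vals, ("interception", name))),
            }
        results["correlations"] = corr
        line = ss.fit_linear(metric_cols["canopy_density_pct"], ic)
        results["interception_vs_canopy_density"] = dataclasses.asdict(line)
        X = pd.DataFrame(metric_cols)
        steps = ss.stepwise_regression(
            np.asarray(tf, float), X, cfg.alpha_enter, cfg.alpha_remove
        )
        results["stepwise_throughfall"] = [dataclasses.asdict(s) for s in steps]
        say("stage stats: correlations, canopy-density line, stepwise selection done")

    params = im.InterceptionParams(
        unload_coeff=cfg.unload_coeff,
        snow_load_coeff=cfg.snow_load_coeff_kgm2,
        fresh_snow_density=cfg.fresh_snow_density_kgm3,
    )
    results["model_coefficients"] = dataclasses.asdict(im.derive_model_coefficients(params))

    if cfg.events:
        events = load_events(cfg.events)
        say(f"stage events: {len(events)} snowfall events")
        obs = load_observations(cfg.observations, events) if cfg.observations else []
        if obs:
            by_event = {}
            for o in obs:
                by_event.setdefault(o.event_id, []).append(o)
            stand = [
                aggregate_stand(by_event[e.event_id], e)
                for e in events
                if e.event_id in by_event
            ]
            results["stand_events"] = [dataclasses.asdict(s) for s in stand]
            results["campaign"] = dataclasses.asdict(campaign_summary(events, obs))
            mean_lai = float(np.mean([t.lai for t in troughs]))
            mean_cc = float(np.mean([t.canopy_density for t in troughs]))
            observed = [s.mean_interception for s in stand]
            used = [e for e in events if e.event_id in by_event]
            sim = im.simulate_events(used, mean_lai, mean_cc, params, observed=observed)
            results["simulation"] = dataclasses.asdict(sim)
            say("stage model: event simulation done")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _round_floats(results)
    (out_dir / "pipeline_results.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "report.txt").write_text(_render_report(payload), encoding="utf-8")
    say(f"results written to {out_dir}")
    return results


def _render_report(res: dict) -> str:
    lines = ["Snow interception pipeline report", "=" * 34, ""]
    lines.append(f"Trough sampling points: {res.get('n_troughs')}")
    mc = res.get("model_coefficients")
    if mc:
        lines.append(
            "Interception model (per unit LAI): "
            f"i = {mc['prefactor']}*LAI*(1 - exp(-Cc*pc/({mc['capacity_per_lai']}*LAI)))"
        )
    line = res.get("interception_vs_canopy_density")
    if line:
        c = line["coefficients"]
        lines.append(
            f"Interception vs canopy density (%): i = {c['intercept']:.3f} "
            f"+ {c['slope']:.4f}*Cc  (R2 = {line['r_squared']:.3f}, n = {line['n']})"
        )
    corr = res.get("correlations")
    if corr:
        lines.append("")
        lines.append("Correlations with campaign averages (r, stars):")
        for name, d in corr.items():
            t, i = d["throughfall"], d["interception"]
            lines.append(
                f"  {name:>20}: throughfall {t['r']:+.2f} ({t['stars']}), "
                f"interception {i['r']:+.2f} ({i['stars']})"
            )
    camp = res.get("campaign")
    if camp:
        lines.append("")
        lines.append(
            f"Campaign: {camp['n_events']} events, snowfall {camp['total_snowfall']:.1f} mm, "
            f"throughfall {camp['total_throughfall']:.1f} mm "
            f"({camp['throughfall_share_pct']:.1f}%), interception "
            f"{camp['total_interception']:.1f} mm ({camp['interception_share_pct']:.1f}%)"
        )
    sim = res.get("simulation")
    if sim and sim.get("fit"):
        lines.append(
            f"Model simulation: cumulative predicted {sim['cumulative_predicted']:.1f} mm "
            f"vs observed {sim['cumulative_observed']:.1f} mm, "
            f"R2 = {sim['fit']['r_squared']:.3f}"
        )
    return "\n".join(lines) + "\n"
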