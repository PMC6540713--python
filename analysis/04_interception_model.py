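#!/usr/bin/env python
"""Interception-model simulation and recalibration on the synthetic campaign.

Derives the printed-form coefficients for the original (Sp 6.25 kg/m2,
rho_s 70 kg/m3) and revised (Sp 6.3, measured rho_s 81) parameter sets,
simulates the synthetic campaign's per-event stand interception with both,
reports cumulative totals and goodness of fit, and recalibrates the
unloading coefficient c against the campaign's observed interception.
Writes predictions and the fit summary under results/model/.
"""

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from snowcept.interception_model import (
    InterceptionParams,
    derive_model_coefficients,
    fit_unloading_coefficient,
    simulate_events,
)
from snowcept.io import load_events, load_observations, load_troughs
from snowcept.observations import aggregate_stand

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "model"


def main() -> None:
    events = load_events(ROOT / "synthetic" / "events.csv")
    troughs = load_troughs(ROOT / "synthetic" / "troughs.csv")
    obs = load_observations(ROOT / "synthetic" / "observations.csv", events)
    by_event = {}
    for o in obs:
        by_event.setdefault(o.event_id, []).append(o)
    observed = [
        aggregate_stand(by_event[e.event_id], e).mean_interception for e in events
    ]
    mean_lai = float(np.mean([t.lai for t in troughs]))
    mean_cc = float(np.mean([t.canopy_density for t in troughs]))

    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    sims = {}
    for label, params in {
        "original": InterceptionParams.pomeroy_hedstrom(),
        "revised": InterceptionParams.revised(),
    }.items():
        mc = derive_model_coefficients(params)
        sim = simulate_events(events, mean_lai, mean_cc, params, observed=observed)
        sims[label] = sim
        summary[label] = {
            "coefficients": dataclasses.asdict(mc),
            "cumulative_predicted_mm": round(sim.cumulative_predicted, 2),
            "cumulative_observed_mm": round(sim.cumulative_observed, 2),
            "r_squared": round(sim.fit.r_squared, 3),
            "bias_mm": round(sim.fit.bias, 3),
        }
        print(f"{label:>8}: i = {mc.prefactor}*LAI*(1 - exp(-Cc*pc/({mc.capacity_per_lai}*LAI)))"
              f"  cumulative {sim.cumulative_predicted:.1f} mm "
              f"(observed {sim.cumulative_observed:.1f} mm), "
              f"R2 = {sim.fit.r_squared:.3f}")

    with open(OUT / "predictions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_id", "observed_mm", "predicted_original_mm",
                    "predicted_revised_mm"])
        for j, eid in enumerate(sims["revised"].event_ids):
            w.writerow([eid, f"{observed[j]:.4f}",
                        f"{sims['original'].predicted[j]:.4f}",
                        f"{sims['revised'].predicted[j]:.4f}"])

    c_hat, rss = fit_unloading_coefficient(events, mean_lai, mean_cc, observed)
    summary["recalibrated_unload_coeff"] = round(c_hat, 4)
    summary["recalibration_rss"] = round(rss, 4)
    print(f"recalibrated unloading coefficient c = {c_hat:.3f} "
          f"(generator truth 0.68; stand-mean fit, rss {rss:.3f})")

    (OUT / "fit_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
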