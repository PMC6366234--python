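"""End-to-end pipeline: simulate -> terrain -> segment -> acc -> suitability
-> intensity -> energy, from one seed.

Every stage's tabular output is written as CSV, rasters as ESRI ASCII grids,
and fit summaries as JSON, so a single seeded command reproduces the whole
analysis on a synthetic landscape with known truth.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import acc as _acc
from . import energy as _energy
from . import intensity as _intensity
from . import io as _io
from . import segmentation as _seg
from . import suitability as _suit
from .synthetic import (LandscapeConfig, ScheduleConfig, generate_landscape,
                        simulate_tracks)

log = logging.getLogger(__name__)


def run_pipeline(seed: int, out_dir: str | Path | None = None,
                 n_birds: int = 20, shape: tuple[int, int] = (150, 150),
                 landscape_config: LandscapeConfig | None = None,
                 schedule: ScheduleConfig | None = None,
                 frameworks: tuple[str, ...] = ("static",),
                 gam_frameworks: tuple[str, ...] = ("static",),
                 write: bool = True) -> dict:
    """Run the full synthetic analysis; returns a dict of all artifacts."""
    t0 = time.time()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    land = generate_landscape(seed, shape=shape, config=landscape_config)
    # the full study tracks birds longer than the quick-look default of
    # ScheduleConfig: presence/absence counts (and hence model stability)
    # scale with tracking effort
    schedule = schedule or ScheduleConfig(n_days=6)
    fixes, bursts, truth = simulate_tracks(land, n_birds=n_birds, seed=seed + 1,
                                           schedule=schedule)
    log.info("simulated %d fixes, %d ACC bursts", len(fixes), len(bursts))

    stack = land.predictor_stack()

    segments = _seg.segment_bursts(fixes, georef=land.georef)
    segments, embc = _seg.embc_classify(segments, seed=seed)
    segments["behaviour"] = _seg.smooth_labels(
        segments["behaviour"].to_numpy(), segments["burst_id"].to_numpy())
    events = _seg.extract_soaring_events(segments)

    bursts = _acc.compute_odba(bursts)
    bursts = _acc.classify_activity(bursts, seed=seed)
    bursts = _acc.geolocate_bursts(bursts, fixes, land.dem)
    flaps = _acc.select_flapping(bursts)

    results: dict = {
        "landscape": land, "fixes": fixes, "acc_bursts": bursts,
        "truth": truth, "stack": stack, "segments": segments,
        "events": events, "flaps": flaps, "embc_model": embc,
        "ensembles": {}, "gam_fits": {},
    }

    for fw in frameworks:
        obs = _suit.assemble_observations(events, flaps, stack, framework=fw)
        ens = _suit.fit_rf_cv(obs, framework=fw, seed=seed)
        results["ensembles"][fw] = ens
        results.setdefault("observations", {})[fw] = obs
    primary = results["ensembles"][frameworks[0]]
    suit_map = _suit.predict_map(primary, stack)
    results["suitability_map"] = suit_map

    # intensity on gridded positive vertical speeds
    fx = []
    for _, b in fixes.groupby("burst_id", sort=False):
        fx.append(_seg.compute_fix_metrics(b.sort_values("timestamp"),
                                           land.georef))
    fx = pd.concat(fx, ignore_index=True)
    cells = _intensity.grid_vertical_speeds(fx, stack.grid)
    cells = _intensity.filter_percentile(cells)
    results["intensity_cells"] = cells
    for fw in gam_frameworks:
        results["gam_fits"][fw] = _intensity.fit_gam(cells, stack, framework=fw)
    if len(results["gam_fits"]) > 1:
        results["gam_comparison"] = _intensity.compare_frameworks(
            list(results["gam_fits"].values()))
    intensity_map = _intensity.predict_intensity_map(
        results["gam_fits"][gam_frameworks[0]], stack, suit_map)
    results["intensity_map"] = intensity_map

    records = _energy.build_daily_records(bursts, suit_map)
    energy_fit = _energy.fit_energy_model(records)
    results["daily_records"] = records
    results["energy_fit"] = energy_fit
    results["runtime_s"] = time.time() - t0

    if out:
        _write_outputs(out, results)
    return results


def _write_outputs(out: Path, r: dict) -> None:
    land = r["landscape"]
    rdir = out / "rasters"
    rdir.mkdir(exist_ok=True)
    for name, ras in land.rasters().items():
        ras.write_ascii(rdir / f"{name}.asc")
    for name, ras in r["stack"].layers.items():
        ras.write_ascii(rdir / f"{name}.asc")
    r["suitability_map"].probability.write_ascii(out / "suitability_probability.asc")
    r["suitability_map"].binary.write_ascii(out / "suitability_binary.asc")
    r["intensity_map"].write_ascii(out / "uplift_intensity.asc")

    _io.write_gps_csv(r["fixes"], out / "gps.csv")
    _io.write_acc_csv(r["acc_bursts"], out / "acc.csv")
    r["segments"].drop(columns=["truth_behaviour"], errors="ignore").to_csv(
        out / "segments.csv", index=False)
    r["events"].to_csv(out / "soaring_events.csv", index=False)
    r["flaps"].to_csv(out / "flapping_absences.csv", index=False)
    r["intensity_cells"].to_csv(out / "intensity_cells.csv", index=False)
    r["daily_records"].to_csv(out / "daily_energy_records.csv", index=False)
    r["truth"].decisions.to_csv(out / "truth_decisions.csv", index=False)
    pd.DataFrame({"fix_truth": r["truth"].fix_labels}).to_csv(
        out / "truth_fix_labels.csv", index=False)

    summary = {
        "runtime_s": r["runtime_s"],
        "n_fixes": int(len(r["fixes"])),
        "n_acc_bursts": int(len(r["acc_bursts"])),
        "n_presences": int(len(r["events"])),
        "n_absences": int(len(r["flaps"])),
        "planted_coefficients": r["truth"].coefficients,
        "suitability": {
            fw: {
                "metrics_mean": ens.metrics.drop(columns=["run"]).mean().to_dict(),
                "threshold": ens.threshold,
                "importances": ens.importances.to_dict(orient="list"),
            } for fw, ens in r["ensembles"].items()},
        "intensity": {
            fw: {"aic": f.aic, "adj_r2": f.adj_r2, "alpha": f.alpha,
                 "edf_by_term": f.edf_by_term, "n_obs": f.n_obs}
            for fw, f in r["gam_fits"].items()},
        "energy": {k: v for k, v in vars(r["energy_fit"]).items()
                   if k != "result"},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
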