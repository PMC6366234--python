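"""Build an uplift-suitability map step by step from its components.

Shows what `run_pipeline` does internally, at a small scale: each stage is
one library call, and every intermediate table can be inspected.

Run:  python examples/suitability_step_by_step.py
"""

import numpy as np

import upliftscape as u
from upliftscape.synthetic import ScheduleConfig

# 1. A synthetic landscape with a known (planted) uplift probability field,
#    and four days of GPS + accelerometer data for eight birds.
land = u.generate_landscape(seed=11, shape=(100, 100))
fixes, bursts, truth = u.simulate_tracks(land, n_birds=8, seed=12,
                                         schedule=ScheduleConfig(n_days=4))
print(f"{len(fixes)} GPS fixes, {len(bursts)} ACC bursts, "
      f"{fixes['individual_id'].nunique()} birds")

# 2. Terrain predictors are derived from the DEM; here the simulator already
#    provides the co-registered stack (DEM, slope, aspect, roughness, ...).
stack = land.predictor_stack()
screen = u.check_multicollinearity(
    stack, fixes.sample(500, random_state=1), threshold=0.7)
print(f"multicollinearity screen: {len(screen)} flagged pairs")

# 3. GPS segmentation: 15 s segments, EM binary clustering, label smoothing,
#    and extraction of soaring events (the uplift presences).
segments = u.segment_bursts(fixes, georef=land.georef)
segments, model = u.embc_classify(segments, seed=13)
segments["behaviour"] = u.smooth_labels(segments["behaviour"].to_numpy(),
                                        segments["burst_id"].to_numpy())
events = u.extract_soaring_events(segments)
print(f"{len(segments)} segments -> {len(events)} soaring events "
      f"(turn delimiter {model.delimiters[1]:.0f} deg)")

# 4. Accelerometer: ODBA, activity classes, geolocation; flapping bursts
#    more than 100 m above ground are uplift absences.
bursts = u.compute_odba(bursts)
bursts = u.classify_activity(bursts, seed=14)
bursts = u.geolocate_bursts(bursts, fixes, land.dem)
flaps = u.select_flapping(bursts)
print(f"{len(flaps)} high-altitude flapping bursts (absences)")

# 5. Random-forest suitability: ten 90/10 cross-validated forests, and a
#    range-masked map binarized at the max-TSS threshold.
obs = u.assemble_observations(events, flaps, stack, framework="static")
ensemble = u.fit_rf_cv(obs, framework="static", seed=15)
suit_map = u.predict_map(ensemble, stack)
print(f"held-out AUC {ensemble.metrics['auc_test'].mean():.3f}, "
      f"threshold {suit_map.threshold:.2f}")

# 6. Compare the map with the planted truth it was supposed to recover.
p_hat = suit_map.probability.data
ok = np.isfinite(p_hat)
r = np.corrcoef(p_hat[ok], land.p_uplift.data[ok])[0, 1]
print(f"correlation with the planted uplift field: {r:.3f}")
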