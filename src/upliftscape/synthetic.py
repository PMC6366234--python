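"""Synthetic landscapes and simulated stork flight with known ground truth.

The generator plants a known uplift-probability surface (a logistic function
of terrain roughness, elevation, NDVI and land use, with water forced to
zero) and a known uplift-intensity surface (increasing with uplift
probability, decreasing with latitude, optionally modulated by a dynamic
thermal-potential field) on correlated Gaussian-random-field terrain.
Simulated birds alternate circular/linear soaring (where a Bernoulli draw on
the local uplift probability succeeds), gliding, and flapping (where it
fails), on the real study's sampling schedules: 1 Hz GPS bursts of 300 s
every 15 min, tri-axial accelerometer bursts of 3.8 s at 10.54 Hz
(40 samples per axis) every 10 min.

Every simulated GPS fix and ACC burst carries a ground-truth behaviour
label, and the planted generating coefficients are returned, so downstream
segmentation, classification and model-fitting stages can be scored against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GeoRef, Raster, M_PER_DEG_LAT
from . import terrain as _terrain

__all__ = [
    "LandscapeConfig", "ScheduleConfig", "SimulatedLandscape",
    "SimulationTruth", "ConfigError", "generate_landscape", "simulate_tracks",
    "make_energy_records", "sample_intensity_cells", "LAND_USE_CODES",
]

LAND_USE_CODES = {
    "bare_soil": 1, "water": 2, "urban": 3, "wetland": 4,
    "dump": 5, "pasture": 6, "forest": 7,
}
LAND_USE_NAMES = {v: k for k, v in LAND_USE_CODES.items()}


class ConfigError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    """Parameters of the planted landscape.

    The logistic coefficients act on per-layer standardized values (mean 0,
    sd 1 over non-water cells), so their magnitudes are comparable.  Signs
    follow the field's expectations: rough, elevated, sparsely vegetated
    terrain and urban/dump land uses favour thermal uplift; water suppresses
    it entirely.
    """

    cellsize: float = 100.0
    corr_length_m: float = 1500.0     # GRF autocorrelation length
    dem_mean: float = 450.0           # m
    dem_sd: float = 120.0             # m
    # logistic model for the uplift-probability surface
    p_intercept: float = 0.0
    coef_roughness: float = 2.0
    coef_dem: float = 1.4
    coef_ndvi: float = -1.6
    land_use_offsets: dict = field(default_factory=lambda: {
        "bare_soil": 1.0, "urban": 1.2, "wetland": -1.2,
        "dump": 1.6, "pasture": 0.2, "forest": -0.6,
    })
    land_use_fractions: dict = field(default_factory=lambda: {
        "water": 0.05, "wetland": 0.05, "urban": 0.07, "dump": 0.01,
        "bare_soil": 0.12, "pasture": 0.35, "forest": 0.35,
    })
    # uplift-intensity surface (m/s)
    w_base: float = 1.0               # non-water mean intensity after scaling
    w_p_weight: float = 0.9           # dependence on uplift probability
    w_lat_coef: float = 0.25          # fractional decrease per degree northward
    w_dyn_weight: float = 0.4         # modulation by the thermal-potential field
    georef: GeoRef = field(default_factory=GeoRef)


@dataclass
class ScheduleConfig:
    """Sampling schedules and flight kinematics of the simulated storks."""

    # observation schedules (study defaults)
    gps_burst_s: int = 300            # 1 Hz burst length
    gps_cycle_s: int = 900            # one burst every 15 min
    acc_cycle_s: int = 600            # ACC burst every 10 min
    acc_n_samples: int = 40           # per axis
    acc_rate_hz: float = 10.54
    # simulated effort
    day_flight_s: int = 7200          # 2 h of flight per bird-day
    n_days: int = 3
    # behaviour budget targets (the study's observed time budget)
    soar_frac_target: float = 0.51
    flap_frac_target: float = 0.05
    linear_soar_prob: float = 0.12    # fraction of soaring bouts that are linear
    # kinematics
    climb_dh_m: float = 450.0         # height gained per soaring bout
    soar_speed: float = 12.5          # m/s ground speed while circling
    circle_period_s: float = 15.0     # one full circle per 15 s
    glide_speed: float = 14.0
    flap_speed: float = 10.0
    base_agl_m: float = 250.0         # cruising height above ground
    w_noise_sd: float = 0.15          # lognormal sd of realized climb rate
    # GPS error: AR(1)-correlated Gaussian per axis
    gps_sigma_xy: float = 3.0
    gps_sigma_z: float = 5.0
    gps_rho: float = 0.95
    # accelerometer signal (units of g)
    flap_amp: float = 1.0
    flap_freq_hz: float = 3.5
    glide_amp: float = 0.18
    soar_amp: float = 0.07
    acc_noise: float = 0.03


@dataclass
class SimulatedLandscape:
    """Raster layers sharing one grid, with the planted truth surfaces."""

    dem: Raster
    ndvi: Raster
    land_use: Raster
    urban_footprint: Raster
    p_uplift: Raster
    w_uplift: Raster
    latitude: Raster
    thermal_uplift: Raster
    orographic_uplift: Raster
    config: LandscapeConfig = field(default_factory=LandscapeConfig)

    def rasters(self) -> dict[str, Raster]:
        return {k: getattr(self, k) for k in (
            "dem", "ndvi", "land_use", "urban_footprint", "p_uplift",
            "w_uplift", "latitude", "thermal_uplift", "orographic_uplift")}

    @property
    def georef(self) -> GeoRef:
        return self.config.georef

    def predictor_stack(self) -> _terrain.PredictorStack:
        """Terrain derivatives plus the observed landscape layers, one grid."""
        stack = _terrain.derive_terrain(self.dem)
        stack.layers.update({
            "ndvi": self.ndvi, "land_use": self.land_use,
            "urban_footprint": self.urban_footprint, "latitude": self.latitude,
            "thermal_uplift": self.thermal_uplift,
            "orographic_uplift": self.orographic_uplift,
        })
        return stack


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run.

    ``fix_labels``/``burst_labels`` are aligned with the returned GPS fixes
    and ACC bursts; ``decisions`` records every Bernoulli uplift draw (cell,
    planted probability, outcome) so the realized soaring rate can be tested
    against the planted field; ``coefficients`` are the planted generating
    parameters.
    """

    fix_labels: pd.Series
    burst_labels: pd.Series
    decisions: pd.DataFrame
    coefficients: dict


def _grf(rng: np.random.Generator, shape, corr_cells: float) -> np.ndarray:
    """Smoothed Gaussian random field, standardized to mean 0 / sd 1."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def _standardize(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu, sd = a[mask].mean(), a[mask].std()
    return (a - mu) / (sd if sd > 0 else 1.0)


def generate_landscape(seed: int, shape: tuple[int, int] = (150, 150),
                       config: LandscapeConfig | None = None) -> SimulatedLandscape:
    """Generate a landscape with a planted uplift field.

    Deterministic given ``(seed, shape, config)``.  ``shape`` must be at
    least 50x50 cells.
    """
    cfg = config or LandscapeConfig()
    if len(shape) != 2 or shape[0] < 50 or shape[1] < 50:
        raise ConfigError("landscape shape must be at least 50x50 cells")
    for name in ("coef_roughness", "coef_dem", "coef_ndvi", "p_intercept"):
        if not np.isfinite(getattr(cfg, name)):
            raise ConfigError(f"non-finite logistic coefficient {name!r}")
    missing = set(LAND_USE_CODES) - {"water"} - set(cfg.land_use_offsets)
    if missing:
        raise ConfigError(f"land_use_offsets missing classes: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    corr_cells = cfg.corr_length_m / cfg.cellsize

    def mk(data, name):
        return Raster(data, cellsize=cfg.cellsize, name=name)

    dem = cfg.dem_mean + cfg.dem_sd * _grf(rng, shape, corr_cells)
    ndvi = np.clip(0.45 + 0.28 * _grf(rng, shape, corr_cells), -1.0, 1.0)

    # categorical land use from a pair of GRFs thresholded at target fractions
    u1 = _grf(rng, shape, corr_cells * 0.6)
    order = ["water", "wetland", "urban", "dump", "bare_soil", "pasture", "forest"]
    fracs = np.array([cfg.land_use_fractions[k] for k in order], float)
    fracs = fracs / fracs.sum()
    edges = np.quantile(u1, np.cumsum(fracs)[:-1])
    land = np.digitize(u1, edges)
    land_use = np.vectorize(lambda i: LAND_USE_CODES[order[i]])(land)
    urban = (land_use == LAND_USE_CODES["urban"]).astype(float)
    water = land_use == LAND_USE_CODES["water"]

    # roughness of the generated DEM drives the planted logistic surface
    rough = _terrain.derive_terrain(mk(dem, "dem")).layers["roughness"].data
    rough = np.where(np.isnan(rough), np.nanmean(rough), rough)

    nonwater = ~water
    eta = (cfg.p_intercept
           + cfg.coef_roughness * _standardize(rough, nonwater)
           + cfg.coef_dem * _standardize(dem, nonwater)
           + cfg.coef_ndvi * _standardize(ndvi, nonwater))
    for name, off in cfg.land_use_offsets.items():
        eta = eta + off * (land_use == LAND_USE_CODES[name])
    p_uplift = 1.0 / (1.0 + np.exp(-eta))
    p_uplift[water] = 0.0

    nr, nc = shape
    lat_row = cfg.georef.lat_north - (np.arange(nr) + 0.5) * cfg.cellsize / M_PER_DEG_LAT
    latitude = np.broadcast_to(lat_row[:, None], shape).copy()
    lat_south = latitude.min()

    thermal = 0.6 * _standardize(p_uplift, nonwater) + 0.8 * _grf(rng, shape, corr_cells)
    thermal = (thermal - thermal.min()) / (thermal.max() - thermal.min())
    orographic = 0.5 * _standardize(rough, nonwater) + 0.9 * _grf(rng, shape, corr_cells)
    orographic = (orographic - orographic.min()) / (orographic.max() - orographic.min())

    w = (0.35 + cfg.w_p_weight * p_uplift)
    w *= 1.0 - cfg.w_lat_coef * (latitude - lat_south)
    w *= 1.0 + cfg.w_dyn_weight * (thermal - 0.5)
    w = np.clip(w, 0.05, None)
    w *= cfg.w_base / w[nonwater].mean()
    w[water] = 0.0

    return SimulatedLandscape(
        dem=mk(dem, "dem"), ndvi=mk(ndvi, "ndvi"),
        land_use=mk(land_use.astype(float), "land_use"),
        urban_footprint=mk(urban, "urban_footprint"),
        p_uplift=mk(p_uplift, "p_uplift"), w_uplift=mk(w, "w_uplift"),
        latitude=mk(latitude, "latitude"),
        thermal_uplift=mk(thermal, "thermal_uplift"),
        orographic_uplift=mk(orographic, "orographic_uplift"),
        config=cfg)


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _budget_params(land: SimulatedLandscape, sch: ScheduleConfig,
                   n_cycles: int = 4000, calibration_seed: int = 12345):
    """Sink rate and flapping-bout duration that realize the target budget.

    One renewal cycle is: repeated flapping bouts at Bernoulli(p) failures
    until a success, then a soaring climb of ~dh at the local intensity and
    a glide of ~dh/sink.  Because uplift probability is spatially
    correlated, failures cluster in low-p regions, so the expected failures
    per success (M) and the expected climb time per success (t_climb,
    including the simulator's multiplicative climb-rate and climb-height
    noise) are estimated by a cheap virtual renewal walk over the
    probability raster (deterministic: own seed, independent of the track
    simulation), and

        sink = (f_soar / f_glide) * dh / t_climb
        t_flap = (f_flap / f_soar) * t_climb / M

    follow from equating expected per-cycle times to the target shares.
    Two passes, since flap-bout length feeds back into the walk.
    """
    p_r, w_r = land.p_uplift, land.w_uplift
    nr, nc = p_r.shape
    cell = p_r.cellsize
    xmax, ymax = nc * cell, nr * cell
    margin = 2 * cell
    f_s = sch.soar_frac_target
    f_f = sch.flap_frac_target
    f_g = max(1.0 - f_s - f_f, 1e-6)
    dh = sch.climb_dh_m
    noise_infl = float(np.exp(sch.w_noise_sd ** 2 / 2))
    if float(p_r.data.min()) >= 0.999:        # uplift everywhere: no flapping
        t_climb = dh * noise_infl * float(
            (1.0 / np.maximum(w_r.data, 0.2)).mean())
        return (f_s / f_g) * dh / t_climb, 30.0

    rng = np.random.default_rng(calibration_seed)
    t_flap = 40.0
    sink = 1.2
    for _ in range(2):
        n_fail = 0
        n_succ = 0
        climb_sum = 0.0
        step = sch.flap_speed * t_flap
        for _ in range(n_cycles):
            x = rng.uniform(margin, xmax - margin)
            y = rng.uniform(margin, ymax - margin)
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(400):
                p_here = p_r.sample(x, y)
                if np.isnan(p_here):
                    p_here = 0.0
                if rng.random() < p_here:
                    n_succ += 1
                    climb = (max(0.2, w_r.sample(x, y))
                             * float(np.exp(rng.normal(0, sch.w_noise_sd))))
                    climb_sum += dh * rng.uniform(0.8, 1.2) / climb
                    break
                n_fail += 1
                heading += rng.normal(0, 0.25)
                x = float(_reflect(x + step * np.sin(heading),
                                   margin, xmax - margin))
                y = float(_reflect(y - step * np.cos(heading),
                                   margin, ymax - margin))
        if n_succ == 0:
            break
        M = max(n_fail / n_succ, 1e-6)
        t_climb = climb_sum / n_succ
        sink = (f_s / f_g) * dh / t_climb
        t_flap = (f_f / f_s) * t_climb / M
        t_flap = float(np.clip(t_flap, 3.0, 300.0))
    return sink, t_flap


def _reflect(pos, lo: float, hi: float):
    """Fold coordinates into [lo, hi] as if reflected at the boundaries."""
    span = hi - lo
    pos = (np.asarray(pos, float) - lo) % (2 * span)
    return lo + (span - np.abs(pos - span))


def simulate_tracks(landscape: SimulatedLandscape, n_birds: int, seed: int,
                    schedule: ScheduleConfig | None = None):
    """Simulate stork GPS fixes and ACC bursts over a landscape.

    Returns ``(fixes, acc_bursts, truth)``.  ``fixes`` is a Movebank-style
    frame (one row per retained 1 Hz fix inside a GPS burst);
    ``acc_bursts`` one row per accelerometer burst with a ``samples`` column
    holding the (3, 40) raw-axis array.
    """
    if n_birds < 1:
        raise ConfigError("n_birds must be >= 1")
    sch = schedule or ScheduleConfig()
    rng = np.random.default_rng(seed)
    land = landscape
    geo = land.georef
    dem_r, p_r, w_r = land.dem, land.p_uplift, land.w_uplift
    nr, nc = dem_r.shape
    cell = dem_r.cellsize
    xmax, ymax = nc * cell, nr * cell
    margin = 2 * cell
    sink, t_flap_mean = _budget_params(land, sch)
    turn_rate = 360.0 / sch.circle_period_s

    fix_rows, acc_meta, acc_samples, decisions = [], [], [], []

    epoch = pd.Timestamp("2014-08-15 06:00:00", tz="UTC")

    for bird in range(n_birds):
        bird_id = f"stork{bird + 1:03d}"
        for day in range(sch.n_days):
            # relocate each day: migration-scale displacement
            while True:
                x = rng.uniform(margin, xmax - margin)
                y = rng.uniform(margin, ymax - margin)
                if land.land_use.sample(x, y) != LAND_USE_CODES["water"]:
                    break
            heading = rng.uniform(0, 360)
            ground = dem_r.sample(x, y)
            alt = ground + sch.base_agl_m

            T = sch.day_flight_s
            parts: list[tuple] = []   # (xs, ys, alts, label) per bout
            t = 0
            # whole bouts are generated until the day is covered, then the
            # stream is trimmed to T: day end does not bias the behaviour mix
            while t < T:
                p_here = p_r.sample(x, y)
                if np.isnan(p_here):
                    p_here = 0.0
                row, col = dem_r.rowcol(x, y)
                u = rng.random()
                soar = u < p_here
                decisions.append((int(row), int(col), p_here, int(soar)))
                if soar:
                    w_here = max(0.2, w_r.sample(x, y))
                    climb = w_here * float(np.exp(rng.normal(0, sch.w_noise_sd)))
                    dh = sch.climb_dh_m * rng.uniform(0.8, 1.2)
                    n_s = max(int(round(dh / climb)), sch.acc_n_samples // 8)
                    linear = rng.random() < sch.linear_soar_prob
                    if linear:
                        dhead = rng.normal(0, 1.0, n_s)
                        label = "linear_soaring"
                        speed = sch.glide_speed
                    else:
                        sgn = -1.0 if rng.random() < 0.5 else 1.0
                        dhead = sgn * turn_rate + rng.normal(0, 2.0, n_s)
                        label = "circular_soaring"
                        speed = sch.soar_speed
                    vs = np.full(n_s, climb) + rng.normal(0, 0.05, n_s)
                    x, y, alt, t, heading = _bout(
                        parts, t, x, y, alt, heading, dhead, speed, vs, label,
                        margin, xmax, ymax)
                    # glide back down toward cruising height
                    ground = dem_r.sample(x, y)
                    if np.isnan(ground):
                        ground = land.config.dem_mean
                    d_down = max(alt - (ground + sch.base_agl_m), 60.0)
                    n_g = max(int(round(d_down / sink)), 15)
                    dhead = rng.normal(0, 1.5, n_g)
                    vs = np.full(n_g, -sink) + rng.normal(0, 0.05, n_g)
                    x, y, alt, t, heading = _bout(
                        parts, t, x, y, alt, heading, dhead, sch.glide_speed,
                        vs, "gliding", margin, xmax, ymax)
                    heading = rng.uniform(0, 360)  # new search direction
                else:
                    n_f = max(int(round(t_flap_mean * rng.uniform(0.8, 1.2))), 3)
                    ground = dem_r.sample(x, y)
                    if np.isnan(ground):
                        ground = land.config.dem_mean
                    low = (alt - ground) < 150.0
                    vs = (np.full(n_f, 0.5) if low else np.zeros(n_f))
                    vs = vs + rng.normal(0, 0.05, n_f)
                    dhead = rng.normal(0, 2.0, n_f)
                    x, y, alt, t, heading = _bout(
                        parts, t, x, y, alt, heading, dhead, sch.flap_speed,
                        vs, "flapping", margin, xmax, ymax)
            xs = np.concatenate([p[0] for p in parts])[:T]
            ys = np.concatenate([p[1] for p in parts])[:T]
            alts = np.concatenate([p[2] for p in parts])[:T]
            beh = np.concatenate([np.full(len(p[0]), p[3], dtype=object)
                                  for p in parts])[:T]

            # --- observation process -----------------------------------
            t0 = epoch + pd.Timedelta(days=day)
            exy = _ar1_noise(rng, T, sch.gps_sigma_xy, sch.gps_rho, 2)
            ez = _ar1_noise(rng, T, sch.gps_sigma_z, sch.gps_rho, 1)[0]
            nx = xs + exy[0]
            ny = ys + exy[1]
            nz = alts + ez
            gspd = np.hypot(np.gradient(nx), np.gradient(ny))

            for k in range(T // sch.gps_cycle_s + 1):
                s = k * sch.gps_cycle_s
                e = min(s + sch.gps_burst_s, T)
                if e - s < 30:
                    continue
                burst_id = f"{bird_id}_d{day}_b{k}"
                lon, lat = geo.to_lonlat(nx[s:e], ny[s:e])
                fix_rows.append(pd.DataFrame({
                    "individual_id": bird_id,
                    "burst_id": burst_id,
                    "timestamp": t0 + pd.to_timedelta(np.arange(s, e), unit="s"),
                    "lon": lon, "lat": lat,
                    "x": nx[s:e], "y": ny[s:e],
                    "height": nz[s:e],
                    "ground_speed": gspd[s:e],
                    "truth_behaviour": beh[s:e],
                }))

            offs = sch.acc_cycle_s // 2  # stagger ACC against GPS cycle
            for tb in range(offs, T, sch.acc_cycle_s):
                b = beh[tb]
                samples = _acc_burst(rng, b, sch)
                acc_meta.append({
                    "individual_id": bird_id,
                    "timestamp": t0 + pd.Timedelta(seconds=int(tb)),
                    "x_true": xs[tb], "y_true": ys[tb],
                    "truth_behaviour": b,
                    "truth_activity": ("flapping" if b == "flapping" else
                                       "gliding" if b == "gliding" else "soaring"),
                })
                acc_samples.append(samples)

    fixes = pd.concat(fix_rows, ignore_index=True)
    acc = pd.DataFrame(acc_meta)
    acc["samples"] = acc_samples
    acc["sampling_rate_hz"] = sch.acc_rate_hz
    truth = SimulationTruth(
        fix_labels=fixes["truth_behaviour"].copy(),
        burst_labels=acc["truth_activity"].copy(),
        decisions=pd.DataFrame(decisions,
                               columns=["row", "col", "p_uplift", "soared"]),
        coefficients={
            "p_intercept": land.config.p_intercept,
            "coef_roughness": land.config.coef_roughness,
            "coef_dem": land.config.coef_dem,
            "coef_ndvi": land.config.coef_ndvi,
            "w_lat_coef": land.config.w_lat_coef,
            "odba_suitability_slope_sign": -1.0,
        })
    return fixes, acc, truth


def _bout(parts, t, x, y, alt, heading, dhead, speed, vs, label,
          margin, xmax, ymax):
    """Generate one whole 1 Hz bout and append it to ``parts``.

    Boundaries are reflective: the unfolded path is folded back into the
    domain with a triangle-wave map, which is equivalent to reflecting the
    heading at the walls for a continuous path.  Returns the updated
    ``(x, y, alt, t, heading)`` state at the end of the bout.
    """
    n = len(dhead)
    if n == 0:
        return x, y, alt, t, heading
    head = (heading + np.cumsum(dhead)) % 360
    rad = np.deg2rad(head)
    px = _reflect(x + speed * np.cumsum(np.sin(rad)), margin, xmax - margin)
    py = _reflect(y - speed * np.cumsum(np.cos(rad)), margin, ymax - margin)
    pa = alt + np.cumsum(vs)
    parts.append((px, py, pa, label))
    return (float(px[-1]), float(py[-1]), float(pa[-1]), t + n,
            float(head[-1]))


def _ar1_noise(rng, n, sigma, rho, n_series):
    out = np.empty((n_series, n))
    innov = rng.normal(0, sigma * np.sqrt(1 - rho ** 2), (n_series, n))
    out[:, 0] = rng.normal(0, sigma, n_series)
    for i in range(1, n):
        out[:, i] = rho * out[:, i - 1] + innov[:, i]
    return out


def _acc_burst(rng, behaviour, sch: ScheduleConfig) -> np.ndarray:
    """(3, 40) raw tri-axial burst in g; z carries gravity plus dynamics."""
    n = sch.acc_n_samples
    tt = np.arange(n) / sch.acc_rate_hz
    static = np.array([rng.normal(0, 0.05), rng.normal(0, 0.05), 1.0])
    s = np.tile(static[:, None], (1, n))
    if behaviour == "flapping":
        phase = rng.uniform(0, 2 * np.pi)
        wing = sch.flap_amp * np.sin(2 * np.pi * sch.flap_freq_hz * tt + phase)
        s[2] += wing
        s[0] += 0.3 * sch.flap_amp * np.sin(
            2 * np.pi * sch.flap_freq_hz * tt + phase + rng.uniform(0, 1))
        s[1] += rng.normal(0, 0.3 * sch.flap_amp, n)
    elif behaviour == "gliding":
        s += rng.normal(0, sch.glide_amp, (3, n))
    else:  # circular or linear soaring
        s += rng.normal(0, sch.soar_amp, (3, n))
    s += rng.normal(0, sch.acc_noise, (3, n))
    return s


# ---------------------------------------------------------------------------
# lightweight record-level generators for model-recovery tests
# ---------------------------------------------------------------------------

def make_energy_records(seed: int, n_individuals: int = 59,
                        n_records: int = 800, slope: float = -0.67,
                        intercept: float = 1.6, sd_individual: float = 0.1,
                        sd_resid: float = 0.15) -> pd.DataFrame:
    """Daily energy/suitability records with a planted linear relationship.

    sqrt(daily ODBA) = intercept + slope * suitability + individual effect
    + residual; the default slope is negative (uplift availability lowers
    flight cost).
    """
    rng = np.random.default_rng(seed)
    ind = rng.integers(0, n_individuals, n_records)
    b = rng.normal(0, sd_individual, n_individuals)
    suit = rng.uniform(0.05, 0.95, n_records)
    sqrt_odba = intercept + slope * suit + b[ind] + rng.normal(0, sd_resid, n_records)
    sqrt_odba = np.clip(sqrt_odba, 0.05, None)
    dates = pd.Timestamp("2014-08-15") + pd.to_timedelta(
        rng.integers(0, 45, n_records), unit="D")
    return pd.DataFrame({
        "individual_id": [f"stork{i + 1:03d}" for i in ind],
        "date": dates,
        "mean_daily_odba": sqrt_odba ** 2,
        "mean_daily_suitability": suit,
        "n_obs": rng.integers(5, 25, n_records),
    })


def sample_intensity_cells(landscape: SimulatedLandscape, seed: int,
                           n_cells: int = 4000, noise_sd: float = 0.25,
                           visit_bias: bool = True) -> pd.DataFrame:
    """Grid cells with observed mean positive vertical speed drawn around the
    planted intensity surface.

    Emulates what gridding real bursts produces, at a fraction of the cost of
    a full track simulation; cells are sampled preferentially where uplift is
    likely when ``visit_bias`` is set (soaring happens where uplift is).
    """
    rng = np.random.default_rng(seed)
    land = landscape
    p = land.p_uplift.data.ravel()
    w = land.w_uplift.data.ravel()
    ok = np.where(w > 0)[0]
    weights = p[ok] + 0.05 if visit_bias else np.ones(ok.size)
    weights = weights / weights.sum()
    idx = rng.choice(ok, size=min(n_cells, ok.size), replace=False, p=weights)
    nr, nc = land.dem.shape
    rows, cols = np.unravel_index(idx, (nr, nc))
    cell = land.dem.cellsize
    xs = land.dem.x0 + (cols + 0.5) * cell
    ys = land.dem.y0 + (rows + 0.5) * cell
    n_fix = rng.integers(3, 40, idx.size)
    obs = w[idx] * np.exp(rng.normal(0, noise_sd / np.sqrt(n_fix / 10.0)))
    return pd.DataFrame({
        "row": rows, "col": cols, "x": xs, "y": ys,
        "mean_vspeed": obs, "n": n_fix,
    })
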