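"""Synthetic captive sessions and wild deployments.

The pipeline is trained on labelled captive sessions and applied to
unlabelled wild deployments.  This module generates both with the
statistical structure the downstream stages assume, so every stage can
be exercised end-to-end without access to field data.

Captive sessions are a semi-Markov behaviour process: behaviours occur
in runs with behaviour-specific dwell times (resting long and quiet,
travelling rhythmic stroking, grooming irregular mid-amplitude flipper
work, foraging short high-amplitude lunges).  The acceleration signal is
a slowly rotating unit-norm gravity vector plus a behaviour-specific
dynamic component, clipped to the +/- 8 g device range.

Wild deployments alternate haul-out blocks (dry, depth 0) with at-sea
trips containing dive cycles (descent / bottom / ascent to drawn maximum
depths) and surface intervals.  Optional depth-sensor drift can be
injected to exercise zero-offset correction, and 20 Hz burst segments
are emitted while the animal is deeper than 1.5 m (continuing a
configurable lag past surfacing).

All randomness flows from a single ``numpy.random.Generator`` seeded
explicitly; identical seeds give bitwise-identical output.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    ACCEL_RANGE_G,
    BEHAVIOURS,
    LOCATIONS,
    AnimalMeta,
    LabelTrack,
    SensorTrace,
)

# ---------------------------------------------------------------------------
# Behaviour signal model
# ---------------------------------------------------------------------------

#: Mean dwell time (s) per behaviour for the semi-Markov run process.
DWELL_MEAN_S = {
    "foraging": 25.0,
    "travelling": 120.0,
    "grooming": 60.0,
    "resting": 240.0,
}

#: Dynamic-component amplitude scale (g) per behaviour.  Chosen so the
#: four behaviours are separable in (VeDBA, q-variability) space while
#: overlapping enough that classification is non-trivial.
AMPLITUDE_G = {
    "foraging": 0.85,
    "travelling": 0.35,
    "grooming": 0.15,
    "resting": 0.02,
}

#: Where each behaviour tends to happen in a captive pool with haul-out
#: access (land, surface, underwater).
LOCATION_PROBS = {
    "foraging": (0.00, 0.35, 0.65),
    "travelling": (0.05, 0.50, 0.45),
    "grooming": (0.30, 0.60, 0.10),
    "resting": (0.70, 0.25, 0.05),
}

#: Captive pools are shallow; "underwater" means at most this depth (m).
CAPTIVE_MAX_DEPTH_M = 3.0


def _draw_dwell(rng: np.random.Generator, behaviour: str) -> int:
    """Behaviour-specific dwell draw, at least 1 s.

    Foraging uses a geometric (short, memoryless lunges); the sedate
    behaviours use log-normal dwells with sigma 0.6.
    """
    mean = DWELL_MEAN_S[behaviour]
    if behaviour == "foraging":
        return int(rng.geometric(1.0 / mean))
    sigma = 0.6
    mu = np.log(mean) - sigma**2 / 2.0
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _behaviour_runs(
    rng: np.random.Generator, duration_s: int, mix: np.ndarray
) -> list[tuple[str, int]]:
    """Run-length plan whose time shares track ``mix`` closely.

    Behaviours are drawn with probability proportional to the remaining
    time quota of each category and dwells are truncated by that quota,
    so empirical proportions converge on the requested mix.
    """
    quota = mix * duration_s
    runs: list[tuple[str, int]] = []
    remaining = duration_s
    last = None
    while remaining > 0:
        active = np.maximum(quota, 0.0)
        if active.sum() <= 0:
            active = mix.copy()
        p = active / active.sum()
        b = BEHAVIOURS[rng.choice(len(BEHAVIOURS), p=p)]
        dwell = min(_draw_dwell(rng, b), remaining)
        if quota[BEHAVIOURS.index(b)] > 0:
            dwell = min(dwell, max(1, int(np.ceil(quota[BEHAVIOURS.index(b)]))))
        quota[BEHAVIOURS.index(b)] -= dwell
        remaining -= dwell
        if last is not None and last[0] == b:
            runs[-1] = (b, last[1] + dwell)
            last = runs[-1]
        else:
            runs.append((b, dwell))
            last = runs[-1]
    return runs


def _gravity_track(rng: np.random.Generator, n: int, rate_hz: int) -> np.ndarray:
    """Slowly rotating unit-norm gravity vector, (n, 3)."""
    # Random-walk the spherical angles with small per-second steps.
    step = 0.02 / rate_hz
    theta = np.cumsum(rng.normal(0.0, step, n))
    phi = np.cumsum(rng.normal(0.0, step, n)) + np.pi / 2  # start roughly z-up
    g = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return g


def _dynamic_component(
    rng: np.random.Generator, behaviour: str, n: int, rate_hz: int, t0: float
) -> np.ndarray:
    """Behaviour-specific dynamic acceleration, (n, 3) in g."""
    amp = AMPLITUDE_G[behaviour]
    t = t0 + np.arange(n) / rate_hz
    if behaviour == "travelling":
        # Periodic fore-flipper stroking at 1-2 Hz plus phase jitter.
        f = rng.uniform(1.0, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        stroke = amp * np.sin(2 * np.pi * f * t + phase)
        dyn = np.column_stack(
            [
                stroke + rng.normal(0, 0.05, n),
                0.4 * stroke + rng.normal(0, 0.05, n),
                0.6 * amp * np.sin(2 * np.pi * f * t + phase + 0.8)
                + rng.normal(0, 0.05, n),
            ]
        )
    elif behaviour == "foraging":
        # Short high-amplitude lunges: bursty envelope times white noise.
        envelope = (rng.random(n) < 0.45).astype(float)
        # smear bursts over ~1 s so they have width at 20 Hz
        if rate_hz > 1:
            kernel = np.ones(rate_hz) / rate_hz
            envelope = np.convolve(envelope, kernel, mode="same")
        dyn = amp * envelope[:, None] * rng.normal(0, 1.0, (n, 3))
        dyn += rng.normal(0, 0.08, (n, 3))
    elif behaviour == "grooming":
        # Irregular mid-amplitude flipper rubbing: on/off bouts of noise.
        gate = (rng.random(n) < 0.6).astype(float)
        dyn = amp * gate[:, None] * rng.normal(0, 1.0, (n, 3))
        dyn += rng.normal(0, 0.03, (n, 3))
    else:  # resting
        dyn = rng.normal(0, amp, (n, 3))
    return dyn


# ---------------------------------------------------------------------------
# Captive sessions
# ---------------------------------------------------------------------------


def generate_captive_session(
    seed: int,
    duration_s: int,
    behaviour_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    rate_hz: int = 1,
    animal: Optional[AnimalMeta] = None,
    water_temp_c: float = 16.0,
) -> tuple[SensorTrace, LabelTrack]:
    """Generate one labelled captive training session.

    Parameters
    ----------
    seed : int
        Seed for the session's private random generator.
    duration_s : int
        Session length in seconds (>= 60).
    behaviour_mix : sequence of 4 floats
        Target time proportions for (foraging, travelling, grooming,
        resting); must sum to 1.  Empirical proportions land within a
        few percentage points for sessions of an hour or more.
    rate_hz : {1, 20}
        Acceleration sampling rate.
    """
    mix = np.asarray(behaviour_mix, dtype=float)
    if mix.shape != (4,):
        raise ValueError("behaviour_mix must have exactly 4 entries")
    if np.any(mix < 0):
        raise ValueError("behaviour_mix proportions must be non-negative")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"behaviour_mix must sum to 1, got {mix.sum()!r}")
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60")
    if rate_hz not in (1, 20):
        raise ValueError(f"unsupported rate_hz {rate_hz}; must be 1 or 20")

    rng = np.random.default_rng(seed)
    if animal is None:
        animal = AnimalMeta()

    runs = _behaviour_runs(rng, duration_s, mix)

    behaviour = np.empty(duration_s, dtype=object)
    location = np.empty(duration_s, dtype=object)
    n_acc = duration_s * rate_hz
    dyn = np.empty((n_acc, 3))
    depth = np.zeros(duration_s)

    pos = 0
    for b, dwell in runs:
        loc = LOCATIONS[rng.choice(3, p=LOCATION_PROBS[b])]
        behaviour[pos : pos + dwell] = b
        location[pos : pos + dwell] = loc
        a0, a1 = pos * rate_hz, (pos + dwell) * rate_hz
        dyn[a0:a1] = _dynamic_component(rng, b, a1 - a0, rate_hz, float(pos))
        if loc == "underwater":
            d_max = rng.uniform(1.2, CAPTIVE_MAX_DEPTH_M)
            # smooth in-out excursion over the dwell
            x = np.linspace(0, np.pi, dwell)
            depth[pos : pos + dwell] = d_max * np.sin(x) ** 0.5
        pos += dwell

    gravity = _gravity_track(rng, n_acc, rate_hz)
    accel = np.clip(gravity + dyn, -ACCEL_RANGE_G, ACCEL_RANGE_G)

    wet = location != "land"
    depth[~wet] = 0.0
    n_temp = duration_s // 2
    temp_base = np.where(wet[: 2 * n_temp : 2], water_temp_c, water_temp_c + 4.0)
    temperature = temp_base + rng.normal(0, 0.1, n_temp)

    trace = SensorTrace(
        accel=accel,
        wet=wet.astype(bool),
        depth=depth,
        temperature=temperature,
        rate_hz=rate_hz,
        animal=animal,
    )
    return trace, LabelTrack(behaviour=behaviour, location=location)


# ---------------------------------------------------------------------------
# Wild deployments
# ---------------------------------------------------------------------------


@dataclass
class WildConfig:
    """Tunables for the wild-deployment generator.

    Defaults emulate juvenile fur seal deployments: multi-hour haul-outs
    alternating with foraging trips whose dives reach a mean maximum
    depth of ~10-20 m, with 20 Hz bursts triggered below 1.5 m that
    continue ``burst_lag_s`` past surfacing.
    """

    at_sea_fraction: float = 0.55
    haulout_mean_s: float = 5 * 3600.0
    trip_mean_s: float = 6 * 3600.0
    dive_depth_median_m: float = 12.0
    dive_depth_sigma: float = 0.45
    dive_min_depth_m: float = 5.0
    descent_rate_m_s: float = 1.0
    ascent_rate_m_s: float = 0.8
    bottom_frac: tuple[float, float] = (0.3, 0.6)
    surface_interval_s: tuple[float, float] = (60.0, 240.0)
    burst_trigger_depth_m: float = 1.5
    burst_lag_s: int = 30
    water_temp_c: dict = field(
        default_factory=lambda: {"winter": 14.0, "summer": 18.0}
    )
    land_temp_c: dict = field(
        default_factory=lambda: {"winter": 10.0, "summer": 22.0}
    )


def _block_plan(
    rng: np.random.Generator, total_s: int, cfg: WildConfig
) -> list[tuple[str, int]]:
    """Alternating (haulout | trip, duration) blocks covering total_s."""
    if cfg.at_sea_fraction <= 0.0:
        return [("haulout", total_s)]
    if cfg.at_sea_fraction >= 1.0:
        return [("trip", total_s)]
    blocks: list[tuple[str, int]] = []
    kind = "haulout" if rng.random() < (1 - cfg.at_sea_fraction) else "trip"
    remaining = total_s
    while remaining > 0:
        if kind == "haulout":
            mean = cfg.haulout_mean_s * (1 - cfg.at_sea_fraction) / 0.5
        else:
            mean = cfg.trip_mean_s * cfg.at_sea_fraction / 0.5
        dur = max(600, int(rng.lognormal(np.log(mean) - 0.08, 0.4)))
        dur = min(dur, remaining)
        blocks.append((kind, dur))
        remaining -= dur
        kind = "trip" if kind == "haulout" else "haulout"
    return blocks


def _trip_depth_profile(
    rng: np.random.Generator, dur: int, cfg: WildConfig
) -> np.ndarray:
    """Depth series (1 Hz) for one at-sea trip: surface intervals + dives."""
    depth = np.zeros(dur)
    t = int(rng.uniform(*cfg.surface_interval_s))
    while t < dur:
        d_max = rng.lognormal(np.log(cfg.dive_depth_median_m), cfg.dive_depth_sigma)
        d_max = min(d_max, 80.0)
        desc = max(2, int(d_max / cfg.descent_rate_m_s))
        asc = max(2, int(d_max / cfg.ascent_rate_m_s))
        bott = max(2, int(rng.uniform(*cfg.bottom_frac) * (desc + asc)))
        total = desc + bott + asc
        if t + total >= dur:
            break
        prof = np.concatenate(
            [
                np.linspace(0, d_max, desc, endpoint=False),
                np.full(bott, d_max) + rng.normal(0, 0.2, bott),
                np.linspace(d_max, 0, asc, endpoint=False),
            ]
        )
        depth[t : t + total] = np.maximum(prof, 0.0)
        t += total + int(rng.uniform(*cfg.surface_interval_s))
    return depth


def _wild_behaviour_for_second(
    rng: np.random.Generator, block: str, depth: np.ndarray
) -> np.ndarray:
    """Latent per-second behaviour used only to synthesise acceleration."""
    n = len(depth)
    beh = np.empty(n, dtype=object)
    if block == "haulout":
        # mostly resting, occasional grooming bouts, brief travelling
        u = rng.random(n)
        beh[:] = "resting"
        beh[u < 0.12] = "grooming"
        beh[u < 0.02] = "travelling"
        return beh
    ddt = np.gradient(depth)
    beh[:] = "travelling"
    beh[(depth > 1.0) & (np.abs(ddt) < 0.2)] = "foraging"  # bottom phase
    beh[(depth > 1.0) & (ddt < -0.2)] = "resting"  # buoyant glide up
    surface = depth <= 1.0
    u = rng.random(n)
    beh[surface & (u < 0.45)] = "grooming"
    beh[surface & (u >= 0.45) & (u < 0.70)] = "resting"
    return beh


def generate_wild_deployment(
    seed: int,
    n_days: int,
    mass_kg: float = 30.0,
    season: str = "winter",
    config: Optional[WildConfig] = None,
    depth_drift: Optional[np.ndarray | float] = None,
    include_bursts: bool = False,
) -> SensorTrace:
    """Generate an unlabelled wild-style deployment of ``n_days`` days.

    ``depth_drift`` (scalar or per-second array, metres) is added to the
    recorded depth channel to emulate pressure-sensor drift; downstream
    zero-offset correction should remove it.  When ``include_bursts`` is
    true, 20 Hz acceleration segments are attached (``trace.bursts``)
    for every interval deeper than the burst trigger, extended
    ``burst_lag_s`` past surfacing.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cfg = config or WildConfig()
    rng = np.random.default_rng(seed)
    total_s = int(n_days * 86400)

    animal = AnimalMeta(mass_kg=mass_kg, season=season)
    blocks = _block_plan(rng, total_s, cfg)

    depth = np.zeros(total_s)
    wet = np.zeros(total_s, dtype=bool)
    block_of = np.empty(total_s, dtype=object)
    pos = 0
    for kind, dur in blocks:
        block_of[pos : pos + dur] = kind
        if kind == "trip":
            wet[pos : pos + dur] = True
            depth[pos : pos + dur] = _trip_depth_profile(rng, dur, cfg)
        pos += dur

    beh = np.empty(total_s, dtype=object)
    pos = 0
    for kind, dur in blocks:
        beh[pos : pos + dur] = _wild_behaviour_for_second(
            rng, kind, depth[pos : pos + dur]
        )
        pos += dur

    # acceleration at 1 Hz: gravity + behaviour-specific dynamics in runs
    gravity = _gravity_track(rng, total_s, 1)
    dyn = np.empty((total_s, 3))
    i = 0
    while i < total_s:
        j = i + 1
        while j < total_s and beh[j] == beh[i]:
            j += 1
        dyn[i:j] = _dynamic_component(rng, beh[i], j - i, 1, float(i))
        i = j
    accel = np.clip(gravity + dyn, -ACCEL_RANGE_G, ACCEL_RANGE_G)

    recorded_depth = depth.copy()
    if depth_drift is not None:
        recorded_depth = recorded_depth + np.asarray(depth_drift, dtype=float)

    n_temp = total_s // 2
    wt = cfg.water_temp_c[season]
    lt = cfg.land_temp_c[season]
    temp_base = np.where(wet[: 2 * n_temp : 2], wt, lt)
    temperature = temp_base + rng.normal(0, 0.15, n_temp)

    bursts = None
    if include_bursts:
        bursts = _burst_segments(rng, depth, beh, animal, cfg)

    return SensorTrace(
        accel=accel,
        wet=wet,
        depth=recorded_depth,
        temperature=temperature,
        rate_hz=1,
        animal=animal,
        bursts=bursts,
    )


def _burst_segments(
    rng: np.random.Generator,
    depth: np.ndarray,
    beh: np.ndarray,
    animal: AnimalMeta,
    cfg: WildConfig,
) -> list[SensorTrace]:
    """20 Hz segments while depth > trigger, extended by the burst lag."""
    deep = depth > cfg.burst_trigger_depth_m
    active = deep.copy()
    # extend each deep interval by burst_lag_s
    idx = np.flatnonzero(deep)
    for k in idx:
        active[k : k + cfg.burst_lag_s + 1] = True
    segments: list[SensorTrace] = []
    i = 0
    n = len(depth)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        dur = j - i
        n_acc = dur * 20
        g = _gravity_track(rng, n_acc, 20)
        dyn = np.empty((n_acc, 3))
        p = i
        while p < j:
            q = p + 1
            while q < j and beh[q] == beh[p]:
                q += 1
            dyn[(p - i) * 20 : (q - i) * 20] = _dynamic_component(
                rng, beh[p], (q - p) * 20, 20, float(p)
            )
            p = q
        seg = SensorTrace(
            accel=np.clip(g + dyn, -ACCEL_RANGE_G, ACCEL_RANGE_G),
            wet=np.ones(dur, dtype=bool),
            depth=depth[i:j],
            temperature=np.full(dur // 2, cfg.water_temp_c[animal.season]),
            rate_hz=20,
            animal=animal,
            start_s=float(i),
        )
        segments.append(seg)
        i = j
    return segments


# ---------------------------------------------------------------------------
# Delimited-text writers (the dialects the pipeline readers consume)
# ---------------------------------------------------------------------------


def write_session(
    directory: str, trace: SensorTrace, labels: Optional[LabelTrack] = None
) -> None:
    """Write one session as accel.csv, env.csv, meta.txt (+ labels.csv)."""
    os.makedirs(directory, exist_ok=True)
    t_acc = trace.times_s
    with open(os.path.join(directory, "accel.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "x", "y", "z"])
        for t, (x, y, z) in zip(t_acc, trace.accel):
            w.writerow([f"{t:.3f}", f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])
    with open(os.path.join(directory, "env.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "wet", "depth_m", "temp_c"])
        for s in range(trace.duration_s):
            temp = trace.temperature[s // 2] if s // 2 < len(trace.temperature) else ""
            w.writerow(
                [s, int(trace.wet[s]), f"{trace.depth[s]:.3f}",
                 f"{temp:.2f}" if temp != "" else ""]
            )
    if labels is not None:
        with open(os.path.join(directory, "labels.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "behaviour", "location"])
            for s in range(len(labels)):
                w.writerow([s, labels.behaviour[s], labels.location[s]])
    a = trace.animal
    with open(os.path.join(directory, "meta.txt"), "w") as fh:
        for k, v in [
            ("mass_kg", a.mass_kg), ("sex", a.sex), ("age_class", a.age_class),
            ("species", a.species), ("attachment", a.attachment),
            ("season", a.season), ("colony", a.colony),
            ("rate_hz", trace.rate_hz),
        ]:
            fh.write(f"{k}:{v}\n")


def read_session(directory: str) -> tuple[SensorTrace, Optional[LabelTrack]]:
    """Read a session written by :func:`write_session`."""
    import pandas as pd

    meta: dict[str, str] = {}
    with open(os.path.join(directory, "meta.txt")) as fh:
        for line in fh:
            k, _, v = line.strip().partition(":")
            meta[k] = v
    animal = AnimalMeta(
        mass_kg=float(meta["mass_kg"]), sex=meta["sex"],
        age_class=meta["age_class"], species=meta["species"],
        attachment=meta["attachment"], season=meta["season"],
        colony=meta.get("colony", ""),
    )
    rate_hz = int(meta["rate_hz"])
    acc = pd.read_csv(os.path.join(directory, "accel.csv"))
    env = pd.read_csv(os.path.join(directory, "env.csv"))
    temperature = env["temp_c"].to_numpy()[::2]
    temperature = temperature[~np.isnan(temperature)]
    trace = SensorTrace(
        accel=acc[["x", "y", "z"]].to_numpy(),
        wet=env["wet"].to_numpy().astype(bool),
        depth=env["depth_m"].to_numpy(),
        temperature=temperature,
        rate_hz=rate_hz,
        animal=animal,
    )
    labels = None
    lab_path = os.path.join(directory, "labels.csv")
    if os.path.exists(lab_path):
        lab = pd.read_csv(lab_path)
        labels = LabelTrack(
            behaviour=lab["behaviour"].to_numpy(),
            location=lab["location"].to_numpy(),
        )
    return trace, labels
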