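"""Epoch-windowed feature extraction from tri-axial acceleration.

The classifier consumes fixed-length, non-overlapping windows (epochs)
of acceleration samples summarised by 52 numeric statistics: eleven
moments/shape statistics per axis, the magnitude statistic q, pairwise
axis correlations, posture angles (inclination and azimuth of the
static vector), and the dynamic-body-acceleration family derived by
splitting each axis into a static (3-s running mean, gravity/posture)
and dynamic (residual) component:

    PDBA_i = raw_i - static_i          (per axis)
    ODBA   = |PDBA_x| + |PDBA_y| + |PDBA_z|
    VeDBA  = sqrt(PDBA_x^2 + PDBA_y^2 + PDBA_z^2)

so that sample-wise VeDBA <= ODBA <= sqrt(3) * VeDBA.

Also here: zero-offset correction for pressure-sensor drift in the
depth channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import LOCATIONS, LabelTrack, SensorTrace

#: Covariate columns appended after the numeric features.
COVARIATE_COLUMNS = ("attachment", "age_class", "mass_kg", "sex", "species")

VALID_EPOCHS = {1: (7, 15, 21), 20: (13, 25, 75)}


@dataclass(frozen=True)
class EpochConfig:
    """Epoching parameters.

    ``epoch_samples`` follows the tested designs: 7/15/21 samples at
    1 Hz, 13/25/75 samples at 20 Hz (other values are accepted but
    warned about).  ``dba_window_s`` is the running-mean span used for
    the static component, default 3 s.
    """

    rate_hz: int = 1
    epoch_samples: int = 21
    dba_window_s: float = 3.0

    def __post_init__(self) -> None:
        if self.rate_hz not in (1, 20):
            raise ValueError(f"rate_hz must be 1 or 20, got {self.rate_hz}")
        if self.epoch_samples < 2:
            raise ValueError("epoch_samples must be >= 2")
        if self.dba_window_s <= 0:
            raise ValueError("dba_window_s must be positive")
        if self.epoch_samples not in VALID_EPOCHS[self.rate_hz]:
            warnings.warn(
                f"epoch_samples={self.epoch_samples} is outside the tested "
                f"designs {VALID_EPOCHS[self.rate_hz]} for {self.rate_hz} Hz",
                stacklevel=2,
            )

    @property
    def epoch_s(self) -> float:
        return self.epoch_samples / self.rate_hz


def _per_axis_names(stat: str) -> list[str]:
    return [f"{stat}_{ax}" for ax in "xyz"]


#: The fixed 52-entry numeric feature registry, in column order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    name
    for stat in (
        "mean", "median", "sd", "skew", "kurt", "min", "max",
        "meanabs", "invcov", "autocorr1", "trend",
    )
    for name in _per_axis_names(stat)
) + (
    "q_mean", "q_sd",
    "corr_xy", "corr_yz", "corr_xz",
    "inclination", "azimuth",
    "odba_mean", "odba_sd", "odba_integral",
    "vedba_mean", "vedba_sd", "vedba_integral",
    "static_mean_x", "static_mean_y", "static_mean_z",
    "pdba_meanabs_x", "pdba_meanabs_y", "pdba_meanabs_z",
)

assert len(FEATURE_NAMES) == 52


# ---------------------------------------------------------------------------
# Depth zero-offset correction
# ---------------------------------------------------------------------------


def zero_offset_correct(
    depth: np.ndarray,
    wet: Optional[np.ndarray] = None,
    window_s: int = 900,
    shallow_m: float = 2.5,
    quantile: float = 0.05,
) -> np.ndarray:
    """Remove pressure-sensor drift from a 1 Hz depth series.

    The surface baseline at each second is the rolling ``quantile`` of
    readings shallower than ``shallow_m`` within a centred ``window_s``
    window; it is subtracted and the result clipped at zero.  Seconds
    flagged dry (``wet`` false) are forced to exactly 0.  A drift-free
    series whose surface sits at 0 is returned unchanged.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth series")
    s = pd.Series(depth).where(depth < shallow_m)
    base = s.rolling(window_s, center=True, min_periods=1).quantile(quantile)
    base = base.interpolate(limit_direction="both").fillna(0.0).to_numpy()
    corrected = np.clip(depth - base, 0.0, None)
    if wet is not None:
        wet = np.asarray(wet, dtype=bool)
        if len(wet) != len(depth):
            raise ValueError("wet and depth must have equal length")
        corrected[~wet] = 0.0
    return corrected


# ---------------------------------------------------------------------------
# Dynamic body acceleration
# ---------------------------------------------------------------------------


def dba_from_pdba(pdba: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ODBA (L1 norm) and VeDBA (L2 norm) of a dynamic component."""
    pdba = np.asarray(pdba, dtype=float)
    odba = np.abs(pdba).sum(axis=-1)
    vedba = np.sqrt((pdba**2).sum(axis=-1))
    return odba, vedba


def decompose_dba(
    accel: np.ndarray, rate_hz: int, window_s: float = 3.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split acceleration into static and dynamic components.

    static  = centred running mean over ``window_s`` per axis, with
              shrunken (not reflected) windows at the edges;
    pdba    = raw - static, exactly (raw reconstructs to machine
              precision from static + pdba);
    odba    = |pdba_x| + |pdba_y| + |pdba_z|;
    vedba   = sqrt(pdba_x^2 + pdba_y^2 + pdba_z^2).
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError("accel must be an (n, 3) array")
    if len(accel) < 2:
        raise ValueError("need at least 2 samples")
    window = max(1, int(round(window_s * rate_hz)))
    static = (
        pd.DataFrame(accel)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    pdba = accel - static
    odba, vedba = dba_from_pdba(pdba)
    return static, pdba, odba, vedba


# ---------------------------------------------------------------------------
# Epoch summary statistics
# ---------------------------------------------------------------------------


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; 0 when either side is constant."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def _majority(labels: np.ndarray) -> str:
    """Majority vote; ties broken by earliest occurrence in the window."""
    values, first_pos, counts = np.unique(
        labels, return_index=True, return_counts=True
    )
    best = counts.max()
    tied = counts == best
    return str(values[tied][np.argmin(first_pos[tied])])


def epoch_features(
    trace: SensorTrace,
    labels: Optional[LabelTrack] = None,
    cfg: EpochConfig = EpochConfig(),
    location: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Summarise a trace into per-epoch feature rows.

    Windows are consecutive and non-overlapping; a trailing partial
    window is dropped.  Per-epoch label and location (when available)
    are the majority per-second values within the window, ties broken
    by the earliest-occurring value.  ``location`` overrides the
    labels' location track (used for wild data, where location comes
    from the wet/dry switch and depth).

    Returns a DataFrame with epoch_index, start_s, end_s, the 52
    numeric features, the animal covariates, location and (when labels
    are given) the true behaviour label.
    """
    if trace.rate_hz != cfg.rate_hz:
        raise ValueError(
            f"trace rate {trace.rate_hz} Hz != config rate {cfg.rate_hz} Hz"
        )
    m = cfg.epoch_samples
    n = len(trace.accel)
    n_epochs = n // m
    if n_epochs == 0:
        warnings.warn("trace shorter than one epoch; returning empty frame")
        return _empty_frame(labels is not None)

    static, pdba, odba, vedba = decompose_dba(
        trace.accel, cfg.rate_hz, cfg.dba_window_s
    )

    def win(x: np.ndarray) -> np.ndarray:
        return x[: n_epochs * m].reshape(n_epochs, m, *x.shape[1:])

    aw = win(trace.accel)  # (E, m, 3)
    sw = win(static)
    pw = win(pdba)
    ow = win(odba)  # (E, m)
    vw = win(vedba)

    cols: dict[str, np.ndarray] = {}
    # exact constant-epoch detection drives the degenerate conventions
    # (summation residue can make the sd of a constant epoch ~1e-17)
    degen = (aw == aw[:, :1, :]).all(axis=1)
    sd = np.where(degen, 0.0, aw.std(axis=1, ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = np.where(degen, 0.0, stats.skew(aw, axis=1, bias=False))
        kurt = np.where(degen, 0.0, stats.kurtosis(aw, axis=1, bias=False))
    skew = np.nan_to_num(skew)
    kurt = np.nan_to_num(kurt)
    var = aw.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        invcov = np.where(degen, 0.0, 1.0 / np.where(var > 0, var, 1.0))
    # lag-1 autocorrelation per axis
    ac = np.where(
        degen,
        0.0,
        np.stack(
            [_safe_corr(aw[:, :-1, k], aw[:, 1:, k]) for k in range(3)], axis=1
        ),
    )
    # OLS slope of value vs sample index; exactly 0 for constant epochs
    t = np.arange(m) - (m - 1) / 2.0
    trend = np.where(
        degen, 0.0, (aw * t[None, :, None]).sum(axis=1) / (t**2).sum()
    )

    per_axis = {
        "mean": aw.mean(axis=1),
        "median": np.median(aw, axis=1),
        "sd": sd,
        "skew": skew,
        "kurt": kurt,
        "min": aw.min(axis=1),
        "max": aw.max(axis=1),
        "meanabs": np.abs(aw).mean(axis=1),
        "invcov": invcov,
        "autocorr1": ac,
        "trend": trend,
    }
    for stat, arr in per_axis.items():
        for k, ax in enumerate("xyz"):
            cols[f"{stat}_{ax}"] = arr[:, k]

    q = np.sqrt((aw**2).sum(axis=2))  # (E, m)
    q_degen = (q == q[:, :1]).all(axis=1)
    cols["q_mean"] = q.mean(axis=1)
    cols["q_sd"] = np.where(q_degen, 0.0, q.std(axis=1, ddof=1))

    pair = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}
    for name, (i, j) in pair.items():
        cols[f"corr_{name}"] = np.where(
            degen[:, i] | degen[:, j],
            0.0,
            _safe_corr(aw[:, :, i], aw[:, :, j]),
        )

    # posture from the epoch-mean static vector
    sm = sw.mean(axis=1)  # (E, 3)
    cols["inclination"] = np.arctan2(
        np.sqrt(sm[:, 0] ** 2 + sm[:, 1] ** 2), sm[:, 2]
    )
    cols["azimuth"] = np.arctan2(sm[:, 1], sm[:, 0])

    dx = 1.0 / cfg.rate_hz
    cols["odba_mean"] = ow.mean(axis=1)
    cols["odba_sd"] = ow.std(axis=1, ddof=1)
    cols["odba_integral"] = np.trapezoid(ow, dx=dx, axis=1)
    cols["vedba_mean"] = vw.mean(axis=1)
    cols["vedba_sd"] = vw.std(axis=1, ddof=1)
    cols["vedba_integral"] = np.trapezoid(vw, dx=dx, axis=1)

    for k, ax in enumerate("xyz"):
        cols[f"static_mean_{ax}"] = sm[:, k]
        cols[f"pdba_meanabs_{ax}"] = np.abs(pw[:, :, k]).mean(axis=1)

    df = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    df.insert(0, "epoch_index", np.arange(n_epochs))
    starts = np.arange(n_epochs) * cfg.epoch_s
    df.insert(1, "start_s", trace.start_s + starts)
    df.insert(2, "end_s", trace.start_s + starts + cfg.epoch_s)

    a = trace.animal
    df["attachment"] = a.attachment
    df["age_class"] = a.age_class
    df["mass_kg"] = a.mass_kg
    df["sex"] = a.sex
    df["species"] = a.species

    # per-second tracks, windowed over whole seconds covered by each epoch
    sec_per_epoch = cfg.epoch_s
    loc_track = None
    if location is not None:
        loc_track = np.asarray(location, dtype=object)
    elif labels is not None:
        loc_track = labels.location
    if loc_track is not None:
        df["location"] = _window_majority(loc_track, sec_per_epoch, n_epochs)
    else:
        df["location"] = "surface"
    if labels is not None:
        df["label"] = _window_majority(labels.behaviour, sec_per_epoch, n_epochs)
    return df


def _window_majority(
    track: np.ndarray, sec_per_epoch: float, n_epochs: int
) -> list[str]:
    out = []
    for e in range(n_epochs):
        i0 = int(np.floor(e * sec_per_epoch))
        i1 = max(i0 + 1, int(np.ceil((e + 1) * sec_per_epoch)))
        out.append(_majority(track[i0 : min(i1, len(track))]))
    return out


def _empty_frame(with_label: bool) -> pd.DataFrame:
    columns = (
        ["epoch_index", "start_s", "end_s"]
        + list(FEATURE_NAMES)
        + list(COVARIATE_COLUMNS)
        + ["location"]
        + (["label"] if with_label else [])
    )
    return pd.DataFrame(columns=columns)


def write_features(df: pd.DataFrame, path: str, cfg: EpochConfig) -> None:
    """Write a feature matrix with a versioned header comment."""
    with open(path, "w") as fh:
        fh.write(
            f"# sealteb feature matrix v1; rate_hz={cfg.rate_hz} "
            f"epoch_samples={cfg.epoch_samples} n_features={len(FEATURE_NAMES)}\n"
        )
        df.to_csv(fh, index=False)


def read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
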