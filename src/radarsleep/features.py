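"""Per-epoch feature extraction: movement, HRV and RRV statistics.

Thirteen features are computed per 30 s epoch in fixed-length sliding
windows (lengths in :class:`~radarsleep.config.FeatureWindowSpec`):

* ACT — the movement value (radar movement feature or raw activity counts),
* MedianNN at 0.5 and 2.5 min, SD2/SD1 (Poincare) at 0.5 min,
* VLF / LF / HF / LF-HF ratio / total power of the NN tachogram at 2.5 min
  (bands 0.003-0.04, 0.04-0.15, 0.15-0.4 Hz),
* MedianBB, the 0.04-0.15 Hz band power of the BB tachogram, CVBB at
  2.5 min and MCVBB at 4.5 min.

The identical estimator runs on radar-derived and reference-modality
streams so that both domains share one feature schema — the precondition
for transferring a model between them.  Epochs whose core features cannot
be computed are flagged invalid, never dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .config import FeatureWindowSpec
from .dsp import BeatSeries, BreathSeries, MovementEpochSeries
from .hypnogram import EPOCH_LEN_S, Hypnogram

__all__ = [
    "FEATURE_COLUMNS",
    "HRV_BANDS",
    "median_nn",
    "sd2sd1",
    "hrv_band_powers",
    "rrv_features",
    "assemble_epoch_table",
    "reference_epoch_table",
]

#: canonical feature column order (1 movement + 8 HRV + 4 RRV)
FEATURE_COLUMNS = [
    "ACT",
    "MedianNN_short", "MedianNN_long", "SD2SD1",
    "VLF", "LF", "HF", "LFHF", "TotalPower",
    "MedianBB", "RRV_LF", "CVBB", "MCVBB",
]

#: HRV frequency bands (Hz), half-open [lo, hi)
HRV_BANDS = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

TACHOGRAM_FS_HZ = 4.0


def _intervals_in_window(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Intervals whose defining event pair ends inside [t0, t1)."""
    if len(times) < 2:
        return np.empty(0)
    iv = np.diff(times)
    ends = times[1:]
    return iv[(ends >= t0) & (ends < t1)]


def median_nn(beats: BeatSeries, window: tuple[float, float]) -> float:
    """Median NN interval (ms) in the window; NaN if fewer than 3 intervals."""
    nn = _intervals_in_window(beats.beat_times_s, *window) * 1000.0
    if len(nn) < 3:
        return float("nan")
    return float(np.median(nn))


def sd2sd1(beats: BeatSeries, window: tuple[float, float]) -> float:
    """Poincare-plot SD2/SD1 ratio of NN intervals in the window.

    SD1^2 = var(successive differences) / 2 measures short-term dispersion
    perpendicular to the identity line; SD2^2 = 2 var(NN) - var(diff)/2 the
    long-term dispersion along it.  Population variances.  NaN when fewer
    than 4 intervals or SD1 = 0 (the ratio is undefined).
    """
    nn = _intervals_in_window(beats.beat_times_s, *window) * 1000.0
    if len(nn) < 4:
        return float("nan")
    var_diff = float(np.var(np.diff(nn)))
    sd1_sq = var_diff / 2.0
    sd2_sq = max(2.0 * float(np.var(nn)) - var_diff / 2.0, 0.0)
    if sd1_sq <= 1e-10:  # constant NN up to float error: ratio undefined
        return float("nan")
    return float(np.sqrt(sd2_sq) / np.sqrt(sd1_sq))


def _resampled_tachogram(times: np.ndarray, values: np.ndarray,
                         window: tuple[float, float],
                         fs: float = TACHOGRAM_FS_HZ) -> np.ndarray | None:
    """Cubic-interpolate an interval series onto a uniform grid inside the
    window (restricted to the span the events cover)."""
    t0 = max(window[0], times[0])
    t1 = min(window[1], times[-1])
    if t1 - t0 < 2.0 / fs or len(times) < 4:
        return None
    spline = CubicSpline(times, values)
    grid = np.arange(t0, t1, 1.0 / fs)
    if len(grid) < 8:
        return None
    return np.asarray(spline(grid), dtype=float)


def _band_powers_from_series(x: np.ndarray, fs: float,
                             bands: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Single-taper (boxcar) periodogram band powers by rectangular
    integration over half-open frequency bands."""
    x = x - np.mean(x)
    n = len(x)
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # one-sided power spectral density of the boxcar periodogram
    psd = (np.abs(X) ** 2) / (fs * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    df = fs / n
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.sum(psd[sel]) * df)
    return out


def hrv_band_powers(beats: BeatSeries, window: tuple[float, float]) -> dict[str, float]:
    """Frequency-domain HRV of the NN tachogram in the window.

    The NN series (ms, indexed by the ending beat time) is resampled to a
    uniform 4 Hz grid by cubic interpolation, mean-removed, and a boxcar
    periodogram is integrated over the VLF/LF/HF bands.  Total power is the
    integral over 0.003-0.4 Hz, so it equals VLF + LF + HF exactly.  The
    LF/HF ratio is NaN when HF is zero.  All powers are NaN when the window
    holds less than 0.5 min of beats.
    """
    times = beats.beat_times_s
    nan = {k: float("nan") for k in ("VLF", "LF", "HF", "LFHF", "TotalPower")}
    if len(times) < 4:
        return nan
    t0, t1 = window
    inside = times[(times >= t0) & (times < t1)]
    if len(inside) < 4 or inside[-1] - inside[0] < 30.0:
        return nan
    nn_ms = np.diff(times) * 1000.0
    tacho = _resampled_tachogram(times[1:], nn_ms, window)
    if tacho is None:
        return nan
    powers = _band_powers_from_series(tacho, TACHOGRAM_FS_HZ, HRV_BANDS)
    total = _band_powers_from_series(tacho, TACHOGRAM_FS_HZ, {"T": (0.003, 0.4)})["T"]
    lfhf = powers["LF"] / powers["HF"] if powers["HF"] > 0 else float("nan")
    return {**powers, "LFHF": lfhf, "TotalPower": total}


def rrv_features(breaths: BreathSeries, windows: dict[str, tuple[float, float]]
                 ) -> dict[str, float]:
    """Respiration-rate-variability features.

    MedianBB = median BB interval (s); CVBB = population SD / mean;
    MCVBB = mean absolute deviation from the mean, divided by the median;
    RRV_LF = 0.04-0.15 Hz band power of the resampled BB tachogram (same
    estimator as the HRV powers).  ``windows`` maps each feature name to
    its own (start, end) window.
    """
    times = breaths.breath_times_s
    out: dict[str, float] = {}
    bb_med = _intervals_in_window(times, *windows["MedianBB"])
    out["MedianBB"] = float(np.median(bb_med)) if len(bb_med) >= 3 else float("nan")
    bb_cv = _intervals_in_window(times, *windows["CVBB"])
    if len(bb_cv) >= 3:
        out["CVBB"] = float(np.std(bb_cv) / np.mean(bb_cv))
    else:
        out["CVBB"] = float("nan")
    bb_m = _intervals_in_window(times, *windows["MCVBB"])
    if len(bb_m) >= 4:
        out["MCVBB"] = float(np.mean(np.abs(bb_m - np.mean(bb_m))) / np.median(bb_m))
    else:
        out["MCVBB"] = float("nan")
    out["RRV_LF"] = float("nan")
    bb_lf = _intervals_in_window(times, *windows["RRV_LF"])
    if len(bb_lf) >= 5 and len(times) >= 5:
        tacho = _resampled_tachogram(times[1:], np.diff(times), windows["RRV_LF"])
        if tacho is not None:
            out["RRV_LF"] = _band_powers_from_series(
                tacho, TACHOGRAM_FS_HZ, {"LF": (0.04, 0.15)})["LF"]
    return out


def assemble_epoch_table(hypnogram: Hypnogram,
                         movement: MovementEpochSeries | np.ndarray,
                         beats: BeatSeries,
                         breaths: BreathSeries,
                         spec: FeatureWindowSpec | None = None,
                         participant_id: str = "") -> pd.DataFrame:
    """One feature row per hypnogram epoch, aligned with the stage labels.

    Each feature is computed on its own sliding window anchored to the
    epoch (centered on the epoch midpoint by default); windows are
    truncated at the recording boundaries, with ``truncated`` marking such
    epochs.  ``valid`` is False when any core feature (MedianNN_long,
    MedianBB or the band powers) could not be computed; features stay NaN
    in the table rather than being dropped.
    """
    spec = spec or FeatureWindowSpec()
    n = len(hypnogram)
    dur = hypnogram.duration_s
    mov = movement.values if isinstance(movement, MovementEpochSeries) else np.asarray(movement, float)
    if abs(len(mov) - n) > 1:
        raise ValueError(
            f"movement series ({len(mov)} epochs) and hypnogram ({n}) differ by "
            "more than one epoch")
    if len(mov) != n:
        mov = np.pad(mov[:n], (0, max(0, n - len(mov))), constant_values=np.nan)
    last_event = max(
        beats.beat_times_s[-1] if len(beats) else 0.0,
        breaths.breath_times_s[-1] if len(breaths) else 0.0,
    )
    if last_event > dur + EPOCH_LEN_S:
        raise ValueError("event streams extend past the hypnogram by more than one epoch")

    rows = []
    for i in range(n):
        w_nn_s = spec.window_for("median_nn_short", i, dur)
        w_nn_l = spec.window_for("median_nn_long", i, dur)
        w_sd = spec.window_for("sd2sd1", i, dur)
        w_pow = spec.window_for("hrv_power", i, dur)
        rrv_windows = {
            "MedianBB": spec.window_for("median_bb", i, dur),
            "CVBB": spec.window_for("cvbb", i, dur),
            "MCVBB": spec.window_for("mcvbb", i, dur),
            "RRV_LF": spec.window_for("rrv_lf", i, dur),
        }
        powers = hrv_band_powers(beats, w_pow)
        rrv = rrv_features(breaths, rrv_windows)
        # widest window: if it had to be clipped, this epoch sits at a boundary
        widest = spec.mcvbb * 60.0
        if spec.anchor == "centered":
            mid = (i + 0.5) * EPOCH_LEN_S
            truncated = mid - widest / 2.0 < 0.0 or mid + widest / 2.0 > dur
        else:
            truncated = (i + 1) * EPOCH_LEN_S - widest < 0.0
        row = {
            "participant_id": participant_id,
            "epoch_index": i,
            "ACT": float(mov[i]),
            "MedianNN_short": median_nn(beats, w_nn_s),
            "MedianNN_long": median_nn(beats, w_nn_l),
            "SD2SD1": sd2sd1(beats, w_sd),
            **powers,
            **rrv,
            "stage": hypnogram.stages[i],
            "truncated": truncated,
        }
        core = (row["MedianNN_long"], row["MedianBB"], row["TotalPower"])
        row["valid"] = bool(np.all(np.isfinite(core)))
        rows.append(row)
    cols = ["participant_id", "epoch_index", *FEATURE_COLUMNS, "stage", "valid", "truncated"]
    return pd.DataFrame(rows)[cols]


def reference_epoch_table(hypnogram: Hypnogram, reference, spec: FeatureWindowSpec | None = None,
                          ) -> pd.DataFrame:
    """Feature table for a reference-modality night (clean event streams and
    per-epoch activity counts); identical schema to the radar table."""
    beats = BeatSeries(reference.beat_times_s)
    breaths = BreathSeries(reference.breath_times_s)
    counts = np.asarray(reference.activity_counts, dtype=float)
    return assemble_epoch_table(hypnogram, counts, beats, breaths, spec,
                                participant_id=reference.participant_id)
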