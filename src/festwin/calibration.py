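"""Strength-duration calibration: curve fits, relative differences, ath choice.

The evaluation pipeline compares simulated and experimental SD curves and
selects, per muscle and per pulse-width range (20-200 µs and 201-500 µs),
the activation threshold (ath) whose simulated curve deviates least from
the experimental mean.  Deviation is the mean over integer pulse widths of
the relative amplitude difference.  Muscles without their own calibration
receive the average of the calibrated ones, rounded up to two decimals —
rounding up keeps the default threshold at least as strict as the average
(and is the convention consistent with the published defaults 0.20/0.12).

SD curves are parameterized by the Weiss hyperbola A(PW) = b (1 + c / PW),
with b the rheobase-like plateau amplitude and c the chronaxie-like time
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ModelError
from .recruitment import PW_RANGE_HIGH, PW_RANGE_LOW, AthTable, SDCurve

ATH_GRID = tuple(round(0.05 * k, 2) for k in range(1, 11))   # 0.05 ... 0.50


@dataclass
class SDFit:
    """Weiss-hyperbola fit A(PW) = b (1 + c/PW)."""

    b_mA: float              # rheobase-like amplitude
    c_us: float              # chronaxie-like pulse width
    pw_range: tuple[float, float]
    rms_residual: float = float("nan")

    def __post_init__(self) -> None:
        if self.b_mA <= 0 or self.c_us < 0:
            raise ModelError("SD fit requires b > 0 and c >= 0")

    def predict(self, pw_us) -> np.ndarray:
        pw = np.asarray(pw_us, dtype=float)
        if np.any(pw < 1):
            raise ValueError("SD fit is evaluable for PW >= 1 µs")
        return self.b_mA * (1.0 + self.c_us / pw)


def _weiss(pw, b, c):
    return b * (1.0 + c / pw)


def fit_sd(pw_us: np.ndarray, amp_mA: np.ndarray) -> SDFit:
    """Least-squares Weiss fit to (pulse width, threshold amplitude) points."""
    pw = np.asarray(pw_us, dtype=float)
    amp = np.asarray(amp_mA, dtype=float)
    ok = np.isfinite(pw) & np.isfinite(amp)
    pw, amp = pw[ok], amp[ok]
    if len(np.unique(pw)) < 3:
        raise ModelError("SD fit needs >= 3 distinct pulse widths")
    p0 = (max(float(np.min(amp)), 1e-6), 100.0)
    popt, _ = curve_fit(_weiss, pw, amp, p0=p0,
                        bounds=([1e-9, 0.0], [np.inf, np.inf]), maxfev=20000)
    resid = amp - _weiss(pw, *popt)
    return SDFit(float(popt[0]), float(popt[1]),
                 (float(pw.min()), float(pw.max())),
                 float(np.sqrt(np.mean(resid ** 2))))


def _evaluable(curve, pw: np.ndarray) -> np.ndarray:
    """Amplitudes of an SDFit or SDCurve at integer pulse widths."""
    if isinstance(curve, SDFit):
        return curve.predict(pw)
    if isinstance(curve, SDCurve):
        fit = fit_sd(curve.pw_us, curve.threshold_mA)
        return fit.predict(pw)
    raise TypeError(f"cannot evaluate {type(curve).__name__} as an SD curve")


def mean_rel_diff(sim, exp, pw_range: tuple[float, float]) -> float:
    """Mean relative amplitude difference over integer pulse widths.

    mean over PW in {lo, lo+1, ..., hi} of |A_sim - A_exp| / A_exp.
    ``sim`` may be an SDFit or an SDCurve (fitted first); ``exp`` likewise.
    """
    lo, hi = pw_range
    pw = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
    a_sim = _evaluable(sim, pw)
    a_exp = _evaluable(exp, pw)
    if np.any(a_exp == 0):
        raise ModelError("experimental curve evaluates to 0 in the PW range")
    return float(np.mean(np.abs(a_sim - a_exp) / a_exp))


@dataclass
class RelDiffSummary:
    """Per-ath mean relative differences for one muscle and PW range."""

    muscle: str
    pw_range: str                    # "20-200" | "201-500"
    values: dict[float, float]       # ath -> mean relative difference

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("relative differences must be >= 0")


@dataclass
class AthSelection:
    """Best-fitting activation threshold for one muscle and PW range."""

    muscle: str
    pw_range: str
    ath: float
    value: float
    tie_break_used: bool = False


def select_ath(summary: RelDiffSummary, printed_decimals: int = 3) -> AthSelection:
    """Pick the ath with the smallest mean relative difference.

    Comparison happens first at the table's printed precision; ties there
    are broken by the full-precision values, remaining exact ties by the
    smaller ath.
    """
    if not summary.values:
        raise ValueError("empty relative-difference map")
    items = sorted(summary.values.items())
    rounded = {a: round(v, printed_decimals) for a, v in items}
    best_rounded = min(rounded.values())
    candidates = [a for a, v in items if rounded[a] == best_rounded]
    tie = len(candidates) > 1
    best_full = min(summary.values[a] for a in candidates)
    winners = [a for a in candidates if summary.values[a] == best_full]
    ath = min(winners)
    return AthSelection(summary.muscle, summary.pw_range, ath,
                        summary.values[ath], tie_break_used=tie)


def _ceil2(x: float) -> float:
    """Round up to 2 decimals (guarding float representation)."""
    return math.ceil(round(x * 100.0, 6)) / 100.0


def default_ath(selections: list[AthSelection]) -> float:
    """Default ath for uncalibrated muscles: mean of the selected values,
    rounded up to two decimals (a threshold is rounded conservatively)."""
    if not selections:
        raise ValueError("need at least one selection")
    return _ceil2(float(np.mean([s.ath for s in selections])))


def rsd(curves: np.ndarray) -> float:
    """Relative standard deviation across repeated SD curves.

    ``curves`` has shape (n_repeats, n_pw) on a common PW grid.  Per PW the
    sample (n-1) standard deviation over repeats is divided by the mean;
    the result is the average over PWs.  Scale-invariant by construction.
    """
    arr = np.asarray(curves, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rsd needs >= 2 curves on a common PW grid")
    mean = arr.mean(axis=0)
    if np.any(mean == 0):
        raise ModelError("zero mean amplitude at some PW")
    return float(np.mean(arr.std(axis=0, ddof=1) / mean))


# ---------------------------------------------------------------------------
# table-driven calibration (the packaged relative-difference table)
# ---------------------------------------------------------------------------

def summaries_from_table(table: pd.DataFrame) -> list[RelDiffSummary]:
    """Tidy (muscle, pw_range, ath, mean_rel_diff) rows -> summaries."""
    out = []
    for (muscle, pw_range), grp in table.groupby(["muscle", "pw_range"],
                                                 sort=False):
        out.append(RelDiffSummary(muscle, pw_range,
                                  dict(zip(grp["ath"], grp["mean_rel_diff"]))))
    return out


@dataclass
class CalibrationReport:
    """Full outcome of the ath calibration pipeline."""

    selections: list[AthSelection]
    ath_table: AthTable

    def to_dict(self) -> dict:
        return {
            "selections": [
                {"muscle": s.muscle, "pw_range": s.pw_range, "ath": s.ath,
                 "mean_rel_diff": s.value, "tie_break_used": s.tie_break_used}
                for s in self.selections],
            "default_ath": {"pw_20_200": self.ath_table.default[0],
                            "pw_201_500": self.ath_table.default[1]},
        }


def calibrate_ath(table: pd.DataFrame | None = None) -> CalibrationReport:
    """Run the ath selection pipeline on a relative-difference table.

    Defaults to the packaged table.  Produces per-muscle selections for
    both PW ranges plus the averaged defaults for uncalibrated muscles.
    """
    if table is None:
        from . import fixtures
        table = fixtures.load_rel_diff_table()
    summaries = summaries_from_table(table)
    selections = [select_ath(s) for s in summaries]
    low = [s for s in selections if s.pw_range == "20-200"]
    high = [s for s in selections if s.pw_range == "201-500"]
    if not low or not high:
        raise ValueError("table must cover both PW ranges")
    per_muscle = {}
    for s_lo in low:
        s_hi = next((s for s in high if s.muscle == s_lo.muscle), None)
        if s_hi is not None:
            per_muscle[s_lo.muscle] = (s_lo.ath, s_hi.ath)
    ath_table = AthTable(per_muscle, (default_ath(low), default_ath(high)))
    return CalibrationReport(selections, ath_table)
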