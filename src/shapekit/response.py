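"""Statistical analysis of subharmonic amplitude versus pressure and drive.

The estimation side of subharmonic-aided pressure estimation:

* :class:`PressureSensitivityModel` — OLS of subharmonic amplitude (dB) on
  hydrostatic pressure (mmHg) within a stated range, per acoustic output;
  the fitted slope is the pressure sensitivity (dB/mmHg) and the output
  maximising |slope| among significant fits is the operating point.
* :class:`GrowthPhaseModel` — continuous three-segment piecewise-linear fit
  of amplitude versus log10(output kPa), recovering the occurrence /
  growth / saturation breakpoints by exhaustive search over the data
  abscissae with the growth (middle) segment required to be the steepest.
* :func:`crossover_qc` — the replicate quality gate: two runs must cross
  within the growth window, otherwise a third run is required.
* :func:`hysteresis_delta` — per-output baseline-minus-post amplitude
  decrease after a pressure exposure, and its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PressureResponseFit",
    "PressureSensitivityModel",
    "PhaseSegmentation",
    "GrowthPhaseModel",
    "HysteresisResult",
    "fit_regression",
    "max_sensitivity",
    "segment_phases",
    "crossover_qc",
    "hysteresis_delta",
]

#: Default sensitivity-search windows, mmHg: ascending and descending limbs.
ASCENDING_RANGE = (0.0, 75.0)
DESCENDING_RANGE = (125.0, 200.0)
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class PressureResponseFit:
    """OLS result for amplitude vs hydrostatic pressure at one output."""

    slope: float            # dB/mmHg
    intercept: float        # dB
    r2: float
    p_value: float
    mean_error: float       # mean |residual|, dB
    pressure_range: tuple[float, float]
    output_kpa: float
    n_points: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant",
                           bool(self.p_value < SIGNIFICANCE_LEVEL))

    def predict(self, p_mmhg):
        return self.intercept + self.slope * np.asarray(p_mmhg, dtype=float)

    def summary(self) -> str:
        lines = [
            "Pressure-sensitivity regression",
            "===============================",
            f"output             {self.output_kpa:10.1f} kPa",
            f"pressure range     {self.pressure_range[0]:.0f}-"
            f"{self.pressure_range[1]:.0f} mmHg ({self.n_points} points)",
            f"slope              {self.slope:10.4f} dB/mmHg",
            f"intercept          {self.intercept:10.2f} dB",
            f"r^2                {self.r2:10.3f}",
            f"p-value            {self.p_value:10.3g}"
            f"{'  *' if self.significant else ''}",
            f"mean |residual|    {self.mean_error:10.3f} dB",
        ]
        return "\n".join(lines)


class PressureSensitivityModel:
    """Amplitude-vs-pressure regressions over a measurement table.

    Parameters
    ----------
    measurements : DataFrame
        Tidy table with at least ``pressure_mmHg``, ``sha_dB`` and (for
        per-output analyses) ``p_neg_kPa`` columns — the format written by
        the extraction stage.
    """

    def __init__(self, measurements: pd.DataFrame):
        required = {"pressure_mmHg", "sha_dB"}
        missing = required - set(measurements.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        self.data = measurements.reset_index(drop=True)

    @classmethod
    def from_measurements(cls, measurements) -> "PressureSensitivityModel":
        from .data import measurements_to_frame

        return cls(measurements_to_frame(measurements))

    def fit(self, pressure_range=ASCENDING_RANGE,
            output_kpa: float | None = None) -> PressureResponseFit:
        """OLS of amplitude on pressure within ``pressure_range``."""
        df = self.data
        if output_kpa is not None:
            df = df[np.isclose(df["p_neg_kPa"], output_kpa)]
        lo, hi = pressure_range
        df = df[(df["pressure_mmHg"] >= lo) & (df["pressure_mmHg"] <= hi)]
        p = df["pressure_mmHg"].to_numpy(dtype=float)
        y = df["sha_dB"].to_numpy(dtype=float)
        if np.unique(p).size < 3:
            raise ValueError(
                f"need >= 3 distinct pressures in [{lo}, {hi}] mmHg, got "
                f"{np.unique(p).size}")
        if np.ptp(p) == 0:
            raise ValueError("zero pressure variance")
        if np.ptp(y) == 0:
            # flat response: slope 0, no explained variance, no evidence
            res_slope, res_intercept, r2, pvalue = 0.0, float(y[0]), 0.0, 1.0
        else:
            res = stats.linregress(p, y)
            res_slope, res_intercept = res.slope, res.intercept
            r2, pvalue = res.rvalue**2, res.pvalue
        resid = y - (res_intercept + res_slope * p)
        return PressureResponseFit(
            slope=float(res_slope),
            intercept=float(res_intercept),
            r2=float(r2),
            p_value=float(pvalue),
            mean_error=float(np.mean(np.abs(resid))),
            pressure_range=(float(lo), float(hi)),
            output_kpa=float(output_kpa) if output_kpa is not None
            else float("nan"),
            n_points=int(p.size),
        )

    def fit_per_output(self, pressure_range=ASCENDING_RANGE) -> list[
            PressureResponseFit]:
        """One regression per acoustic output level (skipping short ones)."""
        fits = []
        for a in np.unique(self.data["p_neg_kPa"].to_numpy(dtype=float)):
            try:
                fits.append(self.fit(pressure_range, output_kpa=a))
            except ValueError:
                continue
        if not fits:
            raise ValueError("no output level has enough pressures to fit")
        return fits

    def max_sensitivity(self, pressure_range=ASCENDING_RANGE) -> \
            PressureResponseFit:
        """Fit with the largest |slope| among significant regressions.

        Ties break toward the lower acoustic output (lower MI is preferred
        clinically).  If no fit is significant the best |slope| is returned
        with ``significant=False``.
        """
        fits = self.fit_per_output(pressure_range)
        candidates = [f for f in fits if f.significant]
        pool = candidates if candidates else fits
        if not candidates:
            warnings.warn("no output level reaches p < "
                          f"{SIGNIFICANCE_LEVEL}; returning the best "
                          "non-significant fit", stacklevel=2)
        # sort by (-|slope|, output): max sensitivity, ties toward low output
        return sorted(pool, key=lambda f: (-abs(f.slope), f.output_kpa))[0]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Occurrence / growth / saturation segmentation of a drive curve."""

    break_lo_kpa: float
    break_hi_kpa: float
    slopes: tuple[float, float, float]   # dB per decade kPa, per segment
    sse: float
    intercept: float                     # level at the first breakpoint, dB

    def __post_init__(self) -> None:
        if not self.break_lo_kpa < self.break_hi_kpa:
            raise ValueError("breakpoints must be increasing")

    def summary(self) -> str:
        s1, s2, s3 = self.slopes
        return "\n".join([
            "Growth-phase segmentation",
            "=========================",
            f"occurrence slope   {s1:8.2f} dB/decade (below "
            f"{self.break_lo_kpa:.0f} kPa)",
            f"growth slope       {s2:8.2f} dB/decade "
            f"({self.break_lo_kpa:.0f}-{self.break_hi_kpa:.0f} kPa)",
            f"saturation slope   {s3:8.2f} dB/decade (above "
            f"{self.break_hi_kpa:.0f} kPa)",
            f"SSE                {self.sse:8.4f} dB^2",
        ])


class GrowthPhaseModel:
    """Three-segment piecewise-linear model of amplitude vs drive.

    ``fit()`` searches breakpoint pairs restricted to the observed output
    abscissae (on the log10-kPa axis), solving the continuous piecewise
    least-squares problem for each pair, and keeps the minimum-SSE
    segmentation whose middle (growth) slope strictly exceeds both outer
    slopes.
    """

    def __init__(self, output_kpa, sha_db):
        a = np.asarray(output_kpa, dtype=float)
        y = np.asarray(sha_db, dtype=float)
        if a.ndim != 1 or a.shape != y.shape:
            raise ValueError("output_kpa and sha_db must be matching 1-D")
        order = np.argsort(a)
        self.a = a[order]
        self.y = y[order]
        if self.a.size < 8:
            raise ValueError("need >= 8 points to segment three phases")
        if np.any(np.diff(self.a) <= 0):
            raise ValueError("output abscissae must be distinct")

    def fit(self) -> PhaseSegmentation:
        x, y = np.log10(self.a), self.y
        n = x.size
        best = None
        for i in range(1, n - 2):
            for j in range(i + 1, n - 1):
                b1, b2 = x[i], x[j]
                design = np.column_stack([
                    np.ones(n), x,
                    np.maximum(x - b1, 0.0), np.maximum(x - b2, 0.0)])
                coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
                s1 = coef[1]
                s2 = coef[1] + coef[2]
                s3 = coef[1] + coef[2] + coef[3]
                tol = 1e-9 * max(1.0, abs(s2))
                if not (s2 > s1 + tol and s2 > s3 + tol):
                    continue
                sse = float(np.sum((design @ coef - y) ** 2))
                key = (sse, b1)
                if best is None or key < best[0]:
                    level = coef[0] + coef[1] * b1
                    best = (key, PhaseSegmentation(
                        break_lo_kpa=float(self.a[i]),
                        break_hi_kpa=float(self.a[j]),
                        slopes=(float(s1), float(s2), float(s3)),
                        sse=sse, intercept=float(level)))
        if best is None:
            raise ValueError("no growth phase detected: no segmentation has "
                             "a steepest middle segment")
        return best[1]


def fit_regression(measurements: pd.DataFrame,
                   pressure_range=ASCENDING_RANGE,
                   output_kpa: float | None = None) -> PressureResponseFit:
    """Functional wrapper around :meth:`PressureSensitivityModel.fit`."""
    return PressureSensitivityModel(measurements).fit(pressure_range,
                                                      output_kpa)


def max_sensitivity(measurements: pd.DataFrame,
                    pressure_range=ASCENDING_RANGE) -> PressureResponseFit:
    """Functional wrapper around
    :meth:`PressureSensitivityModel.max_sensitivity`."""
    return PressureSensitivityModel(measurements).max_sensitivity(
        pressure_range)


def segment_phases(output_kpa, sha_db) -> PhaseSegmentation:
    """Functional wrapper around :meth:`GrowthPhaseModel.fit`."""
    return GrowthPhaseModel(output_kpa, sha_db).fit()


def crossover_qc(set_a, set_b, growth_window=(50.0, 250.0)):
    """Replicate crossover check within the growth window.

    ``set_a``/``set_b``: DataFrames with ``p_neg_kPa`` and ``sha_dB`` on the
    same output grid.  Passes iff the difference A - B changes sign inside
    the window; a consistently one-sided pair means a third replicate is
    required.  Returns ``(passed, report_dict)``.
    """
    a = set_a.sort_values("p_neg_kPa").reset_index(drop=True)
    b = set_b.sort_values("p_neg_kPa").reset_index(drop=True)
    if len(a) != len(b) or not np.allclose(a["p_neg_kPa"], b["p_neg_kPa"]):
        raise ValueError("replicates measured on different output grids")
    lo, hi = growth_window
    mask = (a["p_neg_kPa"] >= lo) & (a["p_neg_kPa"] <= hi)
    if not mask.any():
        raise ValueError("growth window contains no outputs")
    d = (a.loc[mask, "sha_dB"].to_numpy()
         - b.loc[mask, "sha_dB"].to_numpy())
    passed = bool(d.min() < 0 < d.max())
    report = {
        "passed": passed,
        "n_in_window": int(mask.sum()),
        "min_diff_dB": float(d.min()),
        "max_diff_dB": float(d.max()),
        "recommendation": ("replicates cross: accept pair" if passed else
                           "no crossover: record a third replicate"),
    }
    return passed, report


@dataclass(frozen=True)
class HysteresisResult:
    """Post-exposure amplitude decrease per output, and its maximum."""

    table: pd.DataFrame          # columns p_neg_kPa, decrease_dB (sorted)
    max_decrease_db: float
    at_output_kpa: float
    exposure_p_mmhg: float

    def summary(self) -> str:
        return (
            "Hysteresis analysis\n"
            "===================\n"
            f"exposure           {self.exposure_p_mmhg:.0f} mmHg\n"
            f"max decrease       {self.max_decrease_db:.2f} dB at "
            f"{self.at_output_kpa:.0f} kPa\n"
            f"outputs analysed   {len(self.table)}"
        )


def hysteresis_delta(baseline: pd.DataFrame, post: pd.DataFrame,
                     exposure_p_mmhg: float) -> HysteresisResult:
    """Baseline-minus-post subharmonic decrease after a pressure exposure.

    Both tables need ``p_neg_kPa`` and ``sha_dB`` on the same output grid.
    The maximum decrease and the output where it occurs are reported (ties
    break toward the lower output); a non-positive maximum (post louder
    everywhere) is reported with a warning.
    """
    b = baseline.sort_values("p_neg_kPa").reset_index(drop=True)
    p = post.sort_values("p_neg_kPa").reset_index(drop=True)
    if len(b) != len(p) or not np.allclose(b["p_neg_kPa"], p["p_neg_kPa"]):
        raise ValueError("baseline and post measured on different grids")
    delta = b["sha_dB"].to_numpy() - p["sha_dB"].to_numpy()
    table = pd.DataFrame({"p_neg_kPa": b["p_neg_kPa"].to_numpy(),
                          "decrease_dB": delta})
    k = int(np.argmax(delta))  # argmax returns the first (lowest-kPa) tie
    max_dec = float(delta[k])
    if max_dec <= 0:
        warnings.warn("post-exposure signal is not lower at any output",
                      stacklevel=2)
    return HysteresisResult(table=table, max_decrease_db=max_dec,
                            at_output_kpa=float(table["p_neg_kPa"][k]),
                            exposure_p_mmhg=float(exposure_p_mmhg))
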