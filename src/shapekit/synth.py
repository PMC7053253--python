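"""Synthetic RF-frame generator for the pressure-phantom protocol.

The phantom experiment this package analyses records pulse-inversion RF
frames of a stirred SonoVue suspension at hydrostatic pressures 0-200 mmHg
and 20 log-spaced acoustic outputs.  No raw scanner data ships with the
package, so this module generates RF datasets carrying the same statistical
structure the analysis stages assume:

* a subharmonic (f0/2) component whose true amplitude follows a
  three-phase occurrence/growth/saturation curve in acoustic output
  (growth between 50 and 250 kPa peak-negative pressure) multiplied by an
  ascending (0-75 mmHg, +0.15 dB/mmHg) / plateau (75-125) / descending
  (125-200, -0.16 dB/mmHg) hydrostatic-pressure response;
* fundamental (f0) echoes from random scatterers that flip sign with the
  pulse-inversion polarity and therefore cancel under PI summation, while
  the period-doubled subharmonic keeps one random phase per PI pair and
  survives;
* a per-acquisition dB jitter of the subharmonic level (``noise_sigma``)
  plus an additive white sample-noise floor (``floor_sigma``).

Every dataset is reproducible from the tuple (master seed, pressure,
output, replicate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bubble import BubbleParams, EquilibriumState, Excitation, simulate_rp
from .calibration import SOUND_SPEED_WATER
from .data import RFDataset, ROI

__all__ = [
    "ResponseModel",
    "AcquisitionConfig",
    "CYCLES_BY_F0",
    "sha_true",
    "generate_dataset",
    "generate_hysteresis_pair",
    "default_destruction_profile",
    "default_output_grid",
    "default_hysteresis_outputs",
    "output_pct_to_kpa",
    "kpa_to_output_pct",
    "physics_mode_line",
]

#: Transmit cycles per pulse at each protocol frequency (long pulses favour
#: the subharmonic SNR; length capped by the 5.2-mm effective chamber depth).
CYCLES_BY_F0 = {
    1.7e6: 5, 2.1e6: 7, 3.0e6: 10, 4.0e6: 12, 5.0e6: 16, 6.0e6: 16, 7.0e6: 16,
}

# Log-affine map between "% maximum scanner acoustic output" and in-chamber
# peak-negative kPa.  The true instrument map is never published; this
# synthetic anchor sends the protocol's 3.5%-100% span to 30-330 kPa, which
# covers the 50-250-kPa growth window.
_PCT_ANCHOR = (3.5, 30.0)
_PCT_ANCHOR_HI = (100.0, 330.0)
_PCT_SLOPE = (math.log10(_PCT_ANCHOR_HI[1] / _PCT_ANCHOR[1])
              / math.log10(_PCT_ANCHOR_HI[0] / _PCT_ANCHOR[0]))

#: Output (kPa) where post-exposure destruction is deepest, and its depth.
DESTRUCTION_DIP_KPA = 181.0
DESTRUCTION_DIP_DB = 3.2
#: Exposures below this hydrostatic pressure (mmHg) leave no after-effect.
DESTRUCTION_THRESHOLD_MMHG = 150.0


def output_pct_to_kpa(pct) -> np.ndarray | float:
    """Synthetic scanner map: % maximum output -> peak-negative kPa."""
    pct = np.asarray(pct, dtype=float)
    kpa = _PCT_ANCHOR[1] * (pct / _PCT_ANCHOR[0]) ** _PCT_SLOPE
    return float(kpa) if kpa.ndim == 0 else kpa


def kpa_to_output_pct(kpa) -> np.ndarray | float:
    """Inverse of :func:`output_pct_to_kpa`."""
    kpa = np.asarray(kpa, dtype=float)
    pct = _PCT_ANCHOR[0] * (kpa / _PCT_ANCHOR[1]) ** (1.0 / _PCT_SLOPE)
    return float(pct) if pct.ndim == 0 else pct


def default_output_grid(n: int = 20, lo_kpa: float = 50.0,
                        hi_kpa: float = 250.0) -> np.ndarray:
    """Log-spaced acoustic outputs (kPa) covering the growth window."""
    return np.geomspace(lo_kpa, hi_kpa, n)


def default_hysteresis_outputs(n: int = 20) -> np.ndarray:
    """Log-spaced outputs spanning 30-330 kPa for hysteresis runs.

    The abscissa nearest the destruction dip is snapped onto it: in the
    protocol the maximal-decrease output is by definition one of the
    measured levels.
    """
    grid = np.geomspace(30.0, 330.0, n)
    grid[np.argmin(np.abs(np.log10(grid / DESTRUCTION_DIP_KPA)))] = (
        DESTRUCTION_DIP_KPA)
    return grid


@dataclass(frozen=True)
class ResponseModel:
    """Ground-truth subharmonic amplitude model of the generator.

    The true amplitude (dB re container full scale) separates as
    ``sha_true(p, a) = sha0 + S(a) + g(p)``:

    * ``S(a)`` — three-segment piecewise-linear in log10(output kPa):
      flat occurrence floor ``occ_level`` below ``growth_breaks[0]``,
      linear growth up to ``growth_breaks[1]``, flat saturation
      ``sat_level`` above.  The growth slope (dB/decade) follows from
      continuity.
    * ``g(p)`` — ascending/plateau/descending hydrostatic response with
      g(0) = 0: slope ``asc_slope`` on [0, 75] mmHg, constant on
      [75, 125], slope ``desc_slope`` on [125, 200].
    """

    sha0: float = 0.0
    occ_level: float = -45.0
    sat_level: float = -15.0
    growth_breaks: tuple[float, float] = (50.0, 250.0)
    asc_slope: float = 0.15
    desc_slope: float = -0.16
    plateau_range: tuple[float, float] = (75.0, 125.0)

    def __post_init__(self) -> None:
        lo, hi = self.growth_breaks
        if not lo < hi:
            raise ValueError("growth_breaks must be increasing")
        if self.occ_level > self.sat_level:
            raise ValueError("occ_level must not exceed sat_level")
        p_lo, p_hi = self.plateau_range
        if not 0 < p_lo < p_hi < 200:
            raise ValueError("plateau_range must lie inside (0, 200) mmHg")

    @property
    def growth_slope(self) -> float:
        """dB per decade of output pressure across the growth phase."""
        lo, hi = self.growth_breaks
        return (self.sat_level - self.occ_level) / math.log10(hi / lo)

    def acoustic_level(self, a_kpa) -> np.ndarray | float:
        """Three-phase component S(a), dB."""
        a = np.asarray(a_kpa, dtype=float)
        lo, hi = self.growth_breaks
        x = np.log10(np.clip(a, lo, hi) / lo)
        s = self.occ_level + self.growth_slope * x
        return float(s) if s.ndim == 0 else s

    def pressure_offset(self, p_mmhg) -> np.ndarray | float:
        """Hydrostatic component g(p), dB, with g(0) = 0."""
        p = np.asarray(p_mmhg, dtype=float)
        if np.any(p < 0) or np.any(p > 200):
            raise ValueError("hydrostatic pressure must be within [0, 200] mmHg")
        p_lo, p_hi = self.plateau_range
        g = (self.asc_slope * np.minimum(p, p_lo)
             + self.desc_slope * np.maximum(p - p_hi, 0.0))
        return float(g) if g.ndim == 0 else g


def sha_true(p_mmhg: float, a_kpa: float, model: ResponseModel) -> float:
    """Generator ground-truth subharmonic amplitude, dB re full scale."""
    return float(model.sha0 + model.acoustic_level(a_kpa)
                 + model.pressure_offset(p_mmhg))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition protocol for one synthetic experiment."""

    f0: float = 4.0e6
    fs: float = 50.0e6
    n_cycles: int | None = None          # default: protocol table for f0
    n_lines: int = 64
    n_frames: int = 3
    n_samples: int = 1536
    roi: ROI = field(default_factory=ROI)
    pressures: tuple = tuple(np.arange(200.0, -1.0, -25.0))
    outputs_kpa: tuple = tuple(default_output_grid())
    n_replicates: int = 2
    noise_sigma: float = 0.3             # per-acquisition dB jitter
    floor_sigma: float = 1.0e-4          # additive white noise, full-scale units
    n_scatterers: int = 50
    fundamental_scale: float = 0.3       # fundamental amplitude at max output
    c: float = SOUND_SPEED_WATER
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 4 * self.f0:
            raise ValueError(
                f"fs={self.fs:g} must exceed 4*f0={4 * self.f0:g} so both the "
                "fundamental and the subharmonic sit below Nyquist")
        if self.n_lines % 2:
            raise ValueError("n_lines must be even (pulse-inversion pairs)")
        if self.noise_sigma < 0 or self.floor_sigma < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def cycles(self) -> int:
        if self.n_cycles is not None:
            return self.n_cycles
        return CYCLES_BY_F0.get(self.f0, 12)

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _dataset_rng(cfg: AcquisitionConfig, pressure: float, output_kpa: float,
                 replicate: int, salt: int) -> np.random.Generator:
    """Deterministic per-acquisition RNG from the documented seed tuple."""
    ss = np.random.SeedSequence(
        [int(cfg.seed), int(round(pressure * 1000)),
         int(round(output_kpa * 1000)), int(replicate), int(salt)])
    return np.random.default_rng(ss)


def generate_dataset(
    cfg: AcquisitionConfig,
    model: ResponseModel,
    pressure: float,
    output_kpa: float,
    replicate: int = 0,
    sha_offset_db: float = 0.0,
    seed_salt: int = 0,
) -> RFDataset:
    """Generate one pulse-inversion RF dataset at (pressure, output).

    Lines alternate +/- transmit polarity.  Per PI pair: the fundamental is
    a sum of tone bursts from ``n_scatterers`` random depths (sign follows
    the polarity); the subharmonic is a single f0/2 tone burst covering the
    ROI with a constant envelope of 10^(sha/20) full-scale units and one
    random phase shared by both lines of the pair.  ``sha`` is the model
    truth plus one N(0, noise_sigma) draw for the whole acquisition plus
    ``sha_offset_db`` (used for post-exposure destruction).
    """
    rng = _dataset_rng(cfg, pressure, output_kpa, replicate, seed_salt)
    t = cfg.time_axis()
    n_pairs = cfg.n_lines // 2

    sha_db = (sha_true(pressure, output_kpa, model) + sha_offset_db
              + rng.normal(0.0, cfg.noise_sigma))
    a_sub = 10.0 ** (sha_db / 20.0)

    # subharmonic envelope: constant over the ROI depth band plus one pulse
    # length of margin, so the ROI interior sees a flat envelope
    sl = cfg.roi.sample_slice(cfg.fs, cfg.c, cfg.n_samples)
    margin = int(round(cfg.cycles / cfg.f0 * cfg.fs))
    env = np.zeros(cfg.n_samples)
    env[max(0, sl.start - margin):min(cfg.n_samples, sl.stop + margin)] = 1.0

    # scatterer depth band = ROI depth band (round-trip delay)
    z0, z1 = cfg.roi.depth_start_mm * 1e-3, cfg.roi.depth_end_mm * 1e-3
    burst_dur = cfg.cycles / cfg.f0
    amp_fund = (cfg.fundamental_scale * (output_kpa / _PCT_ANCHOR_HI[1])
                / math.sqrt(cfg.n_scatterers))

    rf = np.empty((cfg.n_frames, cfg.n_lines, cfg.n_samples))
    for frame in range(cfg.n_frames):
        for pair in range(n_pairs):
            tau = 2.0 * rng.uniform(z0, z1, cfg.n_scatterers) / cfg.c
            dt = t[None, :] - tau[:, None]
            bursts = np.where((dt >= 0) & (dt < burst_dur),
                              np.sin(2 * np.pi * cfg.f0 * dt), 0.0)
            fund = amp_fund * bursts.sum(axis=0)
            phase = rng.uniform(0.0, 2 * np.pi)
            sub = a_sub * env * np.cos(np.pi * cfg.f0 * t + phase)
            rf[frame, 2 * pair] = fund + sub
            rf[frame, 2 * pair + 1] = -fund + sub
    if cfg.floor_sigma > 0:
        rf += rng.normal(0.0, cfg.floor_sigma, rf.shape)

    meta = {
        "schema_version": 1,
        "f0": cfg.f0, "fs": cfg.fs, "c": cfg.c, "n_cycles": cfg.cycles,
        "n_frames": cfg.n_frames, "n_lines": cfg.n_lines,
        "n_samples": cfg.n_samples,
        "roi": [cfg.roi.depth_start_mm, cfg.roi.depth_end_mm,
                cfg.roi.lateral_start_mm, cfg.roi.lateral_end_mm],
        "pressure_mmHg": float(pressure),
        "p_neg_kPa": float(output_kpa),
        "output_pct": float(kpa_to_output_pct(output_kpa)),
        "replicate": int(replicate),
        "polarity": [1, -1] * n_pairs,
        "pi_combined": False,
        "noise_sigma": cfg.noise_sigma, "floor_sigma": cfg.floor_sigma,
        "seed": int(cfg.seed), "seed_salt": int(seed_salt),
        "sha_true_dB": float(sha_true(pressure, output_kpa, model)),
    }
    return RFDataset(rf=rf, meta=meta)


def default_destruction_profile(exposure_p_mmhg: float):
    """Post-exposure signal-loss profile (dB as a function of output kPa).

    Exposure below 150 mmHg leaves the bubbles intact (zero offset); at and
    above, a Gaussian dip on the log-output axis reaching -3.2 dB at
    181 kPa, the deepest loss the hysteresis analysis should recover.
    """
    if exposure_p_mmhg < DESTRUCTION_THRESHOLD_MMHG:
        return lambda a_kpa: np.zeros_like(np.asarray(a_kpa, dtype=float))

    def profile(a_kpa):
        x = np.log10(np.asarray(a_kpa, dtype=float) / DESTRUCTION_DIP_KPA)
        return -DESTRUCTION_DIP_DB * np.exp(-0.5 * (x / 0.08) ** 2)

    return profile


def generate_hysteresis_pair(
    cfg: AcquisitionConfig,
    model: ResponseModel,
    exposure_p_mmhg: float,
    offset_profile=None,
    outputs_kpa=None,
    replicate: int = 0,
):
    """Baseline / post-exposure dataset lists at 0 mmHg across outputs.

    Both arms are recorded at ambient pressure; the post arm applies
    ``offset_profile(output)`` dB to the subharmonic truth (default:
    :func:`default_destruction_profile`).  Returns
    ``(baseline_list, post_list)`` ordered as ``outputs_kpa``.
    """
    if outputs_kpa is None:
        outputs_kpa = default_hysteresis_outputs()
    outputs_kpa = np.asarray(outputs_kpa, dtype=float)
    if offset_profile is None:
        offset_profile = default_destruction_profile(exposure_p_mmhg)
    offsets = np.asarray(offset_profile(outputs_kpa), dtype=float)
    if exposure_p_mmhg >= DESTRUCTION_THRESHOLD_MMHG and np.any(offsets > 0):
        raise ValueError(
            "offset_profile must be <= 0 everywhere for exposures >= "
            f"{DESTRUCTION_THRESHOLD_MMHG} mmHg (destruction only removes signal)")

    baseline = [generate_dataset(cfg, model, 0.0, a, replicate,
                                 seed_salt=1)
                for a in outputs_kpa]
    post = [generate_dataset(cfg, model, 0.0, a, replicate,
                             sha_offset_db=float(off), seed_salt=2)
            for a, off in zip(outputs_kpa, offsets)]
    return baseline, post


def physics_mode_line(
    params: BubbleParams,
    eq: EquilibriumState,
    exc: Excitation,
    cfg: AcquisitionConfig,
    normalize: float = 0.5,
) -> np.ndarray:
    """One RF line synthesised from the bubble model itself.

    The far-field scattered pressure of a pulsating bubble is proportional
    to the second time derivative of its volume; this samples that quantity
    on the acquisition grid (zero-padded beyond the simulated interval).
    Demonstration coupling between the mechanistic and the signal stages —
    the amplitude scale is normalised, not calibrated.
    """
    trace = simulate_rp(params, eq, exc)
    vol = 4.0 / 3.0 * np.pi * trace.r**3
    t = cfg.time_axis()
    # a quiescent bubble scatters nothing; avoid normalising solver jitter
    if (vol.max() - vol.min()) / vol.mean() < 1e-7:
        return np.zeros_like(t)
    d2v = np.gradient(np.gradient(vol, trace.t), trace.t)
    line = np.interp(t, trace.t, d2v, left=0.0, right=0.0)
    return normalize * line / np.max(np.abs(line))
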