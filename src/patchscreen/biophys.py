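"""Biophysical measurement analysis.

Four instrument models and one reporting operation:

* DLS interaction parameter: Dapp = D0·(1 + kD·c) fit by ordinary least
  squares; kD = slope/intercept in mL/mg, also reported as mL/g against the
  customary −15 mL/g attractive-interaction threshold.
* Viscosity–concentration: η = Y0·e^(kC) by nonlinear least squares on the
  cP scale (log-linear initialisation), with the concentration at which the
  fit crosses the 30 cP acceptability line.
* AC-SINS: plasmon-peak red shift of a sample trace against a gold-
  conjugate control; shift > 10 nm flags self-association risk; a valid
  control must peak below 535 nm.
* nanoDSF: melting temperatures from first-derivative peaks of the 350/330
  fluorescence ratio, onset from a fractional-threshold crossing, and an
  aggregation-onset temperature from the scattering channel.
* Pearson correlation matrix between descriptor and measurement tables
  with |R| >= 0.8 flagged as strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

KD_ATTRACTIVE_THRESHOLD = -0.015  # mL/mg, i.e. -15 mL/g
ACCEPTABLE_VISCOSITY_CP = 30.0
ACSINS_FLAG_NM = 10.0
ACSINS_CONTROL_MAX_NM = 535.0
STRONG_R = 0.8


@dataclass(frozen=True)
class ConcentrationSeries:
    concentrations: np.ndarray  # mg/mL
    responses: np.ndarray       # diffusion (any consistent unit) or cP
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class KdFit:
    d0: float
    kd: float                 # mL/mg
    d0_se: float
    kd_se: float
    r_squared: float
    flag_attractive: bool

    @property
    def kd_ml_per_g(self) -> float:
        return self.kd * 1000.0


@dataclass(frozen=True)
class ViscosityFit:
    y0: float                 # cP
    k: float                  # mL/mg
    y0_se: float
    k_se: float
    c_at_30cp: float | None   # mg/mL, None when the fit never reaches 30 cP
    dof: int = 0              # residual degrees of freedom (n − 2)

    def confidence_intervals(self, level: float = 0.95):
        """t-based (Y0, k) confidence intervals at the given level."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.dof)
        return (
            (self.y0 - tcrit * self.y0_se, self.y0 + tcrit * self.y0_se),
            (self.k - tcrit * self.k_se, self.k + tcrit * self.k_se),
        )


@dataclass(frozen=True)
class SpectrumTrace:
    wavelengths: np.ndarray   # nm, strictly increasing
    absorbance: np.ndarray    # AU

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class Thermogram:
    temperature: np.ndarray          # °C, strictly increasing
    ratio_350_330: np.ndarray
    scattering: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass(frozen=True)
class RedShiftResult:
    delta_lambda_nm: float
    sample_peak_nm: float
    control_peak_nm: float
    flag_self_association: bool


@dataclass(frozen=True)
class DsfResult:
    tonset: float | None
    tm: tuple[float, ...]     # ascending, at most 3
    tagg: float | None


def fit_kd(
    series: ConcentrationSeries,
    attractive_threshold: float = KD_ATTRACTIVE_THRESHOLD,
) -> KdFit:
    """Fit the apparent-diffusion line and extract the interaction parameter.

    The model is multiplicative in kD: Dapp = D0 + (D0·kD)·c, so the
    regression slope is D0·kD and kD = slope/intercept.
    """
    c = np.asarray(series.concentrations, dtype=float)
    d = np.asarray(series.responses, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("kD fit needs at least 3 distinct concentrations")
    res = stats.linregress(c, d)
    if res.intercept <= 0:
        raise ValueError(f"fit rejected: non-positive D0 = {res.intercept:.4g}")
    kd = res.slope / res.intercept
    # first-order error propagation for the ratio
    kd_se = abs(kd) * float(
        np.sqrt(
            (res.stderr / res.slope) ** 2 + (res.intercept_stderr / res.intercept) ** 2
        )
    ) if res.slope != 0 else res.stderr / res.intercept
    return KdFit(
        d0=float(res.intercept),
        kd=float(kd),
        d0_se=float(res.intercept_stderr),
        kd_se=float(kd_se),
        r_squared=float(res.rvalue**2),
        flag_attractive=bool(kd < attractive_threshold),
    )


def fit_viscosity(series: ConcentrationSeries) -> ViscosityFit:
    """Exponential-growth fit η = Y0·e^(kC) on the linear (cP) scale.

    The loss is weighted by 1/η² (rheometer error is proportional to the
    reading), which keeps the fit on the cP scale while making the reported
    standard errors calibrated under relative noise; initial values come
    from a log-linear regression.
    """
    c = np.asarray(series.concentrations, dtype=float)
    eta = np.asarray(series.responses, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("viscosity fit needs at least 3 distinct concentrations")
    if (eta <= 0).any():
        raise ValueError("viscosities must be positive")
    # log-linear initialisation, then least squares on the stated model
    slope, intercept = np.polyfit(c, np.log(eta), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, pcov = curve_fit(
            lambda x, y0, k: y0 * np.exp(k * x),
            c,
            eta,
            p0=p0,
            sigma=eta,
            absolute_sigma=False,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit did not converge (log-linear start Y0={p0[0]:.3g}, "
            f"k={p0[1]:.3g} may still be informative): {exc}"
        ) from exc
    y0, k = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    if y0 <= 0:
        raise ValueError(f"fit rejected: non-positive Y0 = {y0:.4g}")
    c30: float | None = None
    if k > 0 and y0 < ACCEPTABLE_VISCOSITY_CP:
        c30 = float(np.log(ACCEPTABLE_VISCOSITY_CP / y0) / k)
    elif y0 >= ACCEPTABLE_VISCOSITY_CP:
        c30 = 0.0
    return ViscosityFit(
        y0=y0, k=k, y0_se=float(se[0]), k_se=float(se[1]),
        c_at_30cp=c30, dof=len(c) - 2,
    )


def _smooth(y: np.ndarray, window_points: int) -> np.ndarray:
    if window_points <= 1:
        return y.astype(float)
    kernel = np.ones(window_points) / window_points
    pad = window_points // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(y)]
    return out


def _peak_wavelength(trace: SpectrumTrace, window_points: int) -> float:
    """Absorbance-maximum wavelength with 3-point quadratic interpolation."""
    w = np.asarray(trace.wavelengths, dtype=float)
    a = _smooth(np.asarray(trace.absorbance, dtype=float), window_points)
    i = int(np.argmax(a))
    if i == 0 or i == len(a) - 1:
        raise ValueError("absorbance peak lies on the grid boundary; unreliable")
    y0, y1, y2 = a[i - 1], a[i], a[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(w[i])
    # vertex of the parabola through the three points (uniform grid assumed)
    offset = 0.5 * (y0 - y2) / denom
    step = w[i + 1] - w[i]
    return float(w[i] + offset * step)


class ControlFailureError(ValueError):
    """The negative-control plasmon peak is out of specification."""


def acsins_redshift(
    sample: SpectrumTrace,
    control: SpectrumTrace,
    smoothing_window: float = 5.0,
) -> RedShiftResult:
    """Plasmon red shift Δλ = λmax(sample) − λmax(control), with risk flag.

    ``smoothing_window`` is in nm and converted to grid points on each
    trace. A shift above 10 nm flags high self-association risk; the
    control peak must sit below 535 nm or the assay is invalid.
    """
    def window_points(trace: SpectrumTrace) -> int:
        step = float(np.median(np.diff(trace.wavelengths)))
        return max(1, int(round(smoothing_window / step)) | 1)  # odd

    control_peak = _peak_wavelength(control, window_points(control))
    if control_peak >= ACSINS_CONTROL_MAX_NM:
        raise ControlFailureError(
            f"control peak at {control_peak:.1f} nm >= {ACSINS_CONTROL_MAX_NM} nm"
        )
    sample_peak = _peak_wavelength(sample, window_points(sample))
    delta = sample_peak - control_peak
    return RedShiftResult(
        delta_lambda_nm=float(delta),
        sample_peak_nm=float(sample_peak),
        control_peak_nm=float(control_peak),
        flag_self_association=bool(delta > ACSINS_FLAG_NM),
    )


def _derivative_peaks(
    t: np.ndarray,
    y: np.ndarray,
    smooth_points: int,
    prominence_frac: float,
    max_peaks: int,
) -> tuple[list[float], np.ndarray]:
    dy = np.gradient(_smooth(y, smooth_points), t)
    span = float(dy.max() - dy.min())
    if span <= 0:
        return [], dy
    # robust noise floor keeps instrument ripple out of the peak list
    mad = float(np.median(np.abs(dy - np.median(dy))))
    threshold = max(prominence_frac * span, 6.0 * 1.4826 * mad)
    peaks, props = find_peaks(dy, prominence=threshold)
    if len(peaks) == 0:
        return [], dy
    # keep the most prominent transitions, then report in ascending T
    order = np.argsort(props["prominences"])[::-1][:max_peaks]
    chosen = np.sort(peaks[order])
    return [float(t[i]) for i in chosen], dy


def dsf_transitions(
    trace: Thermogram,
    smooth_points: int = 5,
    prominence_frac: float = 0.05,
    onset_frac: float = 0.10,
) -> DsfResult:
    """Extract Tonset and Tm1..Tm3 from the ratio trace, Tagg from scattering.

    Melting temperatures are first-derivative peaks above a prominence
    threshold (default 5% of the derivative range), at most three, reported
    ascending. Tonset is the lowest temperature at which the derivative
    first exceeds ``onset_frac`` of the first peak's height. A flat trace
    yields an empty result rather than an error.
    """
    t = np.asarray(trace.temperature, dtype=float)
    if len(t) < 20:
        raise ValueError("thermogram needs at least 20 temperature points")
    ratio = np.asarray(trace.ratio_350_330, dtype=float)
    tms, dy = _derivative_peaks(t, ratio, smooth_points, prominence_frac, 3)

    tonset: float | None = None
    if tms:
        first_peak_idx = int(np.argmin(np.abs(t - tms[0])))
        height = dy[first_peak_idx]
        threshold = onset_frac * height
        above = np.flatnonzero(dy[: first_peak_idx + 1] >= threshold)
        if len(above):
            tonset = float(t[above[0]])

    tagg: float | None = None
    if trace.scattering is not None:
        agg_peaks, _ = _derivative_peaks(
            t, np.asarray(trace.scattering, dtype=float),
            smooth_points, prominence_frac, 1,
        )
        if agg_peaks:
            tagg = agg_peaks[0]

    return DsfResult(tonset=tonset, tm=tuple(tms), tagg=tagg)


def correlation_matrix(
    descriptors: pd.DataFrame,
    measurements: pd.DataFrame,
    min_pairs: int = 3,
    strong: float = STRONG_R,
) -> pd.DataFrame:
    """Pearson R between every descriptor and measurement column.

    Tables join on variant_id (the index). Each cell reports R over
    complete pairs, the pair count, and a strong flag for |R| >= 0.8; cells
    with fewer than ``min_pairs`` complete pairs are left undefined (NaN).
    Returns a long-format frame (descriptor, measurement, r, n, strong).
    """
    joined = descriptors.join(measurements, how="inner", lsuffix="_desc")
    rows = []
    for dcol in descriptors.columns:
        dc = dcol + "_desc" if dcol + "_desc" in joined.columns else dcol
        for mcol in measurements.columns:
            pair = joined[[dc, mcol]].dropna()
            n = len(pair)
            if n < min_pairs or pair[dc].nunique() < 2 or pair[mcol].nunique() < 2:
                r = np.nan
            else:
                r = float(stats.pearsonr(pair[dc], pair[mcol]).statistic)
            rows.append(
                {
                    "descriptor": dcol,
                    "measurement": mcol,
                    "r": r,
                    "n": n,
                    "strong": bool(abs(r) >= strong) if np.isfinite(r) else False,
                }
            )
    return pd.DataFrame(rows)
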