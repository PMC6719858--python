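"""Equilibrium DNA-binding and thermal-stability assay analysis.

Two instruments are modelled.  Fluorescence-anisotropy titrations of a
labelled oligonucleotide against increasing protein are fit with the
quadratic ligand-depletion (Morrison) model, which is required when the
labelled DNA concentration (20 nM here) is comparable to the dissociation
constant so free and total protein differ appreciably:

    FB(P) = ((P + D + Kd) − sqrt((P + D + Kd)² − 4·P·D)) / (2·D)
    A(P)  = a_free + (a_bound − a_free) · FB(P)

with P the *tetramer* protein concentration (a monomer/tetramer mix-up is
a 4× error in Kd), D the total DNA and FB the bound DNA fraction.

Differential scanning fluorimetry melt curves are reduced to melting
temperatures at the peaks of the smoothed first derivative dF/dT; the
highest peak is the major transition, remaining qualifying peaks are
minor.  Peak positions are refined by parabolic interpolation through the
peak sample and its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "TitrationCurve",
    "IsothermFit",
    "MeltCurve",
    "TmPeak",
    "TmResult",
    "FitError",
    "NoTransitionError",
    "fraction_bound",
    "predict_anisotropy",
    "fit_isotherm",
    "fit_isotherm_replicates",
    "melt_derivative",
    "find_tm",
    "load_titration_csv",
    "load_melt_csv",
]


class FitError(RuntimeError):
    """Non-linear regression failed to converge."""


class NoTransitionError(ValueError):
    """No qualifying derivative peak in a melt curve."""


@dataclass
class TitrationCurve:
    """Anisotropy vs total protein (tetramer) concentration at fixed DNA."""

    protein_tetramer_conc: np.ndarray  # nM, strictly ascending
    anisotropy: np.ndarray
    dna_total: float = 20.0  # nM
    replicate_sd: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_tetramer_conc = np.asarray(self.protein_tetramer_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        p = self.protein_tetramer_conc
        if p.ndim != 1 or p.size < 6:
            raise ValueError("titration needs at least 6 concentration points")
        if np.any(p < 0) or np.any(np.diff(p) <= 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if self.anisotropy.shape != p.shape:
            raise ValueError("anisotropy length must match concentrations")
        if self.dna_total <= 0:
            raise ValueError("dna_total must be positive")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != p.shape:
                raise ValueError("replicate_sd length must match concentrations")


@dataclass
class IsothermFit:
    kd_apparent: float  # nM
    kd_sd: float  # nM
    a_free: float
    a_bound: float
    residual_rms: float
    covariance: np.ndarray  # 3x3 for (kd, a_free, a_bound)


def fraction_bound(p_total, d_total: float, kd: float):
    """Bound DNA fraction under 1:1 binding with ligand depletion (Morrison)."""
    p = np.asarray(p_total, dtype=float)
    if d_total <= 0:
        raise ValueError("d_total must be positive")
    if np.any(p < 0) or kd < 0:
        raise ValueError("p_total and kd must be non-negative")
    s = p + d_total + kd
    disc = np.clip(s * s - 4.0 * p * d_total, 0.0, None)
    fb = (s - np.sqrt(disc)) / (2.0 * d_total)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if np.isscalar(p_total) else fb


def predict_anisotropy(p_total, kd: float, a_free: float, a_bound: float, d_total: float = 20.0):
    """Anisotropy model A(P) = a_free + (a_bound − a_free)·FB(P)."""
    return a_free + (a_bound - a_free) * fraction_bound(p_total, d_total, kd)


def _model(d_total: float):
    def f(p, kd, a_free, a_bound):
        return a_free + (a_bound - a_free) * fraction_bound(p, d_total, kd)

    return f


def fit_isotherm(curve: TitrationCurve, weighted: bool = False) -> IsothermFit:
    """Least-squares fit of (Kd, a_free, a_bound) to a titration curve.

    Initial values: a_free from the first point, a_bound from the last,
    Kd from the concentration nearest half-amplitude.  Kd is bounded
    positive; on failure the fit is retried from Kd/10 and 10·Kd.
    """
    p = curve.protein_tetramer_conc
    a = curve.anisotropy
    if np.ptp(a) <= 0:
        raise FitError("anisotropy does not vary; nothing to fit")
    a0, a1 = float(a[0]), float(a[-1])
    half = (a0 + a1) / 2.0
    kd0 = float(p[np.argmin(np.abs(a - half))])
    kd0 = max(kd0, 1e-6)
    sigma = None
    if weighted and curve.replicate_sd is not None and np.all(curve.replicate_sd > 0):
        sigma = curve.replicate_sd
    model = _model(curve.dna_total)
    bounds = ([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    last_exc: Exception | None = None
    for kd_init in (kd0, kd0 / 10.0, kd0 * 10.0):
        try:
            popt, pcov = curve_fit(
                model, p, a, p0=[kd_init, a0, a1], sigma=sigma,
                bounds=bounds, maxfev=20000,
            )
            resid = a - model(p, *popt)
            return IsothermFit(
                kd_apparent=float(popt[0]),
                kd_sd=float(np.sqrt(max(pcov[0, 0], 0.0))),
                a_free=float(popt[1]),
                a_bound=float(popt[2]),
                residual_rms=float(np.sqrt(np.mean(resid**2))),
                covariance=pcov,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            last_exc = exc
    raise FitError(f"isotherm fit did not converge after restarts: {last_exc}")


def fit_isotherm_replicates(curves: Sequence[TitrationCurve]) -> IsothermFit:
    """Fit each replicate curve; Kd and SD are reported across replicates.

    With >= 3 curves the SD is the replicate-level standard deviation of
    fitted Kd values, matching how triplicate experiments are summarised.
    """
    fits = [fit_isotherm(c) for c in curves]
    kds = np.array([f.kd_apparent for f in fits])
    best = fits[int(np.argmin([f.residual_rms for f in fits]))]
    kd_sd = float(kds.std(ddof=1)) if len(fits) >= 3 else float(np.mean([f.kd_sd for f in fits]))
    return IsothermFit(float(kds.mean()), kd_sd, best.a_free, best.a_bound,
                       float(np.mean([f.residual_rms for f in fits])), best.covariance)


@dataclass
class MeltCurve:
    """DSF melt curve: fluorescence vs temperature on an ascending grid."""

    temperature: np.ndarray  # deg C, strictly ascending
    fluorescence: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        t = self.temperature
        if t.ndim != 1 or t.size < 20:
            raise ValueError("melt curve needs at least 20 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must be strictly ascending")
        if t[-1] - t[0] < 15.0:
            raise ValueError("temperature range must cover at least 15 degC")
        if self.fluorescence.shape != t.shape:
            raise ValueError("fluorescence length must match temperature")


def melt_derivative(curve: MeltCurve, smooth_window: int = 7) -> np.ndarray:
    """Savitzky–Golay smoothed dF/dT on the curve's own temperature grid."""
    n = curve.temperature.size
    if smooth_window % 2 == 0 or smooth_window < 5 or smooth_window >= n / 2:
        raise ValueError("smooth_window must be odd, >= 5 and < n/2")
    smooth = savgol_filter(curve.fluorescence, smooth_window, polyorder=2)
    return np.gradient(smooth, curve.temperature)


@dataclass
class TmPeak:
    tm: float  # deg C
    derivative_height: float
    prominence: float
    label: str  # "major" | "minor"


@dataclass
class TmResult:
    peaks: list[TmPeak]  # sorted by tm

    @property
    def major(self) -> TmPeak:
        return next(p for p in self.peaks if p.label == "major")

    @property
    def minor(self) -> list[TmPeak]:
        return [p for p in self.peaks if p.label == "minor"]


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (x[i-1..i+1], y[i-1..i+1]), clamped to one grid step."""
    if i == 0 or i == x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = (x[i + 1] - x[i - 1]) / 2.0
    return float(x[i] + delta * step)


def find_tm(
    curve: MeltCurve,
    prominence_fraction: float = 0.05,
    smooth_window: int = 7,
) -> TmResult:
    """Melting temperatures from the first-derivative peaks of a melt curve.

    Local maxima of dF/dT with prominence >= prominence_fraction times the
    maximum derivative qualify; the highest is labelled major, the rest
    minor.  Raises :class:`NoTransitionError` for flat / monotone-baseline
    curves with no unfolding transition.
    """
    deriv = melt_derivative(curve, smooth_window)
    top = float(deriv.max())
    if top <= 0:
        raise NoTransitionError("derivative never positive; no melting transition")
    idx, props = find_peaks(deriv, prominence=prominence_fraction * top)
    if idx.size == 0:
        raise NoTransitionError("no derivative peak exceeds the prominence threshold")
    heights = deriv[idx]
    major_pos = int(np.argmax(heights))
    peaks = []
    for k, i in enumerate(idx):
        peaks.append(
            TmPeak(
                tm=_parabolic_refine(curve.temperature, deriv, int(i)),
                derivative_height=float(deriv[i]),
                prominence=float(props["prominences"][k]),
                label="major" if k == major_pos else "minor",
            )
        )
    peaks.sort(key=lambda p: p.tm)
    return TmResult(peaks)


# ---------------------------------------------------------------------------
# Plain-text I/O (two-column CSV/TSV with a header)


def load_titration_csv(path, dna_total: float = 20.0) -> TitrationCurve:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    conc = cols.get("conc_nm") or cols.get("protein_nm") or df.columns[0]
    ani = cols.get("anisotropy") or df.columns[1]
    sd = df[cols["replicate_sd"]].to_numpy() if "replicate_sd" in cols else None
    return TitrationCurve(df[conc].to_numpy(), df[ani].to_numpy(), dna_total, sd)


def load_melt_csv(path) -> MeltCurve:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    temp = cols.get("temp_c") or cols.get("temperature") or df.columns[0]
    fl = cols.get("fluorescence") or df.columns[1]
    return MeltCurve(df[temp].to_numpy(), df[fl].to_numpy())
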