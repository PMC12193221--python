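"""Melt-curve simulation, derivative curves and peak calling.

A saturation-dye melt curve tracks duplex helicity over the instrument ramp
(65 -> 90 C). Each melting transition is modelled as a two-state logistic,

    h_i(T) = 1 / (1 + exp((T - Tm_i) / w_i)),

so h_i(Tm_i) = 1/2 exactly; the fluorescence signal is the weighted sum of
component helicities plus a baseline and optional Gaussian noise. The width
``w_i`` is either a fixed transition width or, in van 't Hoff mode,
R * Tm_i(K)^2 / |dH_i| from the component's enthalpy. The default width of
0.25 C matches the van 't Hoff width of a ~100 bp amplicon (~0.3 C) and
keeps transitions 1 C apart resolvable, as they are on the instrument.

The derivative curve is -dF/dT: local polynomial (Savitzky-Golay) smoothing
followed by central finite differences over a +/- 0.1 C stencil (plain
adjacent-point differences on a 0.01 C grid amplify high-frequency noise
that Savitzky-Golay filters pass largely unattenuated).

Peak calling runs in two stages: candidate transitions are counted on a
more heavily smoothed copy of the derivative (local maxima above a relative
prominence floor, with peaks closer than 0.1 C merged to the higher one --
the instrument never reports peaks that close), then each candidate Tm is
refined by a joint least-squares fit of two-state transition shapes
(sech^2 components) to the derivative, which recovers planted Tms to the
instrument's +/- 0.02 C resolution under realistic noise.

Multi-peak species (seen for some primer/species combinations) are simulated
as mixtures of transitions; no mechanistic claim is made about what produces
the extra transitions in real amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .thermo import R_GAS

__all__ = [
    "MeltConfig",
    "MeltCurve",
    "Peak",
    "PeakSet",
    "simulate_melt",
    "derivative_curve",
    "call_peaks",
]


@dataclass(frozen=True)
class MeltConfig:
    """Ramp window, grid, noise and transition-shape settings.

    The 0.01 C analysis grid keeps the instrument's +/- 0.02 C resolution
    representable; the instrument's 0.1 C/s is a ramp *rate*, not a grid.
    """

    t_start: float = 65.0
    t_end: float = 90.0
    t_step: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0
    transition_width: float | str = 0.25  # C, or "vantHoff"
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.transition_width, str):
            if self.transition_width != "vantHoff":
                raise ValueError("transition_width must be a float or 'vantHoff'")
        elif self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


@dataclass(frozen=True)
class MeltCurve:
    """A temperature grid and a same-length fluorescence (or -dF/dT) series."""

    temps: np.ndarray
    fluor: np.ndarray

    def __post_init__(self) -> None:
        if len(self.temps) != len(self.fluor):
            raise ValueError("temps and fluor lengths differ")
        steps = np.diff(self.temps)
        if len(steps) and (np.any(steps <= 0)
                           or not np.allclose(steps, steps[0], atol=1e-9)):
            raise ValueError("temperature grid must ascend with constant step")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def t_step(self) -> float:
        return float(self.temps[1] - self.temps[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature_c": self.temps, "fluorescence": self.fluor}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeltCurve":
        return cls(np.asarray(df["temperature_c"], dtype=float),
                   np.asarray(df["fluorescence"], dtype=float))


@dataclass(frozen=True)
class Peak:
    tm: float
    height: float
    prominence: float


@dataclass(frozen=True)
class PeakSet:
    """Called derivative-curve peaks, ascending by Tm."""

    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def tms(self) -> tuple[float, ...]:
        return tuple(p.tm for p in self.peaks)

    @property
    def principal(self) -> Peak:
        """The highest peak (the signature's dominant transition)."""
        if not self.peaks:
            raise ValueError("empty peak set has no principal peak")
        return max(self.peaks, key=lambda p: p.height)


def _component_widths(components, config: MeltConfig) -> list[float]:
    widths = []
    for comp in components:
        if config.transition_width == "vantHoff":
            if len(comp) < 3:
                raise ValueError(
                    "vantHoff mode needs (tm, weight, dH_kcal_per_mol) components"
                )
            tm_k = comp[0] + 273.15
            widths.append(R_GAS * tm_k**2 / (abs(comp[2]) * 1000.0))
        else:
            widths.append(float(config.transition_width))
    return widths


def simulate_melt(components, config: MeltConfig | None = None) -> MeltCurve:
    """Simulate a melt curve from (tm, weight[, dH]) components.

    Every component Tm must lie inside the ramp window and every weight must
    be positive. The same seed reproduces the identical curve.
    """
    config = config or MeltConfig()
    comps = [tuple(c) for c in components]
    if not comps:
        raise ValueError("need at least one melt component")
    for c in comps:
        tm, weight = c[0], c[1]
        if not config.t_start < tm < config.t_end:
            raise ValueError(
                f"component tm {tm} outside ramp window "
                f"({config.t_start}, {config.t_end})"
            )
        if weight <= 0:
            raise ValueError("component weights must be > 0")

    temps = config.grid()
    widths = _component_widths(comps, config)
    fluor = np.full_like(temps, config.baseline, dtype=float)
    for (tm, weight, *_), w in zip(comps, widths):
        fluor = fluor + weight / (1.0 + np.exp((temps - tm) / w))
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=temps.shape)
    return MeltCurve(temps=temps, fluor=fluor)


def derivative_curve(
    curve: MeltCurve,
    smooth_window: int = 51,
    smooth_degree: int = 3,
    stencil: int = 10,
) -> MeltCurve:
    """-dF/dT via Savitzky-Golay smoothing + central finite differences.

    ``stencil`` is the half-width, in grid points, of the central-difference
    stencil (0.1 C on the default grid). The output grid drops the margin
    where smoothing or difference stencils are incomplete.
    """
    n = len(curve)
    if smooth_window > n:
        raise ValueError(f"smooth_window {smooth_window} exceeds series length {n}")
    if smooth_degree >= smooth_window:
        raise ValueError("smooth_degree must be < smooth_window")
    if not 1 <= stencil < n // 2:
        raise ValueError("stencil must be >= 1 and fit the series")
    smoothed = savgol_filter(curve.fluor, smooth_window, smooth_degree)
    deriv = np.empty(n)
    h = stencil * curve.t_step
    deriv[stencil:n - stencil] = -(
        smoothed[2 * stencil:] - smoothed[:n - 2 * stencil]
    ) / (2.0 * h)
    margin = max(smooth_window // 2, stencil)
    sl = slice(margin, n - margin)
    return MeltCurve(temps=curve.temps[sl], fluor=deriv[sl])


def _transition_mixture(T: np.ndarray, *params: float) -> np.ndarray:
    """Sum of two-state transition derivative shapes A * sech^2((T-tm)/2w)."""
    out = np.zeros_like(T)
    for i in range(len(params) // 3):
        amp, tm, w = params[3 * i:3 * i + 3]
        u = np.clip((T - tm) / (2.0 * w), -300.0, 300.0)
        out = out + amp / np.cosh(u) ** 2
    return out


def _fit_mixture(T: np.ndarray, D: np.ndarray, tms: list[float]):
    """Least-squares fit of a sech^2 mixture anchored at candidate Tms.

    Returns (amp, tm, width) per component, or None on failure.
    """
    p0: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    amp_cap = 3.0 * max(float(D.max()), 1e-6)
    for tm in tms:
        amp = min(max(float(D[np.argmin(np.abs(T - tm))]), 1e-6), amp_cap)
        p0 += [amp, tm, 0.3]
        lb += [0.0, tm - 0.6, 0.05]
        ub += [amp_cap, tm + 0.6, 5.0]
    try:
        popt, _ = curve_fit(_transition_mixture, T, D, p0=p0,
                            bounds=(lb, ub), maxfev=10000)
    except (RuntimeError, ValueError):
        return None
    return [(float(popt[3 * i]), float(popt[3 * i + 1]),
             float(popt[3 * i + 2])) for i in range(len(tms))]


def _residual_transition(T: np.ndarray, resid: np.ndarray, floor: float,
                         edge_margin: float = 0.3) -> float | None:
    """Largest unmodelled bump in a fit residual, if significant.

    The residual is smoothed and its maximum compared against both the
    relative amplitude floor and a 6-sigma robust noise bound, so only a
    genuine missed transition (e.g. a shoulder swallowed by smoothing at the
    counting stage) triggers another component. Bumps within
    ``edge_margin`` C of the fitted region's edges are ignored: they are
    window artifacts, not transitions.
    """
    if len(resid) < 51:
        return None
    rs = savgol_filter(resid, 51, 2)
    sigma = 1.4826 * np.median(np.abs(rs - np.median(rs)))
    interior = np.ones(len(T), dtype=bool)
    gap = np.flatnonzero(np.diff(T) > 1.5 * (T[1] - T[0]))
    edges = np.concatenate(([T[0]], T[gap], T[gap + 1], [T[-1]]))
    for e in edges:
        interior &= np.abs(T - e) >= edge_margin
    if not interior.any():
        return None
    i = int(np.argmax(np.where(interior, rs, -np.inf)))
    if rs[i] >= max(floor, 7.0 * sigma):
        return float(T[i])
    return None


def _refine_peaks(
    temps: np.ndarray, deriv: np.ndarray, coarse: list[float],
    min_amp_frac: float, merge_radius: float, fit_halfwidth: float = 1.5,
) -> list[tuple[float, float]]:
    """Validate and refine candidate Tms by joint sech^2 mixture fitting.

    Starting from the counted candidates, fits the mixture, greedily adds up
    to two components where the residual shows a significant unmodelled
    transition, and finally drops components whose amplitude falls under
    ``min_amp_frac`` of the largest or whose width is below 0.08 C (narrower
    than any real amplicon transition; a noise spike). Returns (tm,
    amplitude) pairs; on fit failure the coarse candidates are returned
    unrefined.
    """
    tms = list(coarse)
    comps = None
    for _ in range(3):  # initial fit + at most two added components
        mask = np.zeros(len(temps), dtype=bool)
        for tm in tms:
            mask |= np.abs(temps - tm) <= fit_halfwidth
        T, D = temps[mask], deriv[mask]
        fitted = _fit_mixture(T, D, tms)
        if fitted is None:
            break
        comps = fitted
        amp_max = max(a for a, _, _ in comps)
        resid = D - _transition_mixture(T, *np.ravel(comps))
        # the add-floor sits above the ~8% side lobes a smoothed transition
        # leaves around its own fit, but below the smallest real component
        extra = _residual_transition(T, resid, 0.08 * amp_max)
        if extra is None or any(abs(extra - tm) < 2 * merge_radius
                                for _, tm, _ in comps):
            break
        tms = sorted([tm for _, tm, _ in comps] + [extra])
    if comps is None:
        amp = [float(deriv[np.argmin(np.abs(temps - tm))]) for tm in coarse]
        return list(zip(coarse, amp))
    amp_max = max(a for a, _, _ in comps)
    out = []
    for i, (amp, tm, width) in enumerate(comps):
        if amp < min_amp_frac * amp_max or width < 0.08:
            continue
        if abs(tm - tms[i]) > 0.5:
            tm = tms[i]
        out.append((tm, amp))
    return sorted(out)


def call_peaks(
    deriv_curve: MeltCurve,
    min_prominence_frac: float = 0.05,
    merge_radius: float = 0.1,
    count_window: int = 21,
    count_degree: int = 2,
) -> PeakSet:
    """Call melt peaks from a derivative curve.

    Candidate transitions are local maxima of a further-smoothed copy of the
    derivative that reach ``min_prominence_frac`` of the global maximum in
    either prominence or height (prominence alone under-scores a real
    transition sitting on the shoulder of a larger one); candidates within
    ``merge_radius`` C of a higher one are merged away. Candidates are then
    validated and their Tms refined by a joint two-state-shape fit to the
    unsmoothed derivative, and reported at grid resolution. A flat curve
    yields an empty peak set.
    """
    y = deriv_curve.fluor
    step = deriv_curve.t_step
    cw = min(count_window, len(y) if len(y) % 2 else len(y) - 1)
    ys = savgol_filter(y, cw, min(count_degree, cw - 1)) if cw > 2 else y
    idx, _ = find_peaks(ys)
    if len(idx) == 0:
        return PeakSet(())
    prominences = peak_prominences(ys, idx)[0]
    # numerically flat input: float-epsilon ripple is not a melt transition
    if prominences.max() < 1e-9:
        return PeakSet(())
    floor = min_prominence_frac * prominences.max()
    height_floor = min_prominence_frac * ys[idx].max()
    keep = (prominences >= floor) | (ys[idx] >= height_floor)
    idx, prominences = idx[keep], prominences[keep]

    order = np.argsort(ys[idx])[::-1]  # by smoothed height, descending
    kept: list[int] = []
    for o in order:
        t = deriv_curve.temps[idx[o]]
        if all(abs(t - deriv_curve.temps[idx[k]]) >= merge_radius for k in kept):
            kept.append(o)
    kept.sort(key=lambda o: deriv_curve.temps[idx[o]])
    coarse = [float(deriv_curve.temps[idx[o]]) for o in kept]

    peaks = []
    for tm, amp in _refine_peaks(deriv_curve.temps, y, coarse,
                                 min_prominence_frac, merge_radius):
        tm_grid = float(np.round(tm / step) * step)
        tm_grid = min(max(tm_grid, float(deriv_curve.temps[0])),
                      float(deriv_curve.temps[-1]))
        # report the counted maximum's height/prominence where one backs
        # this transition; fitted amplitude otherwise (residual-recovered)
        near = [o for o in kept
                if abs(deriv_curve.temps[idx[o]] - tm) <= 2 * merge_radius]
        if near:
            o = max(near, key=lambda o: ys[idx[o]])
            height, prom = float(ys[idx[o]]), float(prominences[o])
        else:
            height = prom = float(amp)
        peaks.append(Peak(tm=tm_grid, height=height, prominence=prom))
    peaks.sort(key=lambda p: p.tm)
    return PeakSet(tuple(peaks))
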