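"""Linear-combination modelling of short-echo spectra with CRLB screening.

A measured spectrum S(nu) is modelled over the fit window as

    S(nu) = sum_m A_m * B_m(nu - dppm; sigma_g)  +  baseline(nu)

where B_m are the rendered basis spectra, dppm a global frequency shift,
sigma_g a Gaussian broadening applied to the basis (Voigt lineshape by
convolution), and the baseline a cubic B-spline with ~0.3 ppm knots.  The
problem is separable: for fixed (dppm, sigma_g) the amplitudes and spline
coefficients solve a bound-constrained linear least squares (A_m >= 0,
spline free), leaving a 2-parameter nonlinear search.

Per-metabolite Cramér–Rao lower bounds are computed from the Jacobian of
the full model (amplitudes + baseline + nonlinear parameters) and expressed
as a percentage of the fitted amplitude; metabolites are screened at
CRLB < 20% before group analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear, minimize

from .acquisition import AcquisitionParams
from .basis import BasisSet

_SQRT8LN2 = np.sqrt(8.0 * np.log(2.0))


class GridError(ValueError):
    pass


@dataclass
class Spectrum:
    """Frequency-domain spectrum on an ascending, uniform ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    acq: AcquisitionParams
    id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        steps = np.diff(self.ppm)
        if np.any(steps <= 0):
            raise ValueError("ppm grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("ppm grid must be uniform")

    @property
    def ppm_step(self) -> float:
        return float(self.ppm[1] - self.ppm[0])


@dataclass(frozen=True)
class FitConfig:
    """Controls for the linear-combination fit (LCModel-analogue knobs)."""

    fit_window_ppm: tuple[float, float] = (0.5, 4.2)
    baseline_knot_spacing_ppm: float = 0.3
    max_shift_ppm: float = 0.05
    max_gauss_broaden_hz: float = 15.0
    noise_region_ppm: tuple[float, float] = (9.0, 10.0)
    fit_baseline: bool = True
    fit_shift: bool = True
    fit_broaden: bool = True
    allow_resample: bool = False
    snr_floor: float = 3.0  # below this the spectrum is flagged as no-signal


@dataclass
class QualityMetrics:
    """Spectral quality: linewidth of the NAA 2.01-ppm singlet and S/N."""

    fwhm_ppm: float
    snr: float
    low_signal: bool = False


@dataclass
class SpectralFitResults:
    """Outcome of a linear-combination fit.

    Amplitudes are in mmol/L-equivalent units under the basis normalisation
    (unit basis amplitude corresponds to 1 mmol/L).  ``crlb_pct`` maps each
    metabolite to 100 * CRLB / amplitude (infinite at zero amplitude).
    """

    amplitudes: dict[str, float]
    crlb_pct: dict[str, float]
    shift_ppm: float
    gauss_broaden_hz: float
    baseline_coeffs: np.ndarray
    residual: np.ndarray
    fitted: np.ndarray
    noise_sd: float
    rss: float
    rank_deficient: bool
    crlb_available: bool
    window_ppm: np.ndarray
    model: "SpectralFitModel" = field(repr=False, default=None)

    def screen(self, threshold_pct: float = 20.0):
        return screen_crlb(self.amplitudes, self.crlb_pct, threshold_pct)

    def baseline(self) -> np.ndarray:
        """Fitted baseline over the window."""
        m = self.model
        if m.spline_design is None:
            return np.zeros_like(self.window_ppm)
        return m.spline_design @ self.baseline_coeffs

    def summary(self) -> str:
        lines = [
            "Linear-combination spectral fit",
            "===============================",
            f"window:        {self.model.config.fit_window_ppm} ppm "
            f"({len(self.window_ppm)} points)",
            f"shift:         {self.shift_ppm:+.4f} ppm",
            f"broadening:    {self.gauss_broaden_hz:.2f} Hz (Gaussian)",
            f"noise sd:      {self.noise_sd:.4g}",
            f"RSS:           {self.rss:.4g}",
            "",
            f"{'metabolite':<12}{'amplitude':>12}{'CRLB %':>10}",
        ]
        for name, amp in sorted(self.amplitudes.items()):
            crlb = self.crlb_pct.get(name, np.inf)
            crlb_s = f"{crlb:10.1f}" if np.isfinite(crlb) else "       inf"
            lines.append(f"{name:<12}{amp:>12.3f}{crlb_s}")
        if self.rank_deficient:
            lines.append("WARNING: rank-deficient design (collinear basis)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data, fit, baseline and residual over the fit window (QC plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.fitted + self.residual
        ax.plot(self.window_ppm, data, color="0.6", lw=0.8, label="data")
        ax.plot(self.window_ppm, self.fitted, "r-", lw=1.0, label="fit")
        ax.plot(self.window_ppm, self.baseline(), "b--", lw=0.8, label="baseline")
        off = 1.1 * data.max() if data.size else 0.0
        ax.plot(self.window_ppm, self.residual + off, "k-", lw=0.6, label="residual")
        ax.invert_xaxis()  # display convention: ppm decreasing left to right
        ax.set_xlabel("ppm")
        ax.legend()
        return ax


def gaussian_broaden(spec: np.ndarray, fwhm_ppm: float, ppm_step: float) -> np.ndarray:
    """Convolve with a unit-area Gaussian of the given FWHM (ppm units)."""
    if fwhm_ppm <= 0:
        return spec
    sigma = fwhm_ppm / _SQRT8LN2
    half = max(int(np.ceil(5 * sigma / ppm_step)), 1)
    x = np.arange(-half, half + 1) * ppm_step
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    return np.convolve(spec, kernel, mode="same")


class SpectralFitModel:
    """Separable linear-combination model of one spectrum against a basis."""

    def __init__(
        self,
        spectrum: Spectrum,
        basis: BasisSet,
        config: FitConfig | None = None,
        metabolites: Sequence[str] | None = None,
    ):
        self.spectrum = spectrum
        self.basis = basis
        self.config = config or FitConfig()
        self.names = (
            list(metabolites) if metabolites is not None else basis.metabolite_names()
        )
        bgrid = basis.ppm
        if len(bgrid) != len(spectrum.ppm) or not np.allclose(bgrid, spectrum.ppm):
            if bgrid[0] > spectrum.ppm[-1] or bgrid[-1] < spectrum.ppm[0]:
                raise GridError("basis grid does not overlap the spectrum grid")
            if not self.config.allow_resample:
                raise GridError(
                    "basis grid differs from spectrum grid; pass "
                    "FitConfig(allow_resample=True) to interpolate"
                )
            self._basis_cols = np.column_stack(
                [
                    np.interp(spectrum.ppm, bgrid, basis.rendered[n])
                    for n in self.names
                ]
            )
        else:
            self._basis_cols = basis.matrix(self.names)
        lo, hi = self.config.fit_window_ppm
        if lo < spectrum.ppm[0] or hi > spectrum.ppm[-1]:
            raise GridError("fit window extends beyond the spectrum grid")
        self.window = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
        self.window_ppm = spectrum.ppm[self.window]
        self.spline_design = (
            self._make_spline_design() if self.config.fit_baseline else None
        )
        nlo, nhi = self.config.noise_region_ppm
        if nlo < spectrum.ppm[0] or nhi > spectrum.ppm[-1]:
            raise GridError("noise region outside the spectrum grid")
        self._noise_mask = (spectrum.ppm >= nlo) & (spectrum.ppm <= nhi)

    # -- design assembly ---------------------------------------------------

    def _make_spline_design(self) -> np.ndarray:
        lo, hi = self.config.fit_window_ppm
        spacing = self.config.baseline_knot_spacing_ppm
        if spacing <= self.spectrum.ppm_step:
            raise ValueError("baseline knot spacing must exceed the grid step")
        n_int = max(int(np.floor((hi - lo) / spacing)) - 1, 0)
        interior = np.linspace(lo, hi, n_int + 2)[1:-1]
        k = 3
        t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
        x = np.clip(self.window_ppm, lo, np.nextafter(hi, lo))
        return BSpline.design_matrix(x, t, k).toarray()

    def _transformed_basis(self, shift_ppm: float, gauss_hz: float) -> np.ndarray:
        """Basis columns broadened, shifted, and restricted to the window."""
        cols = self._basis_cols
        step = self.spectrum.ppm_step
        if gauss_hz > 0:
            fwhm_ppm = gauss_hz / self.spectrum.acq.hz_per_ppm
            cols = np.column_stack(
                [gaussian_broaden(cols[:, j], fwhm_ppm, step) for j in range(cols.shape[1])]
            )
        if shift_ppm != 0.0:
            grid = self.spectrum.ppm
            cols = np.column_stack(
                [
                    np.interp(grid - shift_ppm, grid, cols[:, j])
                    for j in range(cols.shape[1])
                ]
            )
        return cols[self.window]

    def _design(self, shift_ppm: float, gauss_hz: float) -> np.ndarray:
        met = self._transformed_basis(shift_ppm, gauss_hz)
        if self.spline_design is None:
            return met
        return np.hstack([met, self.spline_design])

    def _linear_solve(self, design: np.ndarray, y: np.ndarray):
        m = len(self.names)
        nb = design.shape[1] - m
        lb = np.r_[np.zeros(m), np.full(nb, -np.inf)]
        ub = np.full(design.shape[1], np.inf)
        res = lsq_linear(design, y, bounds=(lb, ub), method="bvls")
        rss = float(np.sum(res.fun**2))
        return res.x, rss

    # -- fitting -----------------------------------------------------------

    def fit(self) -> SpectralFitResults:
        y = self.spectrum.intensity[self.window]
        cfg = self.config

        def objective(p):
            shift = float(np.clip(p[0], -cfg.max_shift_ppm, cfg.max_shift_ppm))
            gauss = float(np.clip(p[1], 0.0, cfg.max_gauss_broaden_hz))
            _, rss = self._linear_solve(self._design(shift, gauss), y)
            return rss

        shift, gauss = 0.0, 0.0
        if cfg.fit_shift or cfg.fit_broaden:
            shifts = (
                np.linspace(-cfg.max_shift_ppm, cfg.max_shift_ppm, 3)
                if cfg.fit_shift
                else [0.0]
            )
            gausses = (
                np.linspace(0.0, cfg.max_gauss_broaden_hz, 4)
                if cfg.fit_broaden
                else [0.0]
            )
            best = (np.inf, 0.0, 0.0)
            for s in shifts:
                for g in gausses:
                    r = objective([s, g])
                    if r < best[0]:
                        best = (r, s, g)
            _, shift, gauss = best
            res = minimize(
                objective,
                x0=[shift, gauss],
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 120},
            )
            shift = float(np.clip(res.x[0], -cfg.max_shift_ppm, cfg.max_shift_ppm))
            gauss = float(np.clip(res.x[1], 0.0, cfg.max_gauss_broaden_hz))
            if not cfg.fit_shift:
                shift = 0.0
            if not cfg.fit_broaden:
                gauss = 0.0

        design = self._design(shift, gauss)
        coeffs, rss = self._linear_solve(design, y)
        m = len(self.names)
        rank_deficient = np.linalg.matrix_rank(design) < design.shape[1]
        if rank_deficient:
            warnings.warn("rank-deficient fit design (collinear columns)", stacklevel=2)
        fitted = design @ coeffs
        residual = y - fitted
        noise_sd = self.estimate_noise_sd()
        amplitudes = {n: float(coeffs[j]) for j, n in enumerate(self.names)}
        result = SpectralFitResults(
            amplitudes=amplitudes,
            crlb_pct={},
            shift_ppm=shift,
            gauss_broaden_hz=gauss,
            baseline_coeffs=coeffs[m:],
            residual=residual,
            fitted=fitted,
            noise_sd=noise_sd,
            rss=rss,
            rank_deficient=rank_deficient,
            crlb_available=True,
            window_ppm=self.window_ppm,
            model=self,
        )
        if noise_sd > 0:
            result.crlb_pct = compute_crlb(result)
        else:  # noiseless input: bounds are zero / undefined, not computable
            result.crlb_pct = {n: np.inf for n in self.names}
            result.crlb_available = False
        return result

    # -- diagnostics -------------------------------------------------------

    def estimate_noise_sd(self) -> float:
        """Noise sigma from the metabolite-free 9-10 ppm region.

        A linear trend is removed so residual baseline roll does not inflate
        the estimate.
        """
        x = self.spectrum.ppm[self._noise_mask]
        v = self.spectrum.intensity[self._noise_mask]
        trend = np.polyval(np.polyfit(x, v, 1), x)
        return float(np.std(v - trend, ddof=2))

    def jacobian(self, result: "SpectralFitResults") -> np.ndarray:
        """Jacobian of the full model at the fitted point.

        Columns: one per metabolite amplitude, one per spline coefficient,
        plus (when fitted) the frequency shift and Gaussian broadening,
        computed by central finite differences of the composed model.
        """
        shift, gauss = result.shift_ppm, result.gauss_broaden_hz
        design = self._design(shift, gauss)
        cols = [design]
        amps = np.array([result.amplitudes[n] for n in self.names])

        def model_at(s, g):
            met = self._transformed_basis(s, g)
            out = met @ amps
            if self.spline_design is not None:
                out = out + self.spline_design @ result.baseline_coeffs
            return out

        if self.config.fit_shift:
            h = 1e-4
            cols.append(((model_at(shift + h, gauss) - model_at(shift - h, gauss)) / (2 * h))[:, None])
        if self.config.fit_broaden:
            h = 1e-2
            g_lo = max(gauss - h, 0.0)
            cols.append(((model_at(shift, gauss + h) - model_at(shift, g_lo)) / (gauss + h - g_lo))[:, None])
        return np.hstack(cols)


def fit_linear_combination(
    spectrum: Spectrum, basis: BasisSet, config: FitConfig | None = None
) -> SpectralFitResults:
    """Functional wrapper around ``SpectralFitModel(...).fit()``."""
    return SpectralFitModel(spectrum, basis, config).fit()


def crlb_from_jacobian(J: np.ndarray, noise_sd: float) -> np.ndarray:
    """CRLB_i = noise_sd * sqrt([(J^T J)^-1]_ii) for each model parameter.

    Returns infinities when the information matrix is numerically singular.
    """
    jtj = J.T @ J
    try:
        cov = np.linalg.inv(jtj)
        diag = np.diag(cov)
        if np.any(diag < 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.inf)
    return noise_sd * np.sqrt(diag)


def compute_crlb(result: SpectralFitResults) -> dict[str, float]:
    """Percent CRLBs for each metabolite amplitude of a fit.

    The information matrix includes baseline and nonlinear parameters
    (conservative).  Zero amplitudes get an infinite percent bound; a
    singular information matrix flags CRLBs as unavailable on the result.
    """
    model = result.model
    if result.noise_sd <= 0:
        raise ValueError("CRLB requires a positive noise estimate")
    J = model.jacobian(result)
    crlb = crlb_from_jacobian(J, result.noise_sd)
    if not np.all(np.isfinite(crlb[: len(model.names)])):
        result.crlb_available = False
    out = {}
    for j, name in enumerate(model.names):
        amp = result.amplitudes[name]
        out[name] = float(100.0 * crlb[j] / amp) if amp > 0 and np.isfinite(crlb[j]) else np.inf
    return out


def screen_crlb(
    amplitudes: Mapping[str, float],
    crlb_pct: Mapping[str, float],
    threshold_pct: float = 20.0,
) -> tuple[dict[str, float], list[str]]:
    """Retain metabolites with CRLB strictly below the threshold.

    Returns (retained amplitude mapping, sorted list of excluded names);
    exclusions are enumerated, never silently dropped.
    """
    if set(amplitudes) != set(crlb_pct):
        raise ValueError("amplitude and CRLB mappings must share keys")
    retained = {
        n: a for n, a in amplitudes.items() if crlb_pct[n] < threshold_pct
    }
    excluded = sorted(set(amplitudes) - set(retained))
    return retained, excluded


def quality_metrics(
    spectrum: Spectrum, result: SpectralFitResults, config: FitConfig | None = None
) -> QualityMetrics:
    """Linewidth and S/N of a fitted spectrum.

    FWHM is measured on the fitted NAA 2.01-ppm acetyl singlet (the
    standard linewidth reference); S/N is the maximum baseline-subtracted
    fitted signal over twice the RMS noise.
    """
    config = config or result.model.config
    model = result.model
    if "NAA" not in result.amplitudes:
        raise ValueError("quality metrics need NAA in the fitted basis")
    met = model._transformed_basis(result.shift_ppm, result.gauss_broaden_hz)
    j = model.names.index("NAA")
    naa = result.amplitudes["NAA"] * met[:, j]
    ppm = model.window_ppm
    peak_mask = (ppm > 1.85) & (ppm < 2.15)
    try:
        fwhm = _fwhm_of_peak(ppm[peak_mask], naa[peak_mask])
    except ValueError:  # vanished NAA component (e.g. pure-noise input)
        fwhm = np.nan
    noise_rms = np.sqrt(np.mean(
        (spectrum.intensity[model._noise_mask]
         - np.mean(spectrum.intensity[model._noise_mask])) ** 2
    ))
    signal = result.fitted - result.baseline()
    snr = float(np.max(signal) / (2.0 * noise_rms)) if noise_rms > 0 else np.inf
    return QualityMetrics(fwhm_ppm=fwhm, snr=snr, low_signal=snr < config.snr_floor)


def _fwhm_of_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    if len(x) < 3 or np.max(y) <= 0:
        raise ValueError("no peak found for FWHM measurement")
    k = int(np.argmax(y))
    half = y[k] / 2.0
    # walk left
    i = k
    while i > 0 and y[i] > half:
        i -= 1
    left = np.interp(half, [y[i], y[i + 1]], [x[i], x[i + 1]]) if i < k else x[0]
    # walk right
    i = k
    while i < len(y) - 1 and y[i] > half:
        i += 1
    right = (
        np.interp(half, [y[i], y[i - 1]], [x[i], x[i - 1]]) if i > k else x[-1]
    )
    return float(right - left)
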