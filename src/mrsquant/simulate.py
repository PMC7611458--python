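"""Synthetic cohort generator for the lesion/NAWM MRS study design.

Emulates the statistical structure the downstream analysis assumes: two
disease groups (11 relapsing-remitting MS, 4 AQP4Ab-NMOSD subjects), two
voxels per subject (chronic white-matter lesion and contralateral NAWM),
per-voxel true metabolite concentrations drawn from truncated normals at
the group/site means, tissue-water T2 higher in lesions than NAWM, CSF
fractions, spectral quality targets (FWHM ~0.03 ppm, S/N ~26-28), and an
EDSS disability score constructed so that NAWM Ins:NAA correlates with
EDSS at a configurable target (default r = 0.55).

The generator produces what a post-processed acquisition would deliver —
phased frequency-domain spectra and multi-TE water integrals — not raw
FIDs, coil data or frequency drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, truncnorm

from .basis import BasisSet
from .specfit import Spectrum
from .waterfit import WaterSeries

GROUPS = ("MS", "NMOSD")
SITES = ("lesion", "nawm")

#: Plausible white-matter concentrations (mmol/L) for compounds whose
#: group/site profiles are not study-specific; applied to every cell.
_BASE_PROFILE = {
    "Ala": 0.5, "Asp": 2.0, "Asc": 1.0, "GPC": 1.3, "PCho": 0.6,
    "Cr": 4.5, "PCr": 4.0, "GABA": 1.3, "Glc": 1.0, "Gln": 2.5,
    "Glu": 7.5, "GSH": 1.5, "Lac": 0.8, "PE": 1.5, "sIns": 0.3,
    "Tau": 1.5,
}

#: Study-specific group x site profiles (mean, sd) for the metabolites of
#: interest: myo-inositol, NAA and NAAG.
_STUDY_PROFILE = {
    ("MS", "lesion"): {"Ins": (8.1, 1.4), "NAA": (8.94, 1.1), "NAAG": (2.09, 0.6)},
    ("MS", "nawm"): {"Ins": (7.28, 1.2), "NAA": (9.69, 0.9), "NAAG": (2.55, 0.9)},
    ("NMOSD", "lesion"): {"Ins": (7.86, 1.3), "NAA": (7.9, 2.2), "NAAG": (1.5, 0.2)},
    ("NMOSD", "nawm"): {"Ins": (7.23, 0.8), "NAA": (8.69, 0.7), "NAAG": (2.19, 0.3)},
}

_T2_DEFAULTS = {  # (mean, sd) ms
    ("MS", "lesion"): (43.3, 2.7),
    ("NMOSD", "lesion"): (44.7, 2.7),
    ("MS", "nawm"): (40.1, 2.9),
    ("NMOSD", "nawm"): (39.3, 1.6),
}

_DEMOGRAPHICS = {  # group -> (duration mean, sd), (lesion-age mean, sd), EDSS centre
    "MS": ((6.8, 5.5), (36.0, 33.3), 2.0),
    "NMOSD": ((8.9, 3.2), (86.6, 27.1), 3.5),
}


class ConfigError(ValueError):
    pass


def default_conc_means() -> dict[tuple[str, str, str], float]:
    out = {}
    for g in GROUPS:
        for s in SITES:
            for m, v in _BASE_PROFILE.items():
                out[(g, s, m)] = v
            for m, (mean, _) in _STUDY_PROFILE[(g, s)].items():
                out[(g, s, m)] = mean
    return out


def default_conc_sds(rel_sd: float = 0.15) -> dict[tuple[str, str, str], float]:
    out = {}
    for g in GROUPS:
        for s in SITES:
            for m, v in _BASE_PROFILE.items():
                out[(g, s, m)] = rel_sd * v
            for m, (_, sd) in _STUDY_PROFILE[(g, s)].items():
                out[(g, s, m)] = sd
    return out


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_ms: int = 11
    n_nmo: int = 4
    sites: tuple[str, str] = SITES
    conc_means: dict = field(default_factory=default_conc_means)
    conc_sds: dict = field(default_factory=default_conc_sds)
    t2_tissue_means: dict = field(
        default_factory=lambda: {k: v[0] for k, v in _T2_DEFAULTS.items()}
    )
    t2_tissue_sds: dict = field(
        default_factory=lambda: {k: v[1] for k, v in _T2_DEFAULTS.items()}
    )
    csf_fraction_range: tuple[float, float] = (0.02, 0.12)
    target_snr: dict = field(default_factory=lambda: {"lesion": 25.7, "nawm": 28.3})
    target_fwhm_ppm: float = 0.03
    edss_ins_naa_r: float = 0.55
    within_subject_rho: float = 0.3  # lesion/NAWM concentration correlation
    baseline_amp_frac: float = 0.1  # MM hump peak relative to signal peak
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.conc_sds.values()):
            raise ConfigError("concentration SDs must be non-negative")
        if any(sd < 0 for sd in self.t2_tissue_sds.values()):
            raise ConfigError("T2 SDs must be non-negative")
        lo, hi = self.csf_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("csf_fraction_range must lie within [0, 1)")
        if abs(self.edss_ins_naa_r) > 1.0:
            raise ConfigError("|edss_ins_naa_r| must be <= 1")
        if abs(self.within_subject_rho) > 1.0:
            raise ConfigError("|within_subject_rho| must be <= 1")


@dataclass
class SubjectRecord:
    """Ground truth for one synthetic subject (both voxels)."""

    subject_id: str
    group: str
    edss: float
    disease_duration_yrs: float
    lesion_age_months: float
    true_conc: dict[str, dict[str, float]]  # site -> metabolite -> mmol/L
    true_t2_ms: dict[str, float]
    true_csf_fraction: dict[str, float]


def _truncnorm_ppf(u: float, mean: float, sd: float, lower: float = 0.0) -> float:
    """Quantile of a normal truncated below at ``lower`` (degenerate at sd=0)."""
    if sd == 0:
        return mean
    a = (lower - mean) / sd
    return float(truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd))


def _draw_truncnorm(rng, mean, sd, lower=0.0):
    return _truncnorm_ppf(rng.uniform(), mean, sd, lower)


def make_cohort(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Draw a cohort of subjects with correlated lesion/NAWM concentrations
    and an EDSS constructed to track NAWM Ins:NAA.

    Deterministic given ``config.seed``.  Concentration marginals are
    normals truncated at zero (Gaussian copula carries the within-subject
    lesion/NAWM correlation); EDSS is a monotone transform of a noisy
    linear function of the standardized Ins:NAA ratio, rounded to the
    ordinal 0.5-point scale.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    rho = config.within_subject_rho
    r = config.edss_ins_naa_r

    metabolites = sorted({m for (_, _, m) in config.conc_means})
    records: list[SubjectRecord] = []
    groups = ["MS"] * config.n_ms + ["NMOSD"] * config.n_nmo
    for i, group in enumerate(groups):
        subject_id = f"{'ms' if group == 'MS' else 'nmo'}{i + 1:02d}"
        conc: dict[str, dict[str, float]] = {s: {} for s in config.sites}
        for m in metabolites:
            z_shared = rng.standard_normal()
            z_l = rho * z_shared + np.sqrt(1 - rho**2) * rng.standard_normal()
            z_n = rho * z_shared + np.sqrt(1 - rho**2) * rng.standard_normal()
            for site, z in zip(config.sites, (z_l, z_n)):
                key = (group, site, m)
                conc[site][m] = _truncnorm_ppf(
                    norm.cdf(z), config.conc_means[key], config.conc_sds[key]
                )
        t2 = {
            site: _draw_truncnorm(
                rng,
                config.t2_tissue_means[(group, site)],
                config.t2_tissue_sds[(group, site)],
                lower=1.0,
            )
            for site in config.sites
        }
        csf = {
            site: float(rng.uniform(*config.csf_fraction_range))
            for site in config.sites
        }
        (dur_m, dur_sd), (age_m, age_sd), _ = _DEMOGRAPHICS[group]
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group=group,
                edss=np.nan,  # filled below from the Ins:NAA latent
                disease_duration_yrs=_draw_truncnorm(rng, dur_m, dur_sd, 0.2),
                lesion_age_months=_draw_truncnorm(rng, age_m, age_sd, 3.0),
                true_conc=conc,
                true_t2_ms=t2,
                true_csf_fraction=csf,
            )
        )

    # EDSS from the NAWM Ins:NAA latent: standardize the ratio across the
    # cohort, mix with noise at the target correlation, map onto the 0-10
    # ordinal scale in 0.5 steps.
    if records:
        nawm = config.sites[1]
        x = np.array([s.true_conc[nawm]["Ins"] / s.true_conc[nawm]["NAA"] for s in records])
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        latent = r * z + np.sqrt(1 - r**2) * rng.standard_normal(len(records))
        for s, lat in zip(records, latent):
            centre = _DEMOGRAPHICS[s.group][2]
            edss = np.clip(np.round((centre + 1.8 * lat) * 2.0) / 2.0, 0.0, 10.0)
            s.edss = float(edss)
    return records


def make_water_series(
    t2_tissue_ms: float,
    csf_fraction: float,
    te_grid_ms: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    total_amplitude: float = 1000.0,
    t2_csf_ms: float = 565.0,
    voxel_id: str = "",
) -> WaterSeries:
    """Simulate multi-TE unsuppressed-water integrals.

    Tissue and CSF amplitudes at TE = 0 are ``total_amplitude * (1 - f)``
    and ``total_amplitude * f`` so the configured CSF fraction holds at
    extrapolated TE = 0.  The default TE grid is 12 log-spaced points over
    the 11-4000 ms acquisition span.
    """
    if t2_tissue_ms <= 0:
        raise ValueError("t2_tissue_ms must be positive")
    if not 0.0 <= csf_fraction < 1.0:
        raise ValueError("csf_fraction must be in [0, 1)")
    if te_grid_ms is None:
        te_grid_ms = np.geomspace(11.0, 4000.0, 12)
    te = np.asarray(te_grid_ms, dtype=float)
    if te.min() < 11.0 - 1e-9 or te.max() > 4000.0 + 1e-9:
        raise ValueError("TE grid must lie within the 11-4000 ms span")
    a_c = total_amplitude * csf_fraction
    a_t = total_amplitude - a_c
    integral = a_t * np.exp(-te / t2_tissue_ms) + a_c * np.exp(-te / t2_csf_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        integral = integral + rng.normal(0.0, noise_sd, size=te.shape)
    return WaterSeries(te_ms=te, integral=integral, voxel_id=voxel_id)


def voigt_gaussian_component(total_fwhm_ppm: float, lorentz_fwhm_ppm: float) -> float:
    """Gaussian FWHM needed so a Lorentzian broadened by it reaches the
    target Voigt width (Olivero-Longbothum approximation, inverted)."""
    inner = (total_fwhm_ppm - 0.5346 * lorentz_fwhm_ppm) ** 2 - 0.2166 * lorentz_fwhm_ppm**2
    return float(np.sqrt(max(inner, 0.0)))


def _mm_baseline(ppm: np.ndarray, peak: float) -> np.ndarray:
    """Smooth macromolecule-like background: three broad Gaussian humps."""
    humps = [(0.9, 0.25, 1.0), (1.4, 0.35, 0.8), (2.1, 0.45, 0.6)]
    out = np.zeros_like(ppm)
    for centre, width, rel in humps:
        out += rel * np.exp(-0.5 * ((ppm - centre) / width) ** 2)
    return peak * out


def make_spectrum(
    true_conc: dict[str, float],
    basis: BasisSet,
    target_snr: float | None = None,
    target_fwhm_ppm: float = 0.03,
    baseline_amp: float = 0.0,
    seed: int | None = None,
    scale: float = 1.0,
    noise_sd: float | None = None,
    id: str = "",
) -> Spectrum:
    """Render a synthetic voxel spectrum from true concentrations.

    The noiseless signal is ``scale * sum_m conc_m * basis_m`` broadened by
    the Gaussian component that brings the basis linewidth to the target
    FWHM, plus a smooth macromolecule-style baseline; white Gaussian noise
    is calibrated so the peak-over-noise S/N estimator lands near
    ``target_snr``.  ``scale`` links metabolite-signal units to
    water-integral units (see ``mrsquant.quantify.signal_scale``).
    """
    from .specfit import gaussian_broaden

    missing = sorted(set(true_conc) - set(basis.rendered))
    if missing:
        raise KeyError(f"metabolites missing from basis: {', '.join(missing)}")
    grid = basis.ppm
    signal = np.zeros_like(grid)
    for m, c in true_conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {m}")
        signal += c * basis.rendered[m]
    signal *= scale

    lorentz_ppm = basis.lorentz_fwhm_hz / basis.acq.hz_per_ppm
    gauss_ppm = voigt_gaussian_component(target_fwhm_ppm, lorentz_ppm)
    if gauss_ppm > 0:
        signal = gaussian_broaden(signal, gauss_ppm, basis.acq.ppm_step)

    intensity = signal.copy()
    if baseline_amp > 0:
        intensity = intensity + _mm_baseline(grid, baseline_amp)
    sigma = noise_sd
    if sigma is None and target_snr is not None and target_snr > 0:
        window = (grid >= 0.5) & (grid <= 4.2)
        peak = float(np.max(signal[window])) if np.any(window) else float(np.max(signal))
        sigma = peak / (2.0 * target_snr)
    if sigma is not None and sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sigma, size=grid.shape)
    return Spectrum(ppm=grid, intensity=intensity, acq=basis.acq, id=id)
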