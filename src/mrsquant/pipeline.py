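"""End-to-end orchestration: simulate a cohort to disk, run the
quantification chain (water fit -> spectral fit -> CRLB screen -> absolute
quantification), and produce demographics / quality / concentration /
statistics / correlation report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .basis import BasisSet, default_basis
from .permstats import (
    DegenerateDataError,
    StatTestResult,
    fwer_correct_batch,
    pearson_with_p,
    sign_flip_test,
    permutation_two_sample,
)
from .quantify import (
    QuantConstants,
    absolute_concentration,
    derived_measures,
)
from .simulate import CohortConfig, SubjectRecord, make_cohort, make_spectrum, make_water_series
from .specfit import FitConfig, SpectralFitModel, quality_metrics, screen_crlb
from .waterfit import WaterFitConfig, WaterT2Model

log = logging.getLogger("mrsquant")

#: Metabolites carried into group statistics (the study's analytes).
ANALYSIS_METABOLITES = ("Ins", "NAA", "NAAG", "tNAA")

#: A-priori one-tailed directions.  Within-group tests are on NAWM - lesion
#: differences: tNAA family expected positive in both diseases; Ins expected
#: negative (lesion > NAWM) in MS and positive in NMOSD.  Between-group
#: tests are on MS - NMOSD: Ins in lesions expected positive, the tNAA
#: family in NAWM expected negative (NMOSD > MS).
WITHIN_TAILS = {
    "MS": {"NAA": "greater", "NAAG": "greater", "tNAA": "greater", "Ins": "less"},
    "NMOSD": {"NAA": "greater", "NAAG": "greater", "tNAA": "greater", "Ins": "greater"},
}
BETWEEN_TAILS = {
    "lesion": {"Ins": "greater", "NAA": "greater", "NAAG": "greater", "tNAA": "greater"},
    "nawm": {"Ins": "less", "NAA": "less", "NAAG": "less", "tNAA": "less"},
}


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate/run pipeline in one place."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    water: WaterFitConfig = field(default_factory=WaterFitConfig)
    quant: QuantConstants = field(default_factory=QuantConstants)
    crlb_threshold_pct: float = 20.0
    water_noise_frac: float = 0.005  # water-integral noise relative to TE=0 amplitude
    water_total_amplitude: float = 1000.0
    fwer_method: str = "max_stat"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "crlb_threshold_pct": self.crlb_threshold_pct,
                "water_noise_frac": self.water_noise_frac,
                "seed": self.seed,
                "quant_te": self.quant.te_ms,
                "t2_csf": self.water.t2_csf_ms,
                "window": self.fit.fit_window_ppm,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ReportTables:
    """Output tables of one pipeline run."""

    demographics: pd.DataFrame
    quality: pd.DataFrame
    concentrations: pd.DataFrame
    statistics: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("demographics", "quality", "concentrations", "statistics", "correlations"):
            mio.write_table(getattr(self, name), outdir / f"{name}.tsv", self.metadata)


# -- simulation to disk -----------------------------------------------------


def _voxel_scale(record: SubjectRecord, site: str, cfg: PipelineConfig) -> tuple[float, float]:
    """(a_tissue, spectrum scale) for a voxel, linking metabolite-signal
    units to water-integral units so quantification round-trips."""
    f = record.true_csf_fraction[site]
    a_tissue = cfg.water_total_amplitude * (1.0 - f)
    t2 = record.true_t2_ms[site]
    k = cfg.quant
    scale = (
        a_tissue
        * np.exp(-k.te_ms / t2)
        / (k.pure_water_conc_mmol_L * k.tissue_water_content * k.calibration)
    )
    return a_tissue, float(scale)


def simulate_cohort_files(
    config: PipelineConfig,
    outdir: str | Path,
    basis: BasisSet | None = None,
    force: bool = False,
) -> Path:
    """Write a full synthetic cohort (spectra, water series, manifest).

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    basis = basis or default_basis()
    cohort_cfg = config.cohort
    records = make_cohort(cohort_cfg)
    rng = np.random.default_rng(config.seed)
    rows = []
    log.info(
        "simulate: %d subjects, seed=%d, config=%s",
        len(records), config.seed, config.config_hash(),
    )
    for rec in records:
        for site in cohort_cfg.sites:
            a_tissue, scale = _voxel_scale(rec, site, config)
            vid = f"{rec.subject_id}_{site}"
            wseed, sseed = int(rng.integers(2**31)), int(rng.integers(2**31))
            series = make_water_series(
                rec.true_t2_ms[site],
                rec.true_csf_fraction[site],
                noise_sd=config.water_noise_frac * config.water_total_amplitude,
                seed=wseed,
                total_amplitude=config.water_total_amplitude,
                t2_csf_ms=config.water.t2_csf_ms,
                voxel_id=vid,
            )
            conc = rec.true_conc[site]
            base_peak = 0.6 * conc.get("NAA", 10.0) * float(np.max(basis.rendered["NAA"]))
            spectrum = make_spectrum(
                conc,
                basis,
                target_snr=cohort_cfg.target_snr[site],
                target_fwhm_ppm=cohort_cfg.target_fwhm_ppm,
                baseline_amp=cohort_cfg.baseline_amp_frac * scale * base_peak,
                seed=sseed,
                scale=scale,
                id=vid,
            )
            spath, wpath = f"{vid}_spectrum.json", f"{vid}_water.csv"
            mio.write_spectrum(spectrum, outdir / spath)
            mio.write_water_series(series, outdir / wpath)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "site": site,
                    "edss": rec.edss,
                    "duration_yrs": round(rec.disease_duration_yrs, 6),
                    "lesion_age_months": round(rec.lesion_age_months, 6),
                    "spectrum_path": spath,
                    "water_path": wpath,
                }
            )
    manifest = pd.DataFrame(rows)
    mpath = outdir / "manifest.tsv"
    mio.write_manifest(manifest, mpath)
    return mpath


# -- analysis ---------------------------------------------------------------


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    basis: BasisSet | None = None,
) -> ReportTables:
    """Quantify every voxel in a cohort manifest and run the group statistics.

    Per voxel: biexponential water fit, linear-combination spectral fit,
    CRLB screening, water-referenced absolute quantification; voxels whose
    water fit fails to converge are excluded with a log entry, and partial
    failures never abort the cohort.  Statistics run in three batches
    (between-group unpaired; within-NMOSD sign-flip; within-MS sign-flip)
    with max-statistic FWER correction inside each batch.
    """
    config = config or PipelineConfig()
    basis = basis or default_basis()
    manifest = mio.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    conc_rows, qual_rows, failures = [], [], []
    for _, row in manifest.iterrows():
        vid = f"{row['subject_id']}_{row['site']}"
        try:
            series = mio.read_water_series(base / row["water_path"])
            water = WaterT2Model(series, config.water).fit()
            if not water.converged:
                log.warning("voxel %s: water fit not converged; excluded", vid)
                failures.append(vid)
                continue
            spectrum = mio.read_spectrum(base / row["spectrum_path"])
            fit = SpectralFitModel(spectrum, basis, config.fit).fit()
            if fit.crlb_available:
                retained, excluded = screen_crlb(
                    fit.amplitudes, fit.crlb_pct, config.crlb_threshold_pct
                )
            else:  # no noise estimate (e.g. noiseless input): nothing to screen on
                log.info("voxel %s: CRLBs unavailable; screening skipped", vid)
                retained, excluded = dict(fit.amplitudes), []
            if excluded:
                log.info("voxel %s: CRLB-excluded %s", vid, ",".join(excluded))
            qm = quality_metrics(spectrum, fit, config.fit)
            qual_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "group": row["group"],
                    "site": row["site"],
                    "t2_water_ms": water.t2_tissue_ms,
                    "csf_fraction": water.csf_fraction,
                    "fwhm_ppm": qm.fwhm_ppm,
                    "snr": qm.snr,
                }
            )
            for name, amp in fit.amplitudes.items():
                conc_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "group": row["group"],
                        "site": row["site"],
                        "metabolite": name,
                        "conc_mmol_L": absolute_concentration(amp, water, config.quant),
                        "crlb_pct": fit.crlb_pct[name],
                        "retained": name in retained,
                    }
                )
        except Exception:
            log.exception("voxel %s: stage failed; excluded", vid)
            failures.append(vid)
    conc = derived_measures(pd.DataFrame(conc_rows))
    quality = pd.DataFrame(qual_rows)
    stats_table = compute_statistics(conc, config)
    correlations = compute_correlations(conc, manifest)
    demographics = _demographics_table(manifest)
    meta = {
        "package": "mrsquant 0.1.0",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "excluded_voxels": ",".join(failures) if failures else "none",
    }
    return ReportTables(
        demographics=demographics,
        quality=_quality_summary(quality),
        concentrations=conc,
        statistics=stats_table,
        correlations=correlations,
        metadata=meta,
    )


def _retained_wide(conc: pd.DataFrame, metabolite: str, site: str) -> pd.DataFrame:
    sub = conc[(conc["metabolite"] == metabolite) & (conc["site"] == site)]
    if "retained" in sub.columns:
        sub = sub[sub["retained"].astype(bool)]
    return sub


def _safe_sign_flip(diffs, tail, seed):
    try:
        return sign_flip_test(np.asarray(diffs), tail=tail, seed=seed)
    except DegenerateDataError:
        n = len(diffs)
        return StatTestResult(
            statistic=0.0, df=n - 1, n_shufflings=2**n,
            p_uncorrected_onetailed=1.0, p_twotailed=1.0, cohens_d=0.0,
            tail=tail, exhaustive=True, scheme=("sign_flip", n),
            perm_stats=np.zeros(2**n),
        )


def compute_statistics(conc: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """The three statistical batches with per-batch FWER correction."""
    rows = []

    def emit(batch, comparison, metabolite, res: StatTestResult):
        rows.append(
            {
                "batch": batch,
                "comparison": comparison,
                "metabolite": metabolite,
                "t": res.statistic,
                "df": res.df,
                "d": res.cohens_d,
                "n_shufflings": res.n_shufflings,
                "p_one": res.p_uncorrected_onetailed,
                "p_two": res.p_twotailed,
                "p_fwer": res.p_fwer,
                "exhaustive": res.exhaustive,
            }
        )

    # batch 1: between-group unpaired tests (both sites, all analytes)
    batch1 = []
    for site in ("lesion", "nawm"):
        for m in ANALYSIS_METABOLITES:
            ms = _retained_wide(conc, m, site).query("group == 'MS'")["conc_mmol_L"]
            nmo = _retained_wide(conc, m, site).query("group == 'NMOSD'")["conc_mmol_L"]
            if len(ms) < 2 or len(nmo) < 2:
                continue
            try:
                res = permutation_two_sample(
                    ms.to_numpy(), nmo.to_numpy(),
                    tail=BETWEEN_TAILS[site][m], seed=config.seed,
                )
            except DegenerateDataError:
                log.warning("between-group test for %s (%s) degenerate; skipped", m, site)
                continue
            batch1.append((f"MS_vs_NMOSD_{site}", m, res))
    if batch1 and len({r.scheme for _, _, r in batch1}) == 1:
        fwer_correct_batch([r for _, _, r in batch1], config.fwer_method)
    for cmp_, m, r in batch1:
        emit("between_groups", cmp_, m, r)

    # batches 2 and 3: within-group lesion-vs-NAWM sign-flip tests
    for group, batch_name in (("NMOSD", "within_NMOSD"), ("MS", "within_MS")):
        batch = []
        for m in ANALYSIS_METABOLITES:
            sub = conc[(conc["metabolite"] == m) & (conc["group"] == group)]
            if "retained" in sub.columns:
                sub = sub[sub["retained"].astype(bool)]
            wide = sub.pivot_table(
                index="subject_id", columns="site", values="conc_mmol_L"
            ).dropna()
            if len(wide) < 2 or "nawm" not in wide or "lesion" not in wide:
                continue
            diffs = (wide["nawm"] - wide["lesion"]).to_numpy()
            res = _safe_sign_flip(diffs, WITHIN_TAILS[group][m], config.seed)
            batch.append((f"{group}_nawm_minus_lesion", m, res))
        if batch and len({r.scheme for _, _, r in batch}) == 1:
            fwer_correct_batch([r for _, _, r in batch], config.fwer_method)
        for cmp_, m, r in batch:
            emit(batch_name, cmp_, m, r)
    return pd.DataFrame(rows)


def compute_correlations(conc: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """NAWM Ins:NAA versus EDSS, per group and pooled."""
    ins = conc[(conc["metabolite"] == "Ins") & (conc["site"] == "nawm")]
    naa = conc[(conc["metabolite"] == "NAA") & (conc["site"] == "nawm")]
    merged = ins.merge(
        naa, on=["subject_id", "group"], suffixes=("_ins", "_naa")
    )
    merged["ins_naa"] = merged["conc_mmol_L_ins"] / merged["conc_mmol_L_naa"]
    edss = (
        manifest[["subject_id", "edss"]]
        .drop_duplicates("subject_id")
        .set_index("subject_id")["edss"]
    )
    merged["edss"] = merged["subject_id"].map(edss)
    rows = []
    for label, sub in [
        ("MS", merged[merged["group"] == "MS"]),
        ("NMOSD", merged[merged["group"] == "NMOSD"]),
        ("combined", merged),
    ]:
        if len(sub) < 3 or sub["edss"].std(ddof=0) == 0 or sub["ins_naa"].std(ddof=0) == 0:
            continue
        cr = pearson_with_p(sub["ins_naa"].to_numpy(), sub["edss"].to_numpy())
        rows.append(
            {
                "subset": label,
                "n": len(sub),
                "r": cr.r,
                "r_squared": cr.r_squared,
                "df": cr.df,
                "p_twotailed": cr.p_twotailed,
            }
        )
    return pd.DataFrame(rows)


def _demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    subj = manifest.drop_duplicates("subject_id")
    rows = []
    for group, sub in subj.groupby("group"):
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "edss_median": sub["edss"].median(),
                "edss_min": sub["edss"].min(),
                "edss_max": sub["edss"].max(),
                "duration_yrs_mean": sub["duration_yrs"].mean(),
                "duration_yrs_sd": sub["duration_yrs"].std(),
                "lesion_age_months_mean": sub["lesion_age_months"].mean(),
                "lesion_age_months_sd": sub["lesion_age_months"].std(),
            }
        )
    return pd.DataFrame(rows)


def _quality_summary(quality: pd.DataFrame) -> pd.DataFrame:
    if quality.empty:
        return quality
    out = (
        quality.groupby(["group", "site"])
        .agg(
            n=("subject_id", "count"),
            t2_water_ms_mean=("t2_water_ms", "mean"),
            t2_water_ms_sd=("t2_water_ms", "std"),
            csf_fraction_mean=("csf_fraction", "mean"),
            fwhm_ppm_mean=("fwhm_ppm", "mean"),
            fwhm_ppm_sd=("fwhm_ppm", "std"),
            snr_mean=("snr", "mean"),
            snr_sd=("snr", "std"),
        )
        .reset_index()
    )
    return out
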