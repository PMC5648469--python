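"""End-to-end in-silico validation study: phantom -> both arms -> agreement.

Mirrors the clinical study design: each virtual patient is imaged at rest
and under stress by both modalities; the CMR arm runs the full signal chain
(dual-echo blood series -> T2*-corrected, LUT-inverted AIF; myocardial
series -> concentration -> per-segment exchange-model fits) and the PET arm
fits the one-compartment model to frame-averaged TACs with extraction
correction.  Segmental tables from both arms are then compared with
correlation, regression, Bland-Altman and contingency statistics.

A single run seed fans out to per-patient, per-stage substreams through
``numpy.random.SeedSequence`` spawn keys, so editing one patient's settings
never perturbs another's noise realization.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aha_segmentation, agreement_stats, btex_kinetics, cmr_signal, phantom
from . import pet_kinetics
from .agreement_stats import AgreementReport, PairedMeasurements
from .btex_kinetics import SolverGrid
from .pet_kinetics import ExtractionModel
from .phantom import (NoiseParams, build_frame_schedule, N_SEGMENTS, PET_FRAMING)

__all__ = ["RunConfig", "StudyReport", "run_validation_study", "validate_config",
           "quantify_cmr_study", "quantify_pet_study"]

logger = logging.getLogger("duoflow")

FLOW_UNIT_FACTORS = {"ml/min/g": 1.0, "ml/s/g": 60.0}


@dataclass
class RunConfig:
    """Configuration of one in-silico validation run (all defaults runnable)."""

    n_patients: int = 21
    scenario_mix: dict = field(default_factory=lambda: {
        "normal": 0.4, "single_vessel": 0.5, "multi_vessel": 0.1})
    seed: int = 2017
    n_frames_stress: int = 90
    n_frames_rest: int = 60
    heart_rate_bpm: float = 60.0
    cmr_sigma: float = 0.0
    pet_noise_scale: float = 0.0
    n_axial: int = 20
    erosion_px: int = 1
    extraction_mode: str = "constant"
    extraction_e: float = 0.90
    stress_cutoff: float = 2.0
    out_dir: str | None = None
    make_plots: bool = False
    flow_unit: str = "ml/min/g"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = np.array(list(self.scenario_mix.values()), float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("scenario_mix proportions must be >= 0 and sum to 1")
        if self.stress_cutoff <= 0:
            raise ValueError("stress_cutoff must be > 0")
        if self.flow_unit not in FLOW_UNIT_FACTORS:
            raise ValueError(f"unknown flow_unit {self.flow_unit!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(path) -> RunConfig:
    """Load + schema-check a YAML run configuration.

    Unknown keys are listed in the error; an empty file yields the full
    default configuration; flow-rate values supplied in ml/s/g are
    converted to ml/min/g with a logged note.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**raw)
    factor = FLOW_UNIT_FACTORS[cfg.flow_unit]
    if factor != 1.0:
        cfg.stress_cutoff *= factor
        cfg.flow_unit = "ml/min/g"
        logger.info("converted flow values from ml/s/g to ml/min/g (x%g)", factor)
    return cfg


# ---------------------------------------------------------------------------
# quantification arms
# ---------------------------------------------------------------------------

def quantify_cmr_study(study: phantom.CMRStudy, erosion_px: int = 1,
                       grid: SolverGrid | None = None) -> pd.DataFrame:
    """CMR arm: signal chain + per-segment exchange-model fits.

    Returns a 16-row table (index: segment) with columns ``mp`` (ml/min/g)
    and ``n_pixels``.
    """
    grid = grid or SolverGrid()
    # blood: dual-echo T2* correction, PD normalization, LUT inversion
    blood_lut = cmr_signal.build_lut(study.protocol_aif, study.relax_blood, te=None)
    corr = cmr_signal.t2star_correct(study.lowres_echo1, study.lowres_echo2,
                                     study.protocol_aif.te1, study.protocol_aif.te2)
    conv = cmr_signal.signal_to_concentration(study.times, corr.s0, blood_lut,
                                              study.pd_lowres)
    aif = cmr_signal.extract_aif(conv.series, study.blood_mask)

    # myocardium: LUT at te1 (no dual echo at high resolution)
    myo_lut = cmr_signal.build_lut(study.protocol, study.relax_myo,
                                   te=study.protocol.te1)
    conv_myo = cmr_signal.signal_to_concentration(study.times, study.highres,
                                                  myo_lut, study.pd_highres)

    rows = []
    for k in range(study.myo_mask.shape[0]):
        mask = aha_segmentation.erode_roi(study.myo_mask[k], erosion_px,
                                          segment_labels=study.segment_maps[k])
        labels = np.where(mask, study.segment_maps[k], 0)
        for seg in sorted(set(np.unique(labels)) - {0}):
            sel = labels == seg
            curve = conv_myo.series.concentration[:, k][:, sel].mean(axis=1)
            fit = btex_kinetics.btex_fit(curve, aif, study.times, grid=grid)
            rows.append((seg, fit.params.Fp, int(sel.sum())))
    table = (pd.DataFrame(rows, columns=["segment", "mp", "n_pixels"])
             .groupby("segment").agg(mp=("mp", "mean"), n_pixels=("n_pixels", "sum")))
    if len(table) != N_SEGMENTS:
        raise ValueError(f"expected {N_SEGMENTS} segments, got {len(table)}")
    return table


def quantify_pet_study(study: phantom.PETStudy,
                       extraction: ExtractionModel | None = None) -> pd.DataFrame:
    """PET arm: one-compartment fits + extraction correction -> MBF table."""
    extraction = extraction or study.extraction
    rows = []
    for seg, tac in study.tacs.items():
        fit = pet_kinetics.degrado_fit(tac, study.blood)
        mbf = pet_kinetics.k1_to_flow(fit.params.K1, extraction)
        rows.append((seg, mbf, fit.params.K1, fit.params.k2, fit.params.Vb,
                     fit.converged))
    return (pd.DataFrame(rows, columns=["segment", "mp", "K1", "k2", "Vb",
                                        "converged"])
            .set_index("segment").sort_index())


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """All tables and statistics of one in-silico validation run."""

    segment_table: pd.DataFrame       # long: patient, segment, arm, state, mp + truth
    patient_table: pd.DataFrame       # per patient: global MP/MPR per arm + positivity
    regional_mp: AgreementReport
    global_mp: AgreementReport
    regional_mpr: AgreementReport
    global_mpr: AgreementReport
    contingency_cmr: np.ndarray       # CMR positivity vs ground-truth lesion
    contingency_pet: np.ndarray       # PET positivity vs ground-truth lesion
    provenance: dict


def _safe_agreement(pairs: PairedMeasurements, k: float = 2.0) -> AgreementReport:
    """Full panel when the sample allows it; NaN-filled placeholders for the
    pieces a tiny cohort cannot support (r/p need n >= 3, SD needs n >= 2)."""
    if pairs.n >= 3 and np.std(pairs.x) > 0 and np.std(pairs.y) > 0:
        return agreement_stats.agreement_report(pairs, k=k)
    d = pairs.x - pairs.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if pairs.n >= 2 else float("nan")
    return AgreementReport(r=float("nan"), p_r=float("nan"),
                           slope=float("nan"), intercept=float("nan"),
                           bias=bias, sd_diff=sd, loa_low=bias - k * sd,
                           loa_high=bias + k * sd, n=pairs.n, unit=pairs.unit)


def _patient_noise(cfg: RunConfig, idx: int, kind: str) -> NoiseParams:
    tag = {"cmr": 1, "pet": 2}[kind]
    seed = int(np.random.SeedSequence([cfg.seed, idx, tag]).generate_state(1)[0]
               % (2**31 - 1))
    return NoiseParams(cmr_sigma=cfg.cmr_sigma, pet_noise_scale=cfg.pet_noise_scale,
                       seed=seed)


def run_validation_study(config: RunConfig | None = None) -> StudyReport:
    """Run the full in-silico comparison and return the assembled report.

    Deterministic given the config seed; when ``config.out_dir`` is set the
    segment/patient tables (CSV), the statistics (JSON) and optional plots
    are written there.
    """
    cfg = config or RunConfig()
    t0 = time.time()
    extraction = ExtractionModel(mode=cfg.extraction_mode, E_const=cfg.extraction_e)
    grid = SolverGrid(n_axial=cfg.n_axial)
    schedule = build_frame_schedule(PET_FRAMING)
    cohort = phantom.generate_cohort(cfg.n_patients, cfg.scenario_mix, cfg.seed)

    seg_rows = []
    pat_rows = []
    for i, patient in enumerate(cohort):
        t_pat = time.time()
        tables = {}
        for state, n_frames in (("rest", cfg.n_frames_rest),
                                ("stress", cfg.n_frames_stress)):
            cmr = phantom.synthesize_cmr_study(
                patient, state=state, n_frames=n_frames,
                heart_rate_bpm=cfg.heart_rate_bpm,
                noise=_patient_noise(cfg, i, "cmr"), grid=grid)
            tables[("cmr", state)] = quantify_cmr_study(cmr, cfg.erosion_px, grid)
            pet = phantom.synthesize_pet_study(
                patient, schedule=schedule, state=state,
                noise=_patient_noise(cfg, i, "pet"), extraction=extraction)
            tables[("pet", state)] = quantify_pet_study(pet, extraction)

        for (arm, state), tab in tables.items():
            for seg, row in tab.iterrows():
                seg_rows.append({
                    "patient_id": patient.patient_id, "segment": seg, "arm": arm,
                    "state": state, "mp": float(row["mp"]),
                    "true_mp": float(patient.true_flows.loc[seg, state]),
                })

        pat = {"patient_id": patient.patient_id,
               "scenario": patient.scenario.label,
               "territory": patient.scenario.territory or "",
               "has_lesion": patient.scenario.has_lesion}
        for arm in ("cmr", "pet"):
            g_rest = aha_segmentation.global_mp(tables[(arm, "rest")]["mp"].to_numpy())
            g_stress = aha_segmentation.global_mp(tables[(arm, "stress")]["mp"].to_numpy())
            _, positive = aha_segmentation.classify_stress_positive(
                tables[(arm, "stress")]["mp"], threshold=cfg.stress_cutoff)
            pat[f"{arm}_global_rest"] = g_rest
            pat[f"{arm}_global_stress"] = g_stress
            pat[f"{arm}_global_mpr"] = g_stress / g_rest
            pat[f"{arm}_positive"] = positive
        pat_rows.append(pat)
        logger.info("patient %s (%s) quantified in %.1f s", patient.patient_id,
                    patient.scenario.label, time.time() - t_pat)

    seg_table = pd.DataFrame(seg_rows)
    pat_table = pd.DataFrame(pat_rows)

    # paired regional/global tables, PET on x (reference), CMR on y
    wide = seg_table.pivot_table(index=["patient_id", "segment", "state"],
                                 columns="arm", values="mp").reset_index()
    regional_pairs = PairedMeasurements(x=wide["pet"].to_numpy(),
                                        y=wide["cmr"].to_numpy())
    regional_mp = _safe_agreement(regional_pairs)

    gx = np.concatenate([pat_table["pet_global_rest"], pat_table["pet_global_stress"]])
    gy = np.concatenate([pat_table["cmr_global_rest"], pat_table["cmr_global_stress"]])
    global_mp_rep = _safe_agreement(PairedMeasurements(x=gx, y=gy))

    mpr_wide = wide.pivot_table(index=["patient_id", "segment"], columns="state",
                                values=["pet", "cmr"])
    reg_mpr_x = (mpr_wide[("pet", "stress")] / mpr_wide[("pet", "rest")]).to_numpy()
    reg_mpr_y = (mpr_wide[("cmr", "stress")] / mpr_wide[("cmr", "rest")]).to_numpy()
    regional_mpr = _safe_agreement(
        PairedMeasurements(x=reg_mpr_x, y=reg_mpr_y, unit="dimensionless"))
    global_mpr = _safe_agreement(PairedMeasurements(
        x=pat_table["pet_global_mpr"].to_numpy(),
        y=pat_table["cmr_global_mpr"].to_numpy(), unit="dimensionless"))

    truth = pat_table["has_lesion"].to_numpy(bool)
    cont_cmr = agreement_stats.contingency_2x2(pat_table["cmr_positive"], truth)
    cont_pet = agreement_stats.contingency_2x2(pat_table["pet_positive"], truth)

    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                  "version": __version__, "n_patients": cfg.n_patients,
                  "runtime_s": round(time.time() - t0, 2)}
    report = StudyReport(segment_table=seg_table, patient_table=pat_table,
                         regional_mp=regional_mp, global_mp=global_mp_rep,
                         regional_mpr=regional_mpr, global_mpr=global_mpr,
                         contingency_cmr=cont_cmr, contingency_pet=cont_pet,
                         provenance=provenance)
    _audit_self_consistency(report)
    if cfg.out_dir:
        _write_report(report, cfg)
    return report


def _audit_self_consistency(report: StudyReport) -> None:
    """Statistics must recompute exactly from the emitted tables."""
    wide = report.segment_table.pivot_table(
        index=["patient_id", "segment", "state"], columns="arm",
        values="mp").reset_index()
    again = _safe_agreement(PairedMeasurements(
        x=wide["pet"].to_numpy(), y=wide["cmr"].to_numpy()))
    if not (np.isnan(again.r) and np.isnan(report.regional_mp.r)) and \
            not np.isclose(again.r, report.regional_mp.r, rtol=0, atol=1e-12):
        raise RuntimeError("self-consistency audit failed: regional r mismatch")


def _write_report(report: StudyReport, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.segment_table.to_csv(out / "segment_table.csv", index=False)
    report.patient_table.to_csv(out / "patient_table.csv", index=False)
    stats_payload = {
        "regional_mp": report.regional_mp.to_dict(),
        "global_mp": report.global_mp.to_dict(),
        "regional_mpr": report.regional_mpr.to_dict(),
        "global_mpr": report.global_mpr.to_dict(),
        "contingency_cmr": report.contingency_cmr.tolist(),
        "contingency_pet": report.contingency_pet.tolist(),
        "provenance": report.provenance,
    }
    (out / "agreement.json").write_text(json.dumps(stats_payload, indent=2))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    if cfg.make_plots:
        wide = report.segment_table.pivot_table(
            index=["patient_id", "segment", "state"], columns="arm",
            values="mp").reset_index()
        agreement_stats.plot_agreement(
            PairedMeasurements(x=wide["pet"].to_numpy(), y=wide["cmr"].to_numpy()),
            report.regional_mp, out / "regional_agreement.png", title="regional MP")
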