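"""Virtual-patient phantom: ground-truth flows, AIFs, CMR and PET raw data.

Generates everything the two quantification arms consume, with known truth:

* gamma-variate arterial input functions (rest / adenosine stress),
* cohorts of virtual patients with per-segment true flows for normal,
  single-territory-stenosis and multi-vessel (balanced ischemia) scenarios,
* dynamic saturation-recovery CMR studies (dual-echo low-resolution blood
  series + high-resolution myocardial series, Rician magnitude noise),
* frame-averaged PET time-activity curves with duration-scaled noise.

Noise-free output inverts exactly (to interpolation tolerance) through the
signal and kinetic chains, which is what makes every downstream stage
testable without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import btex_kinetics, cmr_signal, pet_kinetics
from .btex_kinetics import BTEXParams, SolverGrid
from .cmr_signal import RelaxationParams, SRProtocol
from .pet_kinetics import DeGradoParams, ExtractionModel

__all__ = [
    "AIFCurve",
    "AIFParams",
    "FlowScenario",
    "VirtualPatient",
    "FrameSchedule",
    "NoiseParams",
    "CMRStudy",
    "PETStudy",
    "generate_aif",
    "build_frame_schedule",
    "generate_cohort",
    "synthesize_cmr_study",
    "synthesize_pet_study",
    "TERRITORY_SEGMENTS",
    "PET_FRAMING",
    "N_SEGMENTS",
]

N_SEGMENTS = 16

#: AHA coronary territory assignment for the 17-segment model (apex excluded)
TERRITORY_SEGMENTS = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}

#: dynamic PET framing of the first 4 minutes: (count, duration_s)
PET_FRAMING = ((12, 5.0), (4, 10.0), (4, 20.0), (1, 60.0))

# scenario flow ranges, ml/min/g
NORMAL_REST_RANGE = (0.6, 1.1)
NORMAL_STRESS_RANGE = (2.0, 4.0)
LESION_STRESS_RANGE = (0.6, 1.8)
MULTI_STRESS_RANGE = (0.6, 1.9)


@dataclass(frozen=True)
class AIFCurve:
    """Arterial input function: sample times (s) + concentration/activity."""

    times: np.ndarray
    values: np.ndarray
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")

    def to_frame(self) -> pd.DataFrame:
        col = "gd_mmol_per_L" if self.unit == "mmol/L" else "activity_kBq_per_mL"
        return pd.DataFrame({"time_s": self.times, col: self.values})


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate bolus: A*((t-t0)/beta)^alpha * exp(-(t-t0)/beta) for
    t > t0, plus an optional recirculation tail (a fraction of the primary
    bolus convolved with a normalized exponential washout kernel)."""

    amplitude: float
    onset_time: float = 5.0
    alpha: float = 2.5
    beta: float = 3.0
    recirculation_fraction: float = 0.15
    washout_rate: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not 0 <= self.recirculation_fraction < 1:
            raise ValueError("recirculation_fraction must be in [0, 1)")
        if self.washout_rate < 0:
            raise ValueError("washout_rate must be >= 0")

    @property
    def peak_value(self) -> float:
        """Peak of the primary bolus, at t = t0 + alpha*beta."""
        return self.amplitude * self.alpha ** self.alpha * np.exp(-self.alpha)

    @classmethod
    def for_peak(cls, peak: float, **kw) -> "AIFParams":
        """Scale the amplitude so the primary bolus peaks at ``peak``."""
        alpha = kw.get("alpha", 2.5)
        return cls(amplitude=peak / (alpha ** alpha * np.exp(-alpha)), **kw)

    @classmethod
    def default_cmr(cls, state: str = "stress") -> "AIFParams":
        """First-pass blood-pool [Gd]: peak about 5 mmol/L; the rest bolus is
        slightly later and more dispersed than the stress bolus."""
        if state == "stress":
            return cls.for_peak(5.0, onset_time=5.0, beta=3.0)
        return cls.for_peak(5.0, onset_time=8.0, alpha=2.5, beta=4.0)

    @classmethod
    def default_pet(cls, state: str = "stress") -> "AIFParams":
        """Blood-pool 13N-NH3 activity, peak about 100 kBq/mL."""
        if state == "stress":
            return cls.for_peak(100.0, onset_time=10.0, beta=4.0)
        return cls.for_peak(100.0, onset_time=15.0, alpha=2.5, beta=5.0)


def generate_aif(params: AIFParams, times) -> AIFCurve:
    """Evaluate the gamma-variate AIF (plus recirculation tail) at ``times``."""
    times = np.asarray(times, float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be >= 0")

    def primary(t):
        x = np.clip((t - params.onset_time) / params.beta, 0.0, None)
        with np.errstate(invalid="ignore"):
            c = params.amplitude * x ** params.alpha * np.exp(-x)
        return np.where(t > params.onset_time, c, 0.0)

    values = primary(times)
    if params.recirculation_fraction > 0 and params.washout_rate > 0:
        # tail on an internal fine grid, then resampled
        dt = 0.05
        tf = np.arange(0.0, times[-1] + dt, dt)
        kern = params.washout_rate * np.exp(-params.washout_rate * tf) * dt
        tail = params.recirculation_fraction * np.convolve(primary(tf), kern)[: tf.size]
        values = values + np.interp(times, tf, tail)
    return AIFCurve(times=times, values=np.maximum(values, 0.0), unit="")


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic frames (start + duration, s)."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_start, float)
        durs = np.asarray(self.frame_duration, float)
        if len(starts) != len(durs) or len(starts) == 0:
            raise ValueError("frame_start and frame_duration must align")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be > 0")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def total_duration(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1] - self.frame_start[0])

    @property
    def frame_mid(self) -> np.ndarray:
        return np.asarray(self.frame_start) + 0.5 * np.asarray(self.frame_duration)


def build_frame_schedule(spec) -> FrameSchedule:
    """Expand a ``[(count, duration_s), ...]`` spec into contiguous frames
    starting at t = 0 (e.g. the 4-min dynamic PET framing 12x5, 4x10,
    4x20, 1x60 -> 21 frames over 240 s)."""
    spec = list(spec)
    if not spec:
        raise ValueError("frame spec must not be empty")
    durs = []
    for count, duration in spec:
        if count < 1 or duration <= 0:
            raise ValueError("counts must be >= 1 and durations > 0")
        durs.extend([float(duration)] * int(count))
    durs = np.asarray(durs)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(frame_start=starts, frame_duration=durs)


@dataclass(frozen=True)
class NoiseParams:
    """cmr_sigma: Rician SD as a fraction of the proton-density reference;
    pet_noise_scale: multiplier for sqrt(activity/duration)-scaled Gaussian
    frame noise.  Zero (the default) means noiseless."""

    cmr_sigma: float = 0.0
    pet_noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cmr_sigma < 0 or self.pet_noise_scale < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def default_realistic(cls, seed: int = 0) -> "NoiseParams":
        return cls(cmr_sigma=0.02, pet_noise_scale=1.0, seed=seed)


@dataclass(frozen=True)
class FlowScenario:
    """Perfusion scenario: normal, single-territory stenosis, or balanced
    multi-vessel disease (global stress MP below the 2.0 ml/min/g cut-off)."""

    label: str
    territory: str | None = None
    rest_flow_range: tuple = NORMAL_REST_RANGE
    stress_flow_range: tuple = NORMAL_STRESS_RANGE
    lesion_stress_range: tuple = LESION_STRESS_RANGE

    def __post_init__(self) -> None:
        if self.label not in ("normal", "single_vessel", "multi_vessel"):
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.label == "single_vessel":
            if self.territory not in TERRITORY_SEGMENTS:
                raise ValueError("single_vessel requires territory LAD/LCX/RCA")
        for rng in (self.rest_flow_range, self.stress_flow_range, self.lesion_stress_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError("flow ranges must be positive and ordered")
        if self.lesion_stress_range[1] > self.stress_flow_range[1]:
            raise ValueError("lesion stress flow must not exceed the normal range")

    @property
    def has_lesion(self) -> bool:
        return self.label != "normal"


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual patient: 16-segment ground-truth flow table + scenario."""

    patient_id: str
    true_flows: pd.DataFrame  # index: segment 1..16; columns: rest, stress
    scenario: FlowScenario
    seed: int

    def __post_init__(self) -> None:
        if len(self.true_flows) != N_SEGMENTS:
            raise ValueError(f"expected {N_SEGMENTS} segment rows")
        if not {"rest", "stress"} <= set(self.true_flows.columns):
            raise ValueError("true_flows needs 'rest' and 'stress' columns")
        if (self.true_flows["rest"] <= 0).any() or (self.true_flows["stress"] < 0).any():
            raise ValueError("rest flows must be > 0 and stress flows >= 0")


def _draw_flows(scenario: FlowScenario, rng: np.random.Generator) -> pd.DataFrame:
    segs = np.arange(1, N_SEGMENTS + 1)
    rest = rng.uniform(*scenario.rest_flow_range, size=N_SEGMENTS)
    if scenario.label == "normal":
        stress = rng.uniform(*scenario.stress_flow_range, size=N_SEGMENTS)
    elif scenario.label == "multi_vessel":
        stress = rng.uniform(*MULTI_STRESS_RANGE, size=N_SEGMENTS)
    else:
        stress = rng.uniform(*scenario.stress_flow_range, size=N_SEGMENTS)
        lesion = np.isin(segs, TERRITORY_SEGMENTS[scenario.territory])
        stress[lesion] = rng.uniform(*scenario.lesion_stress_range, size=lesion.sum())
    return pd.DataFrame({"rest": rest, "stress": stress}, index=pd.Index(segs, name="segment"))


def generate_cohort(n_patients: int, scenario_mix: dict, seed: int) -> list:
    """Reproducible cohort of virtual patients.

    ``scenario_mix`` maps scenario labels to proportions summing to 1;
    single-vessel lesions are spread over the three coronary territories.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    probs = np.array(list(scenario_mix.values()), float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("scenario proportions must be >= 0 and sum to 1")
    labels = list(scenario_mix.keys())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    territories = ("LAD", "RCA", "LCX")
    patients = []
    for i in range(n_patients):
        label = labels[rng.choice(len(labels), p=probs)]
        territory = territories[i % 3] if label == "single_vessel" else None
        scenario = FlowScenario(label=label, territory=territory)
        pseed = int(rng.integers(0, 2**31 - 1))
        flows = _draw_flows(scenario, np.random.default_rng(pseed))
        patients.append(VirtualPatient(
            patient_id=f"vp{i:03d}", true_flows=flows, scenario=scenario, seed=pseed,
        ))
    return patients


# ---------------------------------------------------------------------------
# CMR study synthesis
# ---------------------------------------------------------------------------

@dataclass
class CMRStudy:
    """Dynamic SR-FLASH study for one hemodynamic state.

    ``highres`` is the myocardial series (n_t, n_slices, H, W) acquired at
    te1; ``lowres_echo1/2`` are the dual-echo blood-pool series; ``pd_*``
    are proton-density reference images in the same raw signal units.
    ``true_conc`` and ``true_aif`` carry the simulated ground truth for
    round-trip checks.
    """

    times: np.ndarray
    highres: np.ndarray
    lowres_echo1: np.ndarray
    lowres_echo2: np.ndarray
    pd_highres: np.ndarray
    pd_lowres: np.ndarray
    myo_mask: np.ndarray
    segment_maps: np.ndarray
    blood_mask: np.ndarray
    protocol: SRProtocol
    protocol_aif: SRProtocol
    relax_myo: RelaxationParams
    relax_blood: RelaxationParams
    true_conc: np.ndarray
    true_aif: AIFCurve
    state: str = "stress"


def _annulus_geometry(shape=(40, 40), r_in=8.0, r_out=14.0):
    """Myocardial annulus mask for one short-axis slice."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    return (r >= r_in) & (r <= r_out), (cy, cx)


def synthesize_cmr_study(
    patient: VirtualPatient,
    protocol: SRProtocol | None = None,
    aif: AIFParams | None = None,
    noise: NoiseParams | None = None,
    state: str = "stress",
    n_frames: int = 90,
    heart_rate_bpm: float = 60.0,
    kinetics: BTEXParams | None = None,
    grid: SolverGrid | None = None,
    shape=(40, 40), lowres_shape=(16, 16),
) -> CMRStudy:
    """Simulate a dynamic first-pass CMR study from ground-truth flows.

    One image per heartbeat (default 60 bpm, i.e. 1 s spacing; the stress
    default of 90 frames emulates acquisition over 90 heart beats).  Tissue
    concentration per segment comes from the distributed exchange model at
    the segment's true flow; blood-pool pixels of the low-resolution series
    carry the AIF itself.  Signals are produced by the Bloch-simulated
    forward chain (T2* losses at both echoes of the blood series, te1 for
    the myocardial series) and Rician noise is added on the magnitude.
    """
    from .aha_segmentation import build_segment_map

    protocol = protocol or SRProtocol.default_myocardial()
    protocol_aif = SRProtocol.default_aif()
    aif = aif or AIFParams.default_cmr(state)
    noise = noise or NoiseParams()
    kin = kinetics or BTEXParams(Fp=1.0)
    grid = grid or SolverGrid()
    relax_myo = RelaxationParams.myocardium_1p5T()
    relax_blood = RelaxationParams.blood_1p5T()

    times = np.arange(n_frames) * (60.0 / heart_rate_bpm)
    aif_curve = generate_aif(aif, times)
    aif_curve = AIFCurve(times=aif_curve.times, values=aif_curve.values, unit="mmol/L")

    # per-segment tissue concentration from the exchange model
    # (zero flow means no tracer delivery: flat pre-contrast baseline)
    seg_conc = {}
    for seg, row in patient.true_flows.iterrows():
        flow = float(row[state])
        if flow == 0.0:
            seg_conc[seg] = np.zeros_like(times)
            continue
        p = BTEXParams(Fp=flow, PS=kin.PS, Vp=kin.Vp,
                       Visf=kin.Visf, delay=kin.delay)
        seg_conc[seg] = btex_kinetics.btex_forward(p, aif_curve, times, grid)

    # geometry: 3 short-axis slices, full annulus, AHA sectors
    myo_mask = np.zeros((3, *shape), bool)
    segment_maps = np.zeros((3, *shape), np.int32)
    for k, level in enumerate(("basal", "mid", "apical")):
        mask, center = _annulus_geometry(shape)
        smap = build_segment_map(shape, center, level, reference_angle=90.0)
        myo_mask[k] = mask
        segment_maps[k] = np.where(mask, smap.labels, 0)

    # forward signal model; LUT validity guard on the peak concentrations
    myo_lut = cmr_signal.build_lut(protocol, relax_myo, te=protocol.te1)
    blood_lut = cmr_signal.build_lut(protocol_aif, relax_blood, te=None)
    peak_tissue = max(c.max() for c in seg_conc.values())
    if peak_tissue > myo_lut.valid_max_gd:
        raise ValueError(
            f"simulated tissue [Gd] {peak_tissue:.2f} mmol/L exceeds the "
            f"monotone LUT range ({myo_lut.valid_max_gd:.2f} mmol/L)"
        )
    if aif_curve.values.max() > blood_lut.valid_max_gd:
        raise ValueError("simulated blood [Gd] exceeds the monotone LUT range")

    pd_scale = 1000.0  # arbitrary raw-signal proton-density amplitude
    pd_highres = np.full((3, *shape), pd_scale)
    pd_lowres = np.full(lowres_shape, pd_scale)

    conc = np.zeros((n_frames, 3, *shape))
    for k in range(3):
        for seg, curve in seg_conc.items():
            sel = segment_maps[k] == seg
            if sel.any():
                conc[:, k, sel] = curve[:, None]
    highres = np.asarray(
        cmr_signal.sr_flash_signal(conc, protocol, relax_myo, te=protocol.te1)
    ) * pd_scale

    # low-resolution dual-echo blood series
    h, w = lowres_shape
    yy, xx = np.mgrid[0:h, 0:w]
    blood_mask = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) <= h / 4
    blood_conc = np.zeros((n_frames, h, w))
    blood_conc[:, blood_mask] = aif_curve.values[:, None]
    lowres_e1 = np.asarray(cmr_signal.sr_flash_signal(
        blood_conc, protocol_aif, relax_blood, te=protocol_aif.te1)) * pd_scale
    lowres_e2 = np.asarray(cmr_signal.sr_flash_signal(
        blood_conc, protocol_aif, relax_blood, te=protocol_aif.te2)) * pd_scale

    if noise.cmr_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 0xC3]))
        sigma = noise.cmr_sigma * pd_scale
        for arr in (highres, lowres_e1, lowres_e2):
            re = arr + rng.normal(0.0, sigma, arr.shape)
            im = rng.normal(0.0, sigma, arr.shape)
            arr[...] = np.hypot(re, im)

    return CMRStudy(
        times=times, highres=highres, lowres_echo1=lowres_e1,
        lowres_echo2=lowres_e2, pd_highres=pd_highres, pd_lowres=pd_lowres,
        myo_mask=myo_mask, segment_maps=segment_maps, blood_mask=blood_mask,
        protocol=protocol, protocol_aif=protocol_aif,
        relax_myo=relax_myo, relax_blood=relax_blood,
        true_conc=conc, true_aif=AIFCurve(times=times, values=aif_curve.values,
                                          unit="mmol/L"),
        state=state,
    )


# ---------------------------------------------------------------------------
# PET study synthesis
# ---------------------------------------------------------------------------

@dataclass
class PETStudy:
    """Per-segment frame-averaged TACs + the (finely sampled) blood curve."""

    tacs: dict               # segment -> pet_kinetics.TAC
    blood: AIFCurve
    schedule: FrameSchedule
    extraction: ExtractionModel
    true_params: dict        # segment -> DeGradoParams
    state: str = "stress"

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.tacs.values()],
                         ignore_index=True)


def synthesize_pet_study(
    patient: VirtualPatient,
    schedule: FrameSchedule | None = None,
    aif: AIFParams | None = None,
    noise: NoiseParams | None = None,
    state: str = "stress",
    extraction: ExtractionModel | None = None,
    k2_per_min: float = 0.3,
    vb: float = 0.3,
    blood_dt: float = 0.1,
) -> PETStudy:
    """Simulate per-segment dynamic PET TACs from ground-truth flows.

    Each segment's continuous activity follows the one-compartment model at
    K1 = E(flow) * flow, frame-averaged over the schedule; frame noise is
    Gaussian with SD proportional to sqrt(mean activity / duration), the
    usual post-reconstruction approximation of count statistics.
    Activities are decay-corrected by construction.
    """
    schedule = schedule or build_frame_schedule(PET_FRAMING)
    aif = aif or AIFParams.default_pet(state)
    noise = noise or NoiseParams()
    extraction = extraction or ExtractionModel()

    t_end = schedule.frame_start[-1] + schedule.frame_duration[-1]
    bt = np.arange(0.0, t_end + blood_dt, blood_dt)
    blood = generate_aif(aif, bt)
    blood = AIFCurve(times=blood.times, values=blood.values, unit="kBq/mL")

    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 0x9E7]))
    tacs, true_params = {}, {}
    for seg, row in patient.true_flows.iterrows():
        flow = float(row[state])
        e = float(extraction.extraction(flow)) if flow > 0 else extraction.E_const
        params = DeGradoParams(K1=e * flow, k2=k2_per_min, Vb=vb)
        cont = pet_kinetics.degrado_forward(params, blood, bt)
        vals = pet_kinetics.frame_average(bt, cont, schedule)
        if noise.pet_noise_scale > 0:
            sd = noise.pet_noise_scale * np.sqrt(
                np.maximum(vals, 0.0) / schedule.frame_duration)
            vals = vals + rng.normal(0.0, 1.0, vals.shape) * sd
        tacs[seg] = pet_kinetics.TAC(
            frame_start=schedule.frame_start, frame_duration=schedule.frame_duration,
            activity=vals, segment_id=seg,
        )
        true_params[seg] = params
    return PETStudy(tacs=tacs, blood=blood, schedule=schedule,
                    extraction=extraction, true_params=true_params, state=state)


# ---------------------------------------------------------------------------
# on-disk interfaces
# ---------------------------------------------------------------------------

def write_cmr_study(study: CMRStudy, out_dir) -> None:
    """NIfTI 4-D volumes + JSON protocol sidecar + AIF ground-truth CSV."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)

    def save(arr, name):
        # (t, z, y, x) -> NIfTI (x, y, z, t); (z, y, x) -> (x, y, z)
        axes = (3, 2, 1, 0) if arr.ndim == 4 else (2, 1, 0)
        data = np.transpose(arr, axes)
        nib.save(nib.Nifti1Image(np.asarray(data, np.float32), aff), out / name)

    save(study.highres, "highres.nii")
    save(study.lowres_echo1[:, None], "lowres_echo1.nii")
    save(study.lowres_echo2[:, None], "lowres_echo2.nii")
    save(study.myo_mask.astype(np.float32), "myo_mask.nii")
    save(study.segment_maps.astype(np.float32), "segment_maps.nii")
    save(study.pd_highres.astype(np.float32), "pd_highres.nii")
    save(study.pd_lowres.astype(np.float32)[None], "pd_lowres.nii")
    save(study.blood_mask.astype(np.float32)[None], "blood_mask.nii")
    sidecar = {
        "state": study.state,
        "times_s": study.times.tolist(),
        "protocol": asdict(study.protocol),
        "protocol_aif": asdict(study.protocol_aif),
        "relax_myo": asdict(study.relax_myo),
        "relax_blood": asdict(study.relax_blood),
    }
    (out / "protocol.json").write_text(json.dumps(sidecar, indent=2))
    study.true_aif.to_frame().to_csv(out / "true_aif.csv", index=False)


def read_cmr_study(in_dir) -> CMRStudy:
    """Load a study written by :func:`write_cmr_study` (NIfTI + sidecar)."""
    import nibabel as nib

    src = Path(in_dir)

    def load(name, ndim):
        arr = np.asarray(nib.load(src / name).dataobj, float)
        axes = (3, 2, 1, 0) if ndim == 4 else (2, 1, 0)
        return np.transpose(arr, axes)

    sidecar = json.loads((src / "protocol.json").read_text())
    times = np.asarray(sidecar["times_s"], float)
    aif_df = pd.read_csv(src / "true_aif.csv")
    return CMRStudy(
        times=times,
        highres=load("highres.nii", 4),
        lowres_echo1=load("lowres_echo1.nii", 4)[:, 0],
        lowres_echo2=load("lowres_echo2.nii", 4)[:, 0],
        pd_highres=load("pd_highres.nii", 3),
        pd_lowres=load("pd_lowres.nii", 3)[0],
        myo_mask=load("myo_mask.nii", 3) > 0.5,
        segment_maps=np.rint(load("segment_maps.nii", 3)).astype(np.int32),
        blood_mask=load("blood_mask.nii", 3)[0] > 0.5,
        protocol=SRProtocol(**sidecar["protocol"]),
        protocol_aif=SRProtocol(**sidecar["protocol_aif"]),
        relax_myo=RelaxationParams(**sidecar["relax_myo"]),
        relax_blood=RelaxationParams(**sidecar["relax_blood"]),
        true_conc=np.zeros((len(times), 0, 0, 0)),
        true_aif=AIFCurve(times=aif_df["time_s"].to_numpy(),
                          values=aif_df.iloc[:, 1].to_numpy(), unit="mmol/L"),
        state=sidecar["state"],
    )


def write_pet_study(study: PETStudy, out_dir) -> None:
    """CSV TAC table + blood curve CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.to_frame().to_csv(out / f"tacs_{study.state}.csv", index=False)
    study.blood.to_frame().to_csv(out / f"blood_{study.state}.csv", index=False)
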