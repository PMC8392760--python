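"""Digital phantom: ground-truthed cohorts for the whole pipeline.

Each synthetic subject has a systemic bolus curve (gamma-variate first
pass plus a recirculation tail), which arrives at the brain after a
short delay — the *local* input function that drives both the carotid
signal and the grey-matter tissue response — and at the wrist detector
after a longer delay and mono-exponential dispersion, in uncalibrated
detector units.  Dynamic images place the local input in two carotid
tubes and the one-tissue response in a grey-matter shell, blur with a
Gaussian PSF (partial volume), frame-average onto the scanner schedule
and add frame-duration-scaled Gaussian noise.

A vasodilator challenge ("acetazolamide") raises true CBF from about
0.45 to about 0.60 mL/min/g, shortens the brain arrival by 3 s and
increases the local bolus area by 15%, emulating the faster cerebral
inflow the method must distinguish from the wrist measurement.

Ground truth lives only in the returned/serialized ``truth`` records;
the analysis pipeline never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .blood import BloodMeasurement, DispersionModel, apply_dispersion
from .carotid_segmentation import DynamicImage, VoiMask
from .curves import FrameSchedule, TimeActivityCurve, default_frame_schedule
from .kinetics import KineticParams, simulate_tissue

__all__ = [
    "PhantomSubject",
    "PhantomGeometry",
    "sample_subject",
    "generate_aif",
    "systemic_curve",
    "render_dynamic_image",
    "generate_wrist_measurement",
    "generate_cohort_subjects",
    "carotid_signal_voxels",
    "DEFAULT_NOISE_SCALE",
    "DEFAULT_COHORT_SIZE",
]

#: Multiplier on the frame-statistics noise model; 1.0 gives roughly 5%
#: relative noise per voxel at the bolus peak in a 5-s frame.
DEFAULT_NOISE_SCALE = 1.0
#: Paired-scan cohort size (number of subjects) used throughout.
DEFAULT_COHORT_SIZE = 22

_CBF_DIST = {"baseline": (0.45, 0.05), "acetazolamide": (0.60, 0.07)}
_ACZ_DELAY_SHIFT_S = 3.0
_ACZ_LOCAL_AREA_FACTOR = 1.15


@dataclass(frozen=True)
class PhantomSubject:
    """Ground-truth generative parameters for one scan."""

    # bolus shape: gamma-variate + recirculation tail
    amplitude: float  # kBq/mL at the first-pass peak
    alpha: float  # gamma-variate shape
    t0: float  # systemic arrival time, s
    tp: float  # time-to-peak after arrival, s
    tail_frac: float  # recirculation level relative to the peak
    tail_rise: float  # s
    tail_decay: float  # s
    # physiology
    cbf_true: float  # mL/min/g
    k2_true: float  # 1/min
    va_true: float  # fraction
    brain_delay: float  # s, systemic -> carotid
    wrist_delay: float  # s, systemic -> wrist detector
    wrist_tau: float  # s, line dispersion constant
    wrist_scale: float  # arbitrary detector-unit gain
    local_area_factor: float  # challenge effect on the local bolus
    condition: str  # "baseline" | "acetazolamide"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def kinetic_params(self) -> KineticParams:
        return KineticParams(self.cbf_true, self.k2_true, self.va_true)


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel-grid layout of the phantom head."""

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: float = 2.0
    carotid_offset_vox: int = 8  # two tubes at centre x -+ offset
    carotid_radius_vox: float = 2.0
    carotid_z_range: tuple[int, int] = (4, 28)
    gm_shell: tuple[float, float] = (0.55, 0.95)  # normalized radii
    gm_semiaxes_vox: tuple[float, float, float] = (26.0, 26.0, 14.0)
    psf_fwhm_mm: float = 5.0

    @property
    def psf_sigma_vox(self) -> float:
        return self.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / self.voxel_size_mm


def sample_subject(rng_seed: int, condition: str = "baseline") -> PhantomSubject:
    """Draw one subject; deterministic given the seed.

    The same seed gives the same bolus shape and physiology under both
    conditions (common random numbers), so baseline/challenge scans of
    one subject are properly paired; only the condition effects differ.
    """
    if condition not in _CBF_DIST:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng_seed)
    amplitude = float(np.clip(rng.normal(60.0, 8.0), 30.0, None))
    alpha = float(rng.uniform(2.0, 4.0))
    t0 = float(rng.uniform(8.0, 14.0))
    tp = float(rng.uniform(8.0, 14.0))
    tail_frac = float(rng.uniform(0.12, 0.20))
    tail_rise = float(rng.uniform(15.0, 25.0))
    tail_decay = float(rng.uniform(200.0, 300.0))
    brain_delay = float(rng.uniform(3.0, 7.0))
    wrist_delay = brain_delay + float(rng.uniform(8.0, 14.0))
    dist_vol = float(np.clip(rng.normal(0.9, 0.05), 0.6, 1.2))  # mL/g
    wrist_scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    # shared standard-normal draw keeps the paired challenge CBF above baseline
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    mu, sd = _CBF_DIST[condition]
    cbf = max(mu + sd * z, 0.2)
    if condition == "acetazolamide":
        brain_delay = max(brain_delay - _ACZ_DELAY_SHIFT_S, 0.0)
        area = _ACZ_LOCAL_AREA_FACTOR
    else:
        area = 1.0
    return PhantomSubject(
        amplitude=amplitude,
        alpha=alpha,
        t0=t0,
        tp=tp,
        tail_frac=tail_frac,
        tail_rise=tail_rise,
        tail_decay=tail_decay,
        cbf_true=cbf,
        k2_true=cbf / dist_vol,
        va_true=0.0,
        brain_delay=brain_delay,
        wrist_delay=wrist_delay,
        wrist_tau=15.0,
        wrist_scale=wrist_scale,
        local_area_factor=area,
        condition=condition,
    )


def _bolus(subject: PhantomSubject, t: np.ndarray) -> np.ndarray:
    """Gamma-variate first pass plus recirculation tail at times t (s),
    relative to systemic arrival."""
    tt = np.maximum(t - subject.t0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        peak = np.where(
            tt > 0,
            (tt / subject.tp) ** subject.alpha * np.exp(subject.alpha * (1.0 - tt / subject.tp)),
            0.0,
        )
    tail = (
        subject.tail_frac
        * (1.0 - np.exp(-tt / subject.tail_rise))
        * np.exp(-tt / subject.tail_decay)
    )
    return subject.amplitude * (peak + tail)


def systemic_curve(subject: PhantomSubject, t: np.ndarray) -> np.ndarray:
    """The subject's systemic bolus concentration at times t (s)."""
    return _bolus(subject, np.asarray(t, dtype=float))


def generate_aif(subject: PhantomSubject, t: np.ndarray | None = None) -> TimeActivityCurve:
    """The brain-local arterial input function on a 1-s grid (0-600 s):
    the systemic bolus delayed by ``brain_delay`` and scaled by the
    condition's local area factor."""
    if t is None:
        t = np.arange(0.0, 601.0)
    vals = subject.local_area_factor * systemic_curve(subject, np.asarray(t) - subject.brain_delay)
    return TimeActivityCurve(np.asarray(t, dtype=float), vals, grid_kind="uniform-1s")


def _indicators(geom: PhantomGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(carotid, grey-matter) indicator volumes; disjoint by construction."""
    nx, ny, nz = geom.shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    carotid = np.zeros(geom.shape, dtype=float)
    z0, z1 = geom.carotid_z_range
    in_z = (z >= z0) & (z < z1)
    for side in (-1, 1):
        r2 = (x - (cx + side * geom.carotid_offset_vox)) ** 2 + (y - cy) ** 2
        carotid[(r2 <= geom.carotid_radius_vox**2) & in_z] = 1.0
    ax, ay, az = geom.gm_semiaxes_vox
    rho = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)
    lo, hi = geom.gm_shell
    gm = ((rho > lo) & (rho <= hi)).astype(float)
    # keep tissue clear of the vessels (with a safety margin for the PSF)
    for side in (-1, 1):
        r2 = (x - (cx + side * geom.carotid_offset_vox)) ** 2 + (y - cy) ** 2
        gm[r2 <= (geom.carotid_radius_vox + 2.0) ** 2] = 0.0
    return carotid, gm


def carotid_signal_voxels(geom: PhantomGeometry, threshold: float = 0.01) -> int:
    """Number of voxels receiving carotid signal after the PSF."""
    carotid, _ = _indicators(geom)
    blurred = gaussian_filter(carotid, geom.psf_sigma_vox) if geom.psf_fwhm_mm > 0 else carotid
    return int(np.count_nonzero(blurred > threshold))


def _frame_average(values_1s: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Frame means of a 1-s curve starting at t = 0."""
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.frame_start, schedule.frame_duration)):
        out[i] = values_1s[int(s) : int(s + d)].mean()
    return out


def render_dynamic_image(
    subject: PhantomSubject,
    geom: PhantomGeometry | None = None,
    schedule: FrameSchedule | None = None,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    rng_seed: int = 0,
) -> tuple[DynamicImage, VoiMask]:
    """Render one dynamic scan and its grey-matter mask.

    Carotid voxels carry the local input function, grey-matter voxels
    the one-tissue response; each frame is the frame-average of the 1-s
    curves, blurred with the PSF, with zero-mean Gaussian noise of
    variance proportional to signal / frame duration.
    """
    geom = geom or PhantomGeometry()
    schedule = schedule or default_frame_schedule()
    if carotid_signal_voxels(geom, threshold=0.0) == 0:
        raise ValueError("geometry produces no carotid signal")
    rng = np.random.default_rng(rng_seed)
    local = generate_aif(subject, np.arange(0.0, schedule.total_duration + 1.0))
    tissue = simulate_tissue(local, subject.kinetic_params)
    car_f = _frame_average(local.value, schedule)
    gm_f = _frame_average(tissue.value, schedule)
    carotid, gm = _indicators(geom)
    frames = np.empty((*geom.shape, schedule.n_frames), dtype=np.float32)
    sigma = geom.psf_sigma_vox
    for i in range(schedule.n_frames):
        vol = carotid * car_f[i] + gm * gm_f[i]
        if geom.psf_fwhm_mm > 0:
            vol = gaussian_filter(vol, sigma)
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(
                (np.maximum(vol, 0.0) + 1.0) / schedule.frame_duration[i]
            )
            vol = vol + rng.normal(0.0, 1.0, size=vol.shape) * sd
        frames[..., i] = vol
    img = DynamicImage(frames, (geom.voxel_size_mm,) * 3, schedule)
    # the returned grey-matter mask is the PSF-safe core of the shell, so
    # region means are not diluted by spill-out at the tissue boundary
    if geom.psf_fwhm_mm > 0:
        core = (gm > 0) & (gaussian_filter(gm, sigma) > 0.99)
    else:
        core = gm > 0
    return img, VoiMask(core)


def generate_wrist_measurement(
    subject: PhantomSubject,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    rng_seed: int = 0,
    duration_s: float = 600.0,
) -> BloodMeasurement:
    """Simulate the 1-Hz wrist detector record plus calibration sample.

    The wrist concentration is the local input function further delayed
    by (wrist_delay - brain_delay) and dispersed with ``wrist_tau``; the
    detector reports it in arbitrary units (per-subject gain) with
    Gaussian noise whose variance scales with the signal (count
    statistics): 1% of peak at the peak per unit noise scale, falling
    as sqrt(signal) toward the tail, plus a small electronic floor.
    The single well-counter sample is the true (undispersed)
    concentration at t = 300 s.
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(0.0, duration_s + 1.0)
    # local AIF shifted by the extra wrist transit (wrist_delay - brain_delay)
    wrist_true = subject.local_area_factor * systemic_curve(subject, t - subject.wrist_delay)
    wrist_conc = TimeActivityCurve(t, wrist_true, grid_kind="uniform-1s")
    dispersed = apply_dispersion(wrist_conc, DispersionModel(subject.wrist_tau))
    counts = subject.wrist_scale * dispersed.value
    if noise_scale > 0:
        peak = wrist_true.max()
        sd = 0.01 * noise_scale * subject.wrist_scale * (
            np.sqrt(np.maximum(dispersed.value, 0.0) * peak) + 0.1 * peak
        )
        counts = counts + rng.normal(0.0, 1.0, size=counts.shape) * sd
    calib_value = float(np.interp(300.0, t, wrist_true))
    return BloodMeasurement(
        counts=TimeActivityCurve(t, counts, grid_kind="uniform-1s"),
        calibration_time=300.0,
        calibration_value=calib_value,
    )


def generate_cohort_subjects(
    n_subjects: int = DEFAULT_COHORT_SIZE,
    seed: int = 0,
    conditions: tuple[str, ...] = ("baseline", "acetazolamide"),
) -> list[PhantomSubject]:
    """Paired subjects for every condition; per-subject seeds are spawned
    from the master seed so cohorts are reproducible and disjoint seeds
    give distinct cohorts."""
    if n_subjects < 3:
        raise ValueError("cohort needs at least 3 subjects")
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    return [
        sample_subject(s_seed, condition)
        for s_seed in subject_seeds
        for condition in conditions
    ]
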