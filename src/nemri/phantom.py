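"""Digital phantoms for every input the analysis pipeline consumes.

Each generator pairs its output with the ground truth it was built from, so
downstream stages (motion-tracked pharmacokinetics, T2* relaxometry, ESR
spin quantification, hemolysis reduction) can be validated without any
acquired data.

Conventions
-----------
* Echo times are stored in milliseconds and converted to seconds wherever
  they multiply a relaxivity (mM^-1 s^-1) or relaxation rate (s^-1).
* The dynamic time axis is in minutes with the injection at t = 0, so the
  accumulation rate tau is in min^-1 and half-lives come out in minutes.
* Magnitude-image noise is Rician: independent Gaussian noise of standard
  deviation sigma on the two complex channels before the modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .constants import GAMMA_PROTON

__all__ = [
    "Organ",
    "TissueState",
    "AcquisitionProtocol",
    "ContrastAgentSpec",
    "AccumulationTruth",
    "Ellipse",
    "PhantomDefinition",
    "DynamicSeries",
    "DynamicTruth",
    "MultiEchoTruth",
    "ESRTruth",
    "HemolysisTruth",
    "build_phantom",
    "default_abdominal_phantom",
    "default_tissues",
    "gre_signal",
    "accumulation_concentration",
    "rician",
    "motion_displacement",
    "warp_image",
    "simulate_dynamic_series",
    "simulate_multiecho_volume",
    "simulate_esr_spectrum",
    "simulate_hemolysis_curve",
]


class Organ(IntEnum):
    """Integer organ codes of the label grid."""

    BACKGROUND = 0
    LIVER = 1
    KIDNEY_CORTEX = 2
    KIDNEY_PYRAMID = 3
    AORTA_WALL = 4
    PLAQUE = 5


@dataclass(frozen=True)
class TissueState:
    """Equilibrium signal and relaxation of one tissue compartment.

    Parameters
    ----------
    m0 : equilibrium signal (arbitrary units), >= 0.
    r1 : longitudinal relaxation rate (s^-1), > 0.
    r2star_baseline : native effective transverse rate R2*(0) (s^-1), > 0.
    """

    m0: float
    r1: float
    r2star_baseline: float

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError("M0 must be >= 0")
        if self.r1 <= 0:
            raise ValueError("R1 must be > 0")
        if self.r2star_baseline <= 0:
            raise ValueError("R2*(0) must be > 0")

    @property
    def t2star_ms(self) -> float:
        """Native T2* in milliseconds (1000 / R2*(0))."""
        return 1000.0 / self.r2star_baseline


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Spoiled gradient-echo acquisition parameters.

    Defaults follow the dynamic liver protocol (flip 30 deg, TE 3.4 ms,
    TR ~ 30 ms, one echo, ~60 s per dynamic frame, 1 mm slices).
    """

    flip_deg: float = 30.0
    te_ms: float = 3.4
    tr_ms: float = 30.0
    n_echoes: int = 1
    delta_te_ms: float | None = None
    frame_duration_s: float = 60.0
    slice_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_deg < 180.0:
            raise ValueError("flip angle must lie in (0, 180) degrees")
        if self.te_ms <= 0:
            raise ValueError("TE must be > 0")
        if self.tr_ms <= self.te_ms:
            raise ValueError("TR must exceed TE")
        if self.n_echoes < 1:
            raise ValueError("echo count must be >= 1")
        if self.n_echoes > 1 and (self.delta_te_ms is None or self.delta_te_ms <= 0):
            raise ValueError("delta TE must be > 0 for multi-echo protocols")
        if self.frame_duration_s <= 0:
            raise ValueError("frame duration must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo train TE_k = TE1 + k * dTE (ms)."""
        if self.n_echoes == 1:
            return np.asarray([self.te_ms])
        return self.te_ms + self.delta_te_ms * np.arange(self.n_echoes)


# Multi-echo aorta protocol used for T2* mapping: TR/TE1/dTE = 1300/2.8/3.6 ms,
# flip 60 deg, 15 echoes (last echo at 2.8 + 14 * 3.6 = 53.2 ms).
MULTIECHO_PROTOCOL = AcquisitionProtocol(
    flip_deg=60.0, te_ms=2.8, tr_ms=1300.0, n_echoes=15, delta_te_ms=3.6
)


@dataclass(frozen=True)
class ContrastAgentSpec:
    """Relaxometric and dosing properties of an SPIO-loaded nano-emulsion.

    r2* defaults to 45 mM^-1 s^-1, the upper end of the measured 42-45
    range; r1 is nearly zero for oil-encapsulated SPIO, which is what makes
    the simplified signal model valid.
    """

    r2star_per_mM_s: float = 45.0
    r1_per_mM_s: float = 0.05
    iron_molar_mass_g_mol: float = 55.845
    dose_mg_per_kg: float = 3.0

    def __post_init__(self) -> None:
        if self.r2star_per_mM_s <= 0:
            raise ValueError("r2* must be > 0")
        if not 0 <= self.r1_per_mM_s < 0.5 * self.r2star_per_mM_s:
            raise ValueError("r1 must be >= 0 and much smaller than r2*")
        if self.iron_molar_mass_g_mol <= 0:
            raise ValueError("molar mass must be > 0")


@dataclass(frozen=True)
class AccumulationTruth:
    """Ground-truth parameters of the first-order accumulation model
    C(t) = Cmax * (1 - exp(-tau * t))."""

    cmax_mM: float
    tau_per_min: float

    def __post_init__(self) -> None:
        if self.cmax_mM < 0:
            raise ValueError("Cmax must be >= 0")
        if self.tau_per_min <= 0:
            raise ValueError("tau must be > 0")

    @property
    def half_life_min(self) -> float:
        return math.log(2.0) / self.tau_per_min

    @classmethod
    def from_half_life(cls, cmax_mM: float, half_life_min: float) -> "AccumulationTruth":
        return cls(cmax_mM=cmax_mM, tau_per_min=math.log(2.0) / half_life_min)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned elliptical organ geometry on the voxel grid."""

    label: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        a, b = self.semi_axes
        return ((rr - self.center[0]) / a) ** 2 + ((cc - self.center[1]) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomDefinition:
    """Label grid plus per-organ tissue state.

    The label grid assigns every voxel exactly one organ code; unlabeled
    voxels are background. Background must still carry a TissueState (air
    is modeled as a very low-M0 compartment).
    """

    labels: np.ndarray
    voxel_size_mm: float
    tissues: Mapping[int, TissueState]

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be > 0")
        if not np.any(self.labels > 0):
            raise ValueError("phantom has no labeled organ voxel")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.tissues)
        if missing:
            raise ValueError(f"labels without tissue state: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def _map(self, attr: str) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=float)
        for lab, tissue in self.tissues.items():
            out[self.labels == lab] = getattr(tissue, attr)
        return out

    @property
    def m0_map(self) -> np.ndarray:
        return self._map("m0")

    @property
    def r1_map(self) -> np.ndarray:
        return self._map("r1")

    @property
    def r2star_map(self) -> np.ndarray:
        """Native R2*(0) per voxel (s^-1)."""
        return self._map("r2star_baseline")

    @property
    def t2star_map_ms(self) -> np.ndarray:
        """Native T2* per voxel (ms); background included."""
        return 1000.0 / self.r2star_map


def default_tissues() -> dict[int, TissueState]:
    """Plausible 4.7 T tissue states (arbitrary M0 units).

    Liver T2* ~ 25 ms, renal cortex 40 ms, pyramid 50 ms, aorta wall 20 ms,
    plaque 9 ms (iron-laden lesions are short-T2*); air has near-zero M0.
    """
    return {
        int(Organ.BACKGROUND): TissueState(m0=4.0, r1=0.3, r2star_baseline=200.0),
        int(Organ.LIVER): TissueState(m0=100.0, r1=1.2, r2star_baseline=40.0),
        int(Organ.KIDNEY_CORTEX): TissueState(m0=95.0, r1=0.9, r2star_baseline=25.0),
        int(Organ.KIDNEY_PYRAMID): TissueState(m0=90.0, r1=0.7, r2star_baseline=20.0),
        int(Organ.AORTA_WALL): TissueState(m0=85.0, r1=1.0, r2star_baseline=50.0),
        int(Organ.PLAQUE): TissueState(m0=80.0, r1=1.1, r2star_baseline=1000.0 / 9.0),
    }


def build_phantom(
    shape: tuple[int, int],
    geometries: Sequence[Ellipse],
    tissues: Mapping[int, TissueState] | None = None,
    voxel_size_mm: float = 0.16,
    seed: int | None = None,
    jitter_vox: float = 0.0,
) -> PhantomDefinition:
    """Rasterize organ geometries into a label grid.

    Organs may not overlap; a conflict is reported with the offending
    labels. ``jitter_vox`` optionally perturbs organ centers by a seeded
    uniform offset (deterministic for a fixed seed).
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("grid shape must be positive")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)
    for geom in geometries:
        if jitter_vox > 0:
            dr, dc = rng.uniform(-jitter_vox, jitter_vox, size=2)
            geom = replace(geom, center=(geom.center[0] + dr, geom.center[1] + dc))
        r0, c0 = geom.center
        a, b = geom.semi_axes
        if r0 - a < 0 or r0 + a > shape[0] - 1 or c0 - b < 0 or c0 + b > shape[1] - 1:
            raise ValueError(
                f"organ {Organ(geom.label).name} geometry does not fit inside the grid"
            )
        mask = geom.mask(shape)
        clash = labels[mask]
        if np.any(clash != 0):
            other = sorted({Organ(int(v)).name for v in clash[clash != 0]})
            raise ValueError(
                f"organ {Organ(geom.label).name} overlaps existing organ(s): {other}"
            )
        if not mask.any():
            raise ValueError(f"organ {Organ(geom.label).name} rasterizes to zero voxels")
        labels[mask] = geom.label
    return PhantomDefinition(
        labels=labels,
        voxel_size_mm=voxel_size_mm,
        tissues=dict(tissues) if tissues is not None else default_tissues(),
    )


def default_abdominal_phantom(
    shape: tuple[int, int] = (64, 64), seed: int | None = None
) -> PhantomDefinition:
    """Liver ellipse plus two kidney discs on a 64 x 64 grid."""
    h, w = shape
    geoms = [
        Ellipse(Organ.LIVER, (0.42 * h, 0.38 * w), (0.26 * h, 0.22 * w)),
        Ellipse(Organ.KIDNEY_CORTEX, (0.78 * h, 0.28 * w), (0.09 * h, 0.09 * w)),
        Ellipse(Organ.KIDNEY_PYRAMID, (0.78 * h, 0.68 * w), (0.09 * h, 0.09 * w)),
    ]
    return build_phantom(shape, geoms, seed=seed)


def default_aorta_phantom(
    shape: tuple[int, int] = (48, 48),
    plaque_t2star_ms: float = 9.0,
    wall_t2star_ms: float = 20.0,
) -> PhantomDefinition:
    """Aorta wall annulus with an eccentric plaque crescent for T2* mapping."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r = np.hypot(rr - h / 2, cc - w / 2)
    labels = np.zeros(shape, dtype=np.int16)
    labels[(r >= 8) & (r <= 14)] = Organ.AORTA_WALL
    plaque = (r >= 8) & (r <= 14) & (cc - w / 2 > 2) & (rr - h / 2 > -6)
    labels[plaque] = Organ.PLAQUE
    tissues = default_tissues()
    tissues[int(Organ.PLAQUE)] = TissueState(
        m0=80.0, r1=1.1, r2star_baseline=1000.0 / plaque_t2star_ms
    )
    tissues[int(Organ.AORTA_WALL)] = TissueState(
        m0=85.0, r1=1.0, r2star_baseline=1000.0 / wall_t2star_ms
    )
    return PhantomDefinition(labels=labels, voxel_size_mm=0.1, tissues=tissues)


# ---------------------------------------------------------------------------
# Forward signal models
# ---------------------------------------------------------------------------


def gre_signal(
    m0: np.ndarray | float,
    flip_deg: float,
    te_ms: float,
    r2star_s: np.ndarray | float,
    full_model: bool = False,
    tr_ms: float | None = None,
    r1_s: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Spoiled-GRE magnitude signal.

    The simplified model ``M0 sin(a) exp(-TE * R2*)`` assumes the
    longitudinal steady-state term is constant over the experiment (valid
    when the agent's r1 is negligible). With ``full_model=True`` the
    complete steady-state expression including the TR/R1 saturation factor
    is used; the phantom uses it only to validate the simplification.
    """
    alpha = math.radians(flip_deg)
    te_s = te_ms / 1000.0
    signal = np.multiply(m0, math.sin(alpha)) * np.exp(-te_s * np.asarray(r2star_s, dtype=float))
    if full_model:
        if tr_ms is None or r1_s is None:
            raise ValueError("full model requires TR and R1")
        e1 = np.exp(-(tr_ms / 1000.0) * np.asarray(r1_s, dtype=float))
        signal = signal * (1.0 - e1) / (1.0 - math.cos(alpha) * e1)
    return signal


def accumulation_concentration(
    t_min: np.ndarray | float, truth: AccumulationTruth
) -> np.ndarray:
    """First-order uptake C(t) = Cmax (1 - e^(-tau t)) for t > 0, else 0."""
    t = np.asarray(t_min, dtype=float)
    return np.where(t > 0, truth.cmax_mM * (1.0 - np.exp(-truth.tau_per_min * t)), 0.0)


def rician(rng: np.random.Generator, clean: np.ndarray, sigma: float) -> np.ndarray:
    """Rician-corrupted magnitude of a noiseless image."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return np.asarray(clean, dtype=float).copy()
    re = clean + rng.normal(0.0, sigma, size=np.shape(clean))
    im = rng.normal(0.0, sigma, size=np.shape(clean))
    return np.hypot(re, im)


def motion_displacement(
    shape: tuple[int, int], amplitude_vox: float, phase_rad: float
) -> np.ndarray:
    """Smooth respiratory-surrogate displacement field, shape (2, H, W).

    A sinusoidal-in-time bulk motion modulated by a broad Gaussian spatial
    envelope; displacement gradients stay well below 1 voxel/voxel for
    amplitudes up to ~10 voxels, so the warp remains invertible.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    env = np.exp(-(((rr - h / 2) / (0.6 * h)) ** 2 + ((cc - w / 2) / (0.6 * w)) ** 2))
    d_row = amplitude_vox * math.sin(phase_rad) * env
    d_col = 0.35 * amplitude_vox * math.sin(phase_rad + 0.9) * env
    return np.stack([d_row, d_col])


def warp_image(image: np.ndarray, displacement: np.ndarray, order: int = 3) -> np.ndarray:
    """Backward-warp: out(p) = image(p + d(p))."""
    h, w = image.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    coords = np.stack([rr + displacement[0], cc + displacement[1]])
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


# ---------------------------------------------------------------------------
# Dynamic series
# ---------------------------------------------------------------------------


@dataclass
class DynamicTruth:
    """Everything the dynamic simulator knows that an analyst would not."""

    accumulation: AccumulationTruth
    concentration_mM: np.ndarray
    noiseless_liver_mean: np.ndarray
    displacements: np.ndarray  # (T, 2, H, W) backward-warp fields
    liver_mask: np.ndarray
    noise_sigma: float
    motion_amplitude_vox: float

    @property
    def max_displacement(self) -> np.ndarray:
        """Per-frame maximum displacement magnitude (voxels)."""
        return np.max(np.hypot(self.displacements[:, 0], self.displacements[:, 1]), axis=(1, 2))


@dataclass
class DynamicSeries:
    """Time-ordered magnitude frames with timestamps (min; injection at 0)."""

    frames: np.ndarray  # (T, H, W)
    timestamps_min: np.ndarray  # strictly increasing; pre-injection negative
    protocol: AcquisitionProtocol
    agent: ContrastAgentSpec
    phantom: PhantomDefinition | None = None
    truth: DynamicTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.timestamps_min.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def simulate_dynamic_series(
    phantom: PhantomDefinition,
    protocol: AcquisitionProtocol,
    agent: ContrastAgentSpec,
    truth: AccumulationTruth,
    n_pre: int = 8,
    n_post: int = 45,
    injection_gap_min: float = 2.0,
    noise_sigma: float = 0.0,
    motion_amplitude_vox: float = 0.0,
    motion_period_min: float = 4.0,
    seed: int | None = None,
    uptake_organs: Sequence[int] = (Organ.LIVER,),
    full_model: bool = False,
) -> DynamicSeries:
    """Simulate a fused two-session dynamic liver acquisition.

    Pre-injection frames sit at negative times ending one frame before the
    injection at t = 0; acquisition resumes at ``injection_gap_min`` (no
    samples exist inside the gap, mirroring the time needed for the manual
    injection). Uptake follows the first-order model in the organs listed
    in ``uptake_organs``; all other tissues keep C = 0.
    """
    if n_pre < 1:
        raise ValueError("at least one pre-injection frame is required")
    if n_post < 1:
        raise ValueError("at least one post-injection frame is required")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if injection_gap_min <= 0:
        raise ValueError("injection gap must be > 0")

    liver_mask = phantom.mask(Organ.LIVER)
    if not liver_mask.any():
        raise ValueError("dynamic simulation requires at least one liver voxel")

    rng = np.random.default_rng(seed)
    dt_min = protocol.frame_duration_s / 60.0
    t_pre = -dt_min * np.arange(n_pre, 0, -1)
    t_post = injection_gap_min + dt_min * np.arange(n_post)
    times = np.concatenate([t_pre, t_post])

    conc = accumulation_concentration(times, truth)
    uptake_mask = np.isin(phantom.labels, np.asarray(uptake_organs, dtype=int))

    m0 = phantom.m0_map
    r2_base = phantom.r2star_map
    r1 = phantom.r1_map
    phase0 = rng.uniform(0.0, 2.0 * math.pi) if motion_amplitude_vox > 0 else 0.0

    frames = np.empty((times.size,) + phantom.shape)
    displacements = np.zeros((times.size, 2) + phantom.shape)
    noiseless_liver_mean = np.empty(times.size)
    for k, t in enumerate(times):
        r2 = r2_base + agent.r2star_per_mM_s * conc[k] * uptake_mask
        if full_model:
            r1_t = r1 + agent.r1_per_mM_s * conc[k] * uptake_mask
            clean = gre_signal(
                m0, protocol.flip_deg, protocol.te_ms, r2,
                full_model=True, tr_ms=protocol.tr_ms, r1_s=r1_t,
            )
        else:
            clean = gre_signal(m0, protocol.flip_deg, protocol.te_ms, r2)
        noiseless_liver_mean[k] = float(np.mean(clean[liver_mask]))
        if motion_amplitude_vox > 0:
            phase = phase0 + 2.0 * math.pi * t / motion_period_min
            disp = motion_displacement(phantom.shape, motion_amplitude_vox, phase)
            displacements[k] = disp
            clean = warp_image(clean, disp)
        frames[k] = rician(rng, clean, noise_sigma)

    return DynamicSeries(
        frames=frames,
        timestamps_min=times,
        protocol=protocol,
        agent=agent,
        phantom=phantom,
        truth=DynamicTruth(
            accumulation=truth,
            concentration_mM=conc,
            noiseless_liver_mean=noiseless_liver_mean,
            displacements=displacements,
            liver_mask=liver_mask,
            noise_sigma=noise_sigma,
            motion_amplitude_vox=motion_amplitude_vox,
        ),
        meta={
            "seed": seed,
            "n_pre": n_pre,
            "n_post": n_post,
            "injection_gap_min": injection_gap_min,
            "flip_deg": protocol.flip_deg,
            "te_ms": protocol.te_ms,
        },
    )


# ---------------------------------------------------------------------------
# Multi-echo volume
# ---------------------------------------------------------------------------


@dataclass
class MultiEchoTruth:
    t2star_ms: np.ndarray  # (S, H, W)
    s0: np.ndarray  # (S, H, W)
    gz_uT_per_mm: np.ndarray  # (S, H, W)
    noise_sigma: float


def sinc_factor(
    gz_uT_per_mm: np.ndarray | float, slice_thickness_mm: float, te_ms: np.ndarray | float
) -> np.ndarray:
    """|sinc(gamma Gz dz TE / 2)| signal modulation from a through-slice
    field gradient (sinc(x) = sin(x)/x, unnormalized; gamma in rad/s/T)."""
    gz_T_per_m = np.asarray(gz_uT_per_mm, dtype=float) * 1e-3  # uT/mm -> T/m
    x = GAMMA_PROTON * gz_T_per_m * (slice_thickness_mm * 1e-3) * (np.asarray(te_ms) / 1000.0) / 2.0
    return np.abs(np.sinc(x / math.pi))  # np.sinc is sin(pi x)/(pi x)


def simulate_multiecho_volume(
    phantoms: Sequence[PhantomDefinition] | PhantomDefinition,
    protocol: AcquisitionProtocol = MULTIECHO_PROTOCOL,
    gz_uT_per_mm: np.ndarray | float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
):
    """Simulate a multi-slice multi-echo magnitude volume with its true T2* map.

    ``phantoms`` gives one 2D phantom per slice (a single phantom is
    broadcast to one slice). The noiseless voxel signal at echo time TE_k is
    ``S0 exp(-TE_k / T2*) |sinc(gamma Gz dz TE_k / 2)|``.
    Returns ``(MultiEchoVolume, MultiEchoTruth)``.
    """
    from .relaxometry import MultiEchoVolume  # local import to avoid a cycle

    if protocol.n_echoes < 3:
        raise ValueError("at least 3 echoes are required")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if isinstance(phantoms, PhantomDefinition):
        phantoms = [phantoms]
    shape = phantoms[0].shape
    n_slices = len(phantoms)

    t2 = np.stack([p.t2star_map_ms for p in phantoms])
    labeled = np.stack([p.labels > 0 for p in phantoms])
    if np.any(t2[labeled] <= 0):
        raise ValueError("nonpositive T2* in a labeled voxel")
    alpha = math.radians(protocol.flip_deg)
    s0 = np.stack([p.m0_map for p in phantoms]) * math.sin(alpha)

    gz = np.broadcast_to(np.asarray(gz_uT_per_mm, dtype=float), (n_slices,) + shape).copy()
    te = protocol.echo_times_ms
    rng = np.random.default_rng(seed)
    data = np.empty((te.size, n_slices) + shape)
    for k, te_k in enumerate(te):
        clean = s0 * np.exp(-te_k / t2) * sinc_factor(gz, protocol.slice_thickness_mm, te_k)
        data[k] = rician(rng, clean, noise_sigma)

    vol = MultiEchoVolume(data=data, echo_times_ms=te, protocol=protocol)
    return vol, MultiEchoTruth(t2star_ms=t2, s0=s0, gz_uT_per_mm=gz, noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# ESR spectra
# ---------------------------------------------------------------------------


@dataclass
class ESRTruth:
    concentration_mol_per_g: float
    double_integral: float  # mass-normalized noiseless double integral
    center_mT: float
    pp_width_mT: float
    lineshape: str


#: Arbitrary spectrometer gain: derivative intensity per (mol/g * g) of spins.
ESR_GAIN = 1.0e9


def _gaussian_derivative(b: np.ndarray, center: float, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Gaussian absorption line.

    The derivative extrema sit at center +/- sigma, so the peak-to-peak
    width equals 2 sigma.
    """
    sigma = pp_width / 2.0
    x = b - center
    absorption = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    return -x / sigma**2 * absorption

def _lorentzian_derivative(b: np.ndarray, center: float, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Lorentzian absorption line
    (p-p width = 2 Gamma / sqrt(3) with Gamma the half-width)."""
    gamma = pp_width * math.sqrt(3.0) / 2.0
    x = b - center
    return -2.0 * gamma * x / (math.pi * (gamma**2 + x**2) ** 2)


def simulate_esr_spectrum(
    concentration_mol_per_g: float,
    center_mT: float = 320.0,
    pp_width_mT: float = 80.0,
    field_mT: np.ndarray | None = None,
    lineshape: str = "gaussian",
    noise_sigma: float = 0.0,
    seed: int | None = None,
    mass_g: float = 0.1,
    freq_GHz: float = 9.54,
):
    """First-derivative ESR spectrum of a superparamagnetic iron-oxide line.

    The double integral of the noiseless spectrum equals
    ``concentration * mass * ESR_GAIN``, i.e. it is linear in the spin
    content. Default line: center ~320 mT (g ~ 2.12 at X band), 80 mT
    peak-to-peak, 0.7 mT/pt sampling. Returns ``(ESRSpectrum, ESRTruth)``.
    """
    from .esr import ESRSpectrum  # local import to avoid a cycle

    if concentration_mol_per_g < 0:
        raise ValueError("concentration must be >= 0")
    if pp_width_mT <= 0:
        raise ValueError("peak-to-peak width must be > 0")
    if field_mT is None:
        field_mT = np.arange(center_mT - 3.2 * pp_width_mT, center_mT + 3.2 * pp_width_mT, 0.7)
    field_mT = np.asarray(field_mT, dtype=float)
    if np.any(np.diff(field_mT) <= 0):
        raise ValueError("field axis must be strictly increasing")
    if field_mT[0] > center_mT - 3.0 * pp_width_mT or field_mT[-1] < center_mT + 3.0 * pp_width_mT:
        raise ValueError("field axis too narrow: must span center +/- 3 widths")

    shape_fn = {"gaussian": _gaussian_derivative, "lorentzian": _lorentzian_derivative}
    if lineshape not in shape_fn:
        raise ValueError(f"unknown lineshape {lineshape!r}")
    area = concentration_mol_per_g * mass_g * ESR_GAIN
    intensity = area * shape_fn[lineshape](field_mT, center_mT, pp_width_mT)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=field_mT.size)

    spectrum = ESRSpectrum(
        field_mT=field_mT, intensity=intensity, freq_GHz=freq_GHz, mass_g=mass_g
    )
    truth = ESRTruth(
        concentration_mol_per_g=concentration_mol_per_g,
        double_integral=concentration_mol_per_g * ESR_GAIN,
        center_mT=center_mT,
        pp_width_mT=pp_width_mT,
        lineshape=lineshape,
    )
    return spectrum, truth


# ---------------------------------------------------------------------------
# Hemolysis kinetics
# ---------------------------------------------------------------------------


@dataclass
class HemolysisTruth:
    t50_min: float
    steepness_per_min: float


def simulate_hemolysis_curve(
    t50_min: float,
    steepness_per_min: float = 0.08,
    time_min: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    label: str = "sample",
    dose_mg_per_l: float = 1000.0,
):
    """Logistic free-radical hemolysis kinetics, 50% lysis at t = T50.

    Returns ``(HemolysisCurve, HemolysisTruth)``. Noise is additive
    Gaussian, clipped to the physical [0, 100]% range.
    """
    from .krl import HemolysisCurve  # local import to avoid a cycle

    if t50_min <= 0:
        raise ValueError("T50 must be > 0")
    if steepness_per_min <= 0:
        raise ValueError("steepness must be > 0")
    if time_min is None:
        time_min = np.arange(0.0, max(300.0, 2.0 * t50_min), 1.0)
    time_min = np.asarray(time_min, dtype=float)
    from scipy.special import expit

    clean = 100.0 * expit(steepness_per_min * (time_min - t50_min))
    if clean.max() < 50.0 or time_min[-1] < t50_min:
        raise ValueError("sampling grid never reaches the 50% crossing")
    values = clean
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(clean + rng.normal(0.0, noise_sigma, size=time_min.size), 0.0, 100.0)
    curve = HemolysisCurve(
        time_min=time_min, hemolysis_pct=values, label=label, dose_mg_per_l=dose_mg_per_l
    )
    return curve, HemolysisTruth(t50_min=t50_min, steepness_per_min=steepness_per_min)
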