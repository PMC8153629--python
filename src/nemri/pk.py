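"""Liver-uptake pharmacokinetics of SPIO-loaded nano-emulsions.

The chain implemented here converts a motion-tracked liver signal S(t)
from a dynamic spoiled-GRE acquisition into an apparent blood half-life:

1. normalize to the pre-injection baseline, S_norm(t) = S(t)/S(0);
2. invert the mono-exponential signal model,
   C(t) = -ln(S_norm(t)) / (TE * r2*), with TE in seconds and r2* in
   mM^-1 s^-1, so C is in mM;
3. fit the first-order accumulation model C(t) = Cmax (1 - e^(-tau t))
   by Levenberg-Marquardt over the post-injection samples;
4. report t1/2 = ln(2) / tau.

Because the agent's longitudinal relaxivity is almost zero, signal changes
are attributed purely to R2*; the full steady-state model is available in
the phantom to bound the error of that simplification.

The module also carries the small dose/ratio arithmetic of the study
(mass dose to molar dose, antibody:droplet ratio, drug loading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .constants import AVOGADRO
from .motion import SignalTimeCourse

__all__ = [
    "NormalizedTimeCourse",
    "ConcentrationCurve",
    "PKFit",
    "estimate_frame_times",
    "fuse_sessions",
    "normalize_signal",
    "signal_to_concentration",
    "fit_accumulation",
    "half_life",
    "tau_from_half_life",
    "convert_dose",
    "antibodies_per_droplet",
    "loading_mg_per_g",
]

TAU_MIN = 1e-6  # min^-1, lower fit bound
TAU_MAX = 10.0  # min^-1, upper fit bound


@dataclass
class NormalizedTimeCourse:
    timestamps_min: np.ndarray
    s_norm: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        if np.any(self.s_norm <= 0):
            raise ValueError("normalized signal must be > 0 everywhere")


@dataclass
class ConcentrationCurve:
    timestamps_min: np.ndarray
    concentration_mM: np.ndarray
    te_ms: float
    r2star_per_mM_s: float


@dataclass
class PKFit:
    """Accumulation-fit result; ``half_life_min * tau_per_min == ln 2``."""

    cmax_mM: float
    tau_per_min: float
    half_life_min: float
    rss: float
    cmax_stderr: float | None
    tau_stderr: float | None
    success: bool
    at_bound: bool = False
    message: str = ""


def estimate_frame_times(
    total_duration: float, n_frames: int, offset: float = 0.0
) -> np.ndarray:
    """Uniform frame-center timestamps of one dynamic session.

    The per-frame time is the total scan time divided by the number of
    dynamic images obtained (e.g. 500 s over 10 frames -> 50 s spacing);
    timestamps sit at frame centers, shifted by ``offset``. Units are
    whatever ``total_duration`` is in.
    """
    if total_duration <= 0:
        raise ValueError("duration must be > 0")
    if n_frames < 1:
        raise ValueError("frame count must be >= 1")
    spacing = total_duration / n_frames
    return offset + spacing * (np.arange(n_frames) + 0.5)


def fuse_sessions(
    pre: SignalTimeCourse, post: SignalTimeCourse, injection_delay_min: float
) -> SignalTimeCourse:
    """Fuse the pre- and post-injection dynamic sessions on one time axis.

    The injection defines t = 0. Post-injection timestamps are shifted so
    the first post frame sits at the measured injection delay; pre
    timestamps are shifted to negative values ending one pre-session frame
    interval before the injection.
    """
    if injection_delay_min <= 0:
        raise ValueError("injection delay must be > 0")
    if post.timestamps_min.size == 0:
        raise ValueError("post-injection course is empty")
    pre_t = pre.timestamps_min
    spacing = float(np.median(np.diff(pre_t))) if pre_t.size > 1 else injection_delay_min
    new_pre = pre_t - pre_t[-1] - spacing
    new_post = post.timestamps_min - post.timestamps_min[0] + injection_delay_min
    t = np.concatenate([new_pre, new_post])
    if np.any(np.diff(t) <= 0):
        raise ValueError("fused sessions have overlapping timestamps")
    return SignalTimeCourse(
        timestamps_min=t,
        mean=np.concatenate([pre.mean, post.mean]),
        sd=np.concatenate([pre.sd, post.sd]),
        n_voxels=np.concatenate([pre.n_voxels, post.n_voxels]),
    )


def normalize_signal(
    course: SignalTimeCourse, baseline_mode: str = "first-frame"
) -> NormalizedTimeCourse:
    """Normalize the signal to its pre-injection baseline.

    ``first-frame`` uses the first dynamic acquisition (the convention of
    the analysis this reproduces); ``pre-injection-mean`` averages all
    frames with negative timestamps, which is less sensitive to
    single-frame noise.
    """
    if baseline_mode == "first-frame":
        baseline = float(course.mean[0])
    elif baseline_mode == "pre-injection-mean":
        pre = course.mean[course.timestamps_min < 0]
        if pre.size == 0:
            raise ValueError("no pre-injection frames to average")
        baseline = float(pre.mean())
    else:
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")
    if baseline <= 0:
        raise ValueError("baseline signal must be > 0")
    return NormalizedTimeCourse(
        timestamps_min=course.timestamps_min.copy(),
        s_norm=course.mean / baseline,
        baseline=baseline,
    )


def signal_to_concentration(
    norm: NormalizedTimeCourse, te_ms: float, r2star_per_mM_s: float
) -> ConcentrationCurve:
    """Invert the signal model: C(t) = -ln(S_norm(t)) / (TE * r2*).

    TE is converted from ms to seconds so C comes out in mM. Values of
    S_norm above 1 (noise) yield slightly negative concentrations; these
    are retained — clamping them to zero would bias the accumulation fit.
    """
    if te_ms <= 0 or r2star_per_mM_s <= 0:
        raise ValueError("TE and r2* must be > 0")
    bad = np.nonzero(norm.s_norm <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive normalized signal at frame {bad[0]}")
    te_s = te_ms / 1000.0
    conc = -np.log(norm.s_norm) / (te_s * r2star_per_mM_s)
    return ConcentrationCurve(
        timestamps_min=norm.timestamps_min.copy(),
        concentration_mM=conc,
        te_ms=te_ms,
        r2star_per_mM_s=r2star_per_mM_s,
    )


def _accumulation_model(t, cmax, tau):
    return cmax * (1.0 - np.exp(-tau * t))


def fit_accumulation(
    curve: ConcentrationCurve,
    cmax_init: float | None = None,
    tau_init: float | None = None,
) -> PKFit:
    """Levenberg-Marquardt fit of C(t) = Cmax (1 - e^(-tau t)).

    Only post-injection samples (t > 0) enter the fit. Defaults: Cmax0 is
    the maximum observed concentration and tau0 the initial slope (from the
    first two post-injection samples) divided by Cmax0. Degenerate data
    (all concentrations <= 0) yields a failed result, not an exception.
    """
    post = curve.timestamps_min > 0
    t = curve.timestamps_min[post]
    c = curve.concentration_mM[post]
    if t.size < 4:
        raise ValueError("need at least 4 post-injection samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be increasing")
    if np.all(c <= 0):
        return PKFit(
            cmax_mM=np.nan, tau_per_min=np.nan, half_life_min=np.nan,
            rss=float(np.sum(c**2)), cmax_stderr=None, tau_stderr=None,
            success=False, message="degenerate data: no positive concentrations",
        )

    cmax0 = cmax_init if cmax_init is not None else float(max(c.max(), 1e-9))
    if tau_init is not None:
        tau0 = tau_init
    else:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        tau0 = slope / cmax0 if slope > 0 else math.log(2.0) / t[-1]
    tau0 = float(np.clip(tau0, 10 * TAU_MIN, 0.1 * TAU_MAX))

    model = Model(_accumulation_model)
    params = model.make_params(cmax=cmax0, tau=tau0)
    params["cmax"].set(min=1e-12, max=10.0 * max(c.max(), 1e-9))
    params["tau"].set(min=TAU_MIN, max=TAU_MAX)
    result = model.fit(
        c, params, t=t, method="leastsq", max_nfev=500,
        fit_kws={"xtol": 1e-12, "ftol": 1e-12},
    )

    tau = float(result.params["tau"].value)
    cmax = float(result.params["cmax"].value)
    at_bound = bool(
        tau >= TAU_MAX * (1 - 1e-6)
        or tau <= TAU_MIN * (1 + 1e-6)
        or cmax >= 10.0 * max(c.max(), 1e-9) * (1 - 1e-6)
    )
    return PKFit(
        cmax_mM=cmax,
        tau_per_min=tau,
        half_life_min=math.log(2.0) / tau,
        rss=float(np.sum(result.residual**2)),
        cmax_stderr=(float(result.params["cmax"].stderr) if result.params["cmax"].stderr else None),
        tau_stderr=(float(result.params["tau"].stderr) if result.params["tau"].stderr else None),
        success=bool(result.success) and not at_bound,
        at_bound=at_bound,
        message=str(result.message),
    )


def half_life(tau_per_min: float) -> float:
    """Apparent blood half-life t1/2 = ln(2) / tau (minutes)."""
    if tau_per_min <= 0:
        raise ValueError("tau must be > 0")
    return math.log(2.0) / tau_per_min


def tau_from_half_life(half_life_min: float) -> float:
    """Exact inverse of :func:`half_life`."""
    if half_life_min <= 0:
        raise ValueError("half-life must be > 0")
    return math.log(2.0) / half_life_min


def convert_dose(dose_mg_per_kg: float, molar_mass_g_mol: float) -> float:
    """Mass dose (mg/kg) to molar dose (umol/kg): dose * 1000 / M.

    3 mg Fe/kg with M(Fe) = 55.845 g/mol gives 53.7 umol/kg.
    """
    if dose_mg_per_kg <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("dose and molar mass must be > 0")
    return dose_mg_per_kg * 1000.0 / molar_mass_g_mol


def antibodies_per_droplet(
    antibody_nmol_per_ml: float, droplets_per_ml: float
) -> float:
    """Mean antibody molecules per droplet from bulk concentrations."""
    if antibody_nmol_per_ml <= 0 or droplets_per_ml <= 0:
        raise ValueError("concentrations must be > 0")
    return antibody_nmol_per_ml * 1e-9 * AVOGADRO / droplets_per_ml


def loading_mg_per_g(weight_percent: float) -> float:
    """Drug loading of a w/w formulation in mg per gram of emulsion.

    A 5% w/w alpha-tocopherol composition carries 50 mg per g of NE.
    """
    if not 0 <= weight_percent <= 100:
        raise ValueError("weight percent must lie in [0, 100]")
    return weight_percent * 10.0
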