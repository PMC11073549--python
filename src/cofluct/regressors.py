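"""Design-matrix construction for task fMRI GLMs.

Builds every regressor family the pipeline needs — canonical double-gamma
HRF task regressors with temporal and dispersion derivatives, finite
impulse response (FIR) task bases, discrete-cosine drift terms, the
expanded 24-parameter motion set — and assembles them into the three
design-matrix flavours used downstream:

``denoise``
    FIR x conditions + motion24 + WM + CSF + global + cosine + intercept;
    used to residualise parcel series before edge (cofluctuation)
    time-series formation.
``node_activation``
    HRF triplets x conditions + the same nuisance set + intercept; used
    for region-level activation GLMs.
``edge_glm``
    intercept + HRF triplets x conditions only; used on edge time series,
    whose intercept then estimates the intrinsic correlation.

Conventions
-----------
* A frame belongs to a task block iff its acquisition time
  ``frame_index * tr`` lies in the half-open interval
  ``[onset, onset + duration)``.
* Convolution is performed at frame resolution by default; an
  ``oversample`` factor is available but block durations are much longer
  than the TR, so boundary effects are negligible.
* The cosine drift basis keeps harmonics ``k >= 1`` whose period
  ``2 * n_frames * tr / k`` strictly exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .data import Confounds

__all__ = [
    "TaskDesign",
    "DesignMatrix",
    "CONDITIONS",
    "double_gamma_hrf",
    "hrf_triplet",
    "fir_basis",
    "cosine_basis",
    "expand_motion",
    "build_design",
    "denoise_design",
    "activation_design",
    "edge_design",
]

#: canonical condition labels of the conflict tasks
CONDITIONS: Tuple[str, str] = ("congruent", "incongruent")

# Canonical double-gamma HRF constants (SPM-style gamma difference):
# response gamma peaking near 5-6 s, undershoot gamma near 15-16 s,
# undershoot scaled by 1/6.  Kernel length 32 s.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0
HRF_LENGTH = 32.0

# finite-difference steps for the derivative kernels
_TEMPORAL_STEP = 1.0  # seconds
_DISPERSION_STEP = 0.01


class DesignError(ValueError):
    """Raised for invalid task designs or design-matrix assembly errors."""


@dataclass
class TaskDesign:
    """Ordered, non-overlapping task blocks for one run.

    Parameters
    ----------
    blocks : list of (condition, onset_s, duration_s)
        Sorted by onset; conditions are free-form labels (canonically
        "congruent" / "incongruent").
    n_frames : int
    tr : float
        Repetition time in seconds.
    """

    blocks: List[Tuple[str, float, float]]
    n_frames: int
    tr: float

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise DesignError("n_frames must be >= 2")
        if self.tr <= 0:
            raise DesignError("tr must be positive")
        self.blocks = [(str(c), float(o), float(d)) for c, o, d in self.blocks]
        self.blocks.sort(key=lambda b: b[1])
        run_len = self.n_frames * self.tr
        prev_end = 0.0
        for cond, onset, dur in self.blocks:
            if onset < 0 or dur <= 0:
                raise DesignError(f"invalid block ({cond}, {onset}, {dur})")
            if onset < prev_end - 1e-9:
                raise DesignError("task blocks overlap")
            if onset + dur > run_len + 1e-9:
                raise DesignError("block extends past the end of the run")
            prev_end = onset + dur

    @property
    def conditions(self) -> List[str]:
        """Condition labels in canonical order, then order of appearance."""
        seen: List[str] = [c for c in CONDITIONS if any(b[0] == c for b in self.blocks)]
        for cond, _, _ in self.blocks:
            if cond not in seen:
                seen.append(cond)
        return seen

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    def boxcar(self, condition: str, oversample: int = 1) -> np.ndarray:
        """0/1 stimulus indicator for ``condition`` sampled on the frame grid.

        With ``oversample > 1`` the grid is refined to ``tr / oversample``.
        A grid point t belongs to a block iff ``onset <= t < onset + duration``.
        """
        n = self.n_frames * oversample
        t = np.arange(n) * (self.tr / oversample)
        box = np.zeros(n)
        for cond, onset, dur in self.blocks:
            if cond == condition:
                box[(t >= onset) & (t < onset + dur)] = 1.0
        return box


@dataclass
class DesignMatrix:
    """Frames x columns design with unique names and per-column role tags.

    Roles are one of {intercept, task_main, task_derivative, fir, motion,
    tissue, global, cosine}.
    """

    values: np.ndarray
    names: List[str]
    roles: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DesignError("design values must be 2-D")
        if len(self.names) != self.values.shape[1] or len(self.roles) != self.values.shape[1]:
            raise DesignError("names/roles length must match column count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise DesignError(f"duplicate design column names: {dupes}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def contrast_vector(self, weights: Dict[str, float]) -> np.ndarray:
        """Contrast weight vector from a {column_name: weight} mapping."""
        c = np.zeros(self.n_columns)
        for name, w in weights.items():
            if name not in self.names:
                raise DesignError(f"unknown design column {name!r}")
            c[self.names.index(name)] = w
        return c


# ---------------------------------------------------------------------------
# HRF kernels and task regressors
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = HRF_PEAK_DELAY,
    undershoot_delay: float = HRF_UNDERSHOOT_DELAY,
    peak_disp: float = HRF_PEAK_DISP,
    undershoot_disp: float = HRF_UNDERSHOOT_DISP,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Gamma-difference form: a response gamma with shape ``peak_delay /
    peak_disp`` and scale ``peak_disp`` minus ``ratio`` times an
    undershoot gamma with shape ``undershoot_delay / undershoot_disp``.
    """
    t = np.asarray(t, dtype=float)
    pos = _gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    neg = _gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    return pos - ratio * neg


def _hrf_kernels(dt: float) -> np.ndarray:
    """Main, temporal-derivative and dispersion-derivative kernels at step dt."""
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    main = double_gamma_hrf(t)
    tder = (main - double_gamma_hrf(t - _TEMPORAL_STEP)) / _TEMPORAL_STEP
    wide = double_gamma_hrf(t, peak_disp=HRF_PEAK_DISP + _DISPERSION_STEP)
    dder = (main - wide) / _DISPERSION_STEP
    return np.vstack([main, tder, dder])


def hrf_triplet(
    design: TaskDesign,
    condition: str,
    model: str = "double-gamma",
    oversample: int = 1,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Task regressors for one condition.

    ``model="double-gamma"`` returns three columns: the condition boxcar
    convolved with the canonical double-gamma HRF, with its temporal
    derivative, and with its dispersion derivative.  ``model="boxcar"``
    returns the raw boxcar as a single column (robustness variant).

    Returns (values, names, roles).  A condition with no blocks yields
    all-zero columns (provided the label is known to the design or one of
    the canonical conditions).
    """
    known = set(design.conditions) | set(CONDITIONS)
    if condition not in known:
        raise DesignError(f"unknown condition label {condition!r}")
    if model == "boxcar":
        col = design.boxcar(condition)[:, None]
        return col, [f"{condition}_box"], ["task_main"]
    if model != "double-gamma":
        raise DesignError(f"unknown HRF model {model!r}")
    if oversample < 1:
        raise DesignError("oversample must be >= 1")
    dt = design.tr / oversample
    box = design.boxcar(condition, oversample=oversample)
    kernels = _hrf_kernels(dt)
    cols = np.empty((design.n_frames, 3))
    for k in range(3):
        conv = np.convolve(box, kernels[k])[: box.size] / oversample
        cols[:, k] = conv[::oversample]
    names = [condition, f"{condition}_derivative", f"{condition}_dispersion"]
    roles = ["task_main", "task_derivative", "task_derivative"]
    return cols, names, roles


def fir_basis(
    design: TaskDesign,
    n_lags: int = 12,
    conditions: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Finite-impulse-response task basis: lagged stimulus indicators.

    For each condition, column ``k`` (k = 0..n_lags-1) is the condition's
    frame-resolution boxcar delayed by ``k`` frames and truncated at the
    run end.  With 12 lags at TR = 2 s this spans ~24 s of response.
    """
    if n_lags < 1:
        raise DesignError("n_lags must be >= 1")
    if n_lags * design.tr > design.n_frames * design.tr:
        raise DesignError("FIR span exceeds run length")
    conds = list(conditions) if conditions is not None else design.conditions
    values = np.zeros((design.n_frames, n_lags * len(conds)))
    names: List[str] = []
    for c_i, cond in enumerate(conds):
        box = design.boxcar(cond)
        for k in range(n_lags):
            col = np.zeros(design.n_frames)
            col[k:] = box[: design.n_frames - k]
            values[:, c_i * n_lags + k] = col
            names.append(f"{cond}_fir{k:02d}")
    roles = ["fir"] * values.shape[1]
    return values, names, roles


def cosine_basis(n_frames: int, tr: float, cutoff: float = 187.0) -> Tuple[np.ndarray, List[str], List[str]]:
    """Discrete-cosine drift columns for periods strictly above ``cutoff`` s.

    Harmonic ``k >= 1`` (DCT-II, unit-normalised) is kept iff
    ``2 * n_frames * tr / k > cutoff``.  May return zero columns.
    """
    if n_frames < 2 or tr <= 0 or cutoff <= 0:
        raise DesignError("invalid cosine-basis parameters")
    total = 2.0 * n_frames * tr
    ks = [k for k in range(1, n_frames) if total / k > cutoff]
    n = np.arange(n_frames)
    cols = np.empty((n_frames, len(ks)))
    for j, k in enumerate(ks):
        col = np.cos(np.pi * k * (2 * n + 1) / (2 * n_frames))
        cols[:, j] = col / np.linalg.norm(col)
    names = [f"cosine{k:02d}" for k in ks]
    return cols, names, ["cosine"] * len(ks)


def expand_motion(motion: np.ndarray) -> Tuple[np.ndarray, List[str], List[str]]:
    """Expand 6 rigid-body parameters to the 24-parameter motion set.

    Output column order: the 6 originals, their 6 backward-difference
    derivatives (0 at the first frame), then the squares of all 12.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DesignError("motion must have exactly 6 columns")
    if motion.shape[0] < 2:
        raise DesignError("motion needs at least 2 frames")
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    first12 = np.hstack([motion, deriv])
    values = np.hstack([first12, first12**2])
    base = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    names = base + [f"{b}_derivative1" for b in base]
    names = names + [f"{n}_power2" for n in names]
    return values, names, ["motion"] * 24


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

Block = Tuple[np.ndarray, List[str], List[str]]


def build_design(
    parts: Sequence[Block],
    include_intercept: bool = True,
    n_frames: Optional[int] = None,
) -> DesignMatrix:
    """Horizontally concatenate column blocks into a DesignMatrix.

    Each part is a (values, names, roles) triple sharing the frame count.
    The intercept, when requested, is appended last.  ``n_frames`` is only
    needed when ``parts`` is empty (intercept-only design).
    """
    mats: List[np.ndarray] = []
    names: List[str] = []
    roles: List[str] = []
    for values, part_names, part_roles in parts:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] == 1 and len(part_names) == 1 and values.shape[1] > 1:
            values = values.T
        if n_frames is None:
            n_frames = values.shape[0]
        elif values.shape[0] != n_frames:
            raise DesignError("design parts disagree on frame count")
        mats.append(values)
        names.extend(part_names)
        roles.extend(part_roles)
    if n_frames is None:
        if not include_intercept:
            raise DesignError("empty design")
        raise DesignError("pass n_frames to build an intercept-only design from no parts")
    if include_intercept:
        mats.append(np.ones((n_frames, 1)))
        names.append("intercept")
        roles.append("intercept")
    return DesignMatrix(np.hstack(mats), names, roles)


def intercept_only(n_frames: int) -> DesignMatrix:
    """Single all-ones column (resting-state edge GLM design)."""
    return DesignMatrix(np.ones((n_frames, 1)), ["intercept"], ["intercept"])


def _confound_blocks(confounds: Confounds, gsr: bool, n_frames: int, tr: float, cutoff: float) -> List[Block]:
    parts: List[Block] = [expand_motion(confounds.motion)]
    parts.append((confounds.white_matter[:, None], ["white_matter"], ["tissue"]))
    parts.append((confounds.csf[:, None], ["csf"], ["tissue"]))
    if gsr:
        parts.append((confounds.global_signal[:, None], ["global_signal"], ["global"]))
    parts.append(cosine_basis(n_frames, tr, cutoff))
    return parts


def denoise_design(
    design: Optional[TaskDesign],
    confounds: Confounds,
    remove_task: bool = True,
    gsr: bool = True,
    n_fir: int = 12,
    cosine_cutoff: float = 187.0,
    conditions: Sequence[str] = CONDITIONS,
) -> DesignMatrix:
    """Single-step denoising design: FIR task terms + nuisance set + intercept.

    With the defaults (two conditions, 12 FIR lags, 24 motion terms, WM,
    CSF, global signal and a 187-s cosine drift basis at 280 frames /
    TR 2 s) this yields 57 columns.  ``remove_task=False`` drops the FIR
    block (used when task effects are deliberately kept in the edge time
    series); ``gsr=False`` drops the global-signal column.
    """
    n_frames, tr = confounds.n_frames, (design.tr if design is not None else None)
    parts: List[Block] = []
    if remove_task:
        if design is None:
            raise DesignError("remove_task requires a task design")
        parts.append(fir_basis(design, n_lags=n_fir, conditions=conditions))
    if tr is None:
        raise DesignError("denoise_design needs a TaskDesign for the TR; use rest helpers otherwise")
    parts.extend(_confound_blocks(confounds, gsr, n_frames, tr, cosine_cutoff))
    return build_design(parts, include_intercept=True)


def rest_denoise_design(
    confounds: Confounds,
    tr: float,
    gsr: bool = True,
    cosine_cutoff: float = 187.0,
) -> DesignMatrix:
    """Denoising design for a resting-state run (no task terms)."""
    parts = _confound_blocks(confounds, gsr, confounds.n_frames, tr, cosine_cutoff)
    return build_design(parts, include_intercept=True)


def activation_design(
    design: TaskDesign,
    confounds: Confounds,
    hrf_model: str = "double-gamma",
    gsr: bool = True,
    cosine_cutoff: float = 187.0,
    conditions: Sequence[str] = CONDITIONS,
) -> DesignMatrix:
    """Node-activation design: HRF triplets per condition + nuisance set."""
    parts: List[Block] = [hrf_triplet(design, c, model=hrf_model) for c in conditions]
    parts.extend(_confound_blocks(confounds, gsr, design.n_frames, design.tr, cosine_cutoff))
    return build_design(parts, include_intercept=True)


def edge_design(
    design: TaskDesign,
    hrf_model: str = "double-gamma",
    conditions: Sequence[str] = CONDITIONS,
) -> DesignMatrix:
    """Edge-GLM design: intercept + HRF triplets per condition (7 columns)."""
    parts = [hrf_triplet(design, c, model=hrf_model) for c in conditions]
    return build_design(parts, include_intercept=True)
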