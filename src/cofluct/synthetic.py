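"""Synthetic multi-subject BOLD cohorts with known ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* block task designs with four congruent and four incongruent blocks of
  52-60 s, each preceded by a 10-17 s fixation, in a 280-frame run at
  TR = 2 s, plus a 150-frame (5 min) resting run;
* modular intrinsic covariance over a handful of systems;
* condition-dependent covariance modulation on a planted edge set,
  gated by the raw condition boxcar (HRF-gated option available);
* HRF-convolved evoked mean responses on a planted region set;
* AR(1) temporal colouring, random-walk motion and tissue/global
  confound leakage.

In dissociation mode (the default) the two tasks share an identical
evoked-amplitude vector but have different planted covariance-modulation
edge sets — the ground-truth twin of two tasks with the same activation
pattern and different network profiles.

Every generated cohort carries a :class:`SyntheticTruth` sufficient to
reproduce it bit-exactly and to score recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import Confounds, ParcelSeries, SubjectRun
from .edges import EdgeIndex
from .regressors import CONDITIONS, TaskDesign, hrf_triplet

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_task_design",
    "generate_cohort",
    "generate_rest_run",
    "plant_rest_frames",
]

_PSD_FLOOR = 1e-6


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the desk-scale study conditions."""

    n_subjects: int = 20
    n_regions: int = 40
    n_systems: int = 4
    tr: float = 2.0
    task_frames: int = 280
    rest_frames: int = 150
    n_blocks_per_condition: int = 4
    block_duration_range: Tuple[float, float] = (52.0, 60.0)
    fixation_range: Tuple[float, float] = (10.0, 17.0)
    first_condition: str = "incongruent"
    within_r: float = 0.3
    between_r: float = 0.05
    n_modulated_edges: int = 30
    delta_incongruent: float = 0.3
    delta_congruent: float = 0.1
    n_active_regions: int = 10
    amp_active: float = 3.0
    amp_incongruent: float = 1.0
    amp_congruent: float = 0.5
    amp_background_sd: float = 1.0
    ar1_rho: float = 0.4
    jitter_blocks: bool = True
    subject_sd: float = 0.2
    confound_leak: float = 0.1
    motion_step_sd: float = 0.02
    hrf_gate: bool = False
    dissociation: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_regions < 2 or self.n_systems < 1:
            raise ValueError("invalid cohort sizes")
        if self.n_systems > self.n_regions:
            raise ValueError("more systems than regions")
        if not (0 <= abs(self.ar1_rho) < 1):
            raise ValueError("|ar1_rho| must be < 1")
        lo, hi = self.block_duration_range
        flo, fhi = self.fixation_range
        if lo > hi or flo > fhi or lo <= 0 or flo < 0:
            raise ValueError("invalid duration ranges")
        min_total = 2 * self.n_blocks_per_condition * (lo + flo)
        if min_total > self.task_frames * self.tr:
            raise ValueError("schedule cannot fit inside the task run")

    @property
    def systems(self) -> List[str]:
        labels = []
        for r in range(self.n_regions):
            labels.append(f"sys{(r * self.n_systems) // self.n_regions + 1}")
        return labels


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated cohort."""

    config: CohortConfig
    sigma_intrinsic: np.ndarray
    amplitudes: Dict[str, np.ndarray]
    modulated_edges: Dict[str, Dict[str, List[Tuple[int, int]]]]
    deltas: Dict[str, Dict[str, float]]
    designs: Dict[str, List[TaskDesign]]
    rho: float
    seed: int


@dataclass
class Cohort:
    """Generated runs for every subject, plus the generating truth."""

    task_a: List[SubjectRun]
    task_b: List[SubjectRun]
    rest: List[SubjectRun]
    truth: SyntheticTruth

    @property
    def n_subjects(self) -> int:
        return len(self.task_a)

    def runs(self) -> Dict[str, List[SubjectRun]]:
        return {"task_a": self.task_a, "task_b": self.task_b, "rest": self.rest}


def generate_task_design(
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TaskDesign:
    """Alternating fixation/condition block schedule for one task run.

    Each of the 2 * n_blocks_per_condition blocks is preceded by a
    fixation of uniformly drawn duration; block conditions alternate
    starting with ``first_condition``.  Durations are redrawn (rejection
    sampling) until the schedule fits in the run.  With
    ``config.jitter_blocks`` off, every duration sits at the midpoint of
    its range, giving an exactly periodic schedule whose cycle length
    (one block of each condition plus two fixations) is known — useful
    when a spectral ground truth is needed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    other = [c for c in CONDITIONS if c != config.first_condition][0]
    order = [config.first_condition if k % 2 == 0 else other for k in range(2 * config.n_blocks_per_condition)]
    run_len = config.task_frames * config.tr
    for _ in range(1000):
        if config.jitter_blocks:
            fixations = rng.uniform(*config.fixation_range, size=len(order))
            durations = rng.uniform(*config.block_duration_range, size=len(order))
        else:
            # deterministic schedule that tiles the run exactly: mean-length
            # blocks, fixations stretched to fill the remainder (keeps the
            # schedule periodic and its fundamental on the frequency grid)
            durations = np.full(len(order), np.mean(config.block_duration_range))
            fix = (run_len - durations.sum()) / len(order)
            fix = min(max(fix, config.fixation_range[0]), config.fixation_range[1])
            fixations = np.full(len(order), fix)
        if fixations.sum() + durations.sum() <= run_len:
            blocks = []
            t = 0.0
            for cond, fix, dur in zip(order, fixations, durations):
                t += fix
                blocks.append((cond, t, dur))
                t += dur
            return TaskDesign(blocks, config.task_frames, config.tr)
    raise RuntimeError("could not fit a block schedule inside the run")


def _modular_correlation(config: CohortConfig) -> np.ndarray:
    labels = config.systems
    C = np.full((config.n_regions, config.n_regions), config.between_r)
    for i in range(config.n_regions):
        for j in range(config.n_regions):
            if labels[i] == labels[j]:
                C[i, j] = config.within_r
    np.fill_diagonal(C, 1.0)
    return C


def _clip_psd(S: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at a small floor to keep Sigma positive definite.

    Large planted covariance deltas can push a state covariance outside
    the PSD cone; clipping (with a warning) keeps the generator usable.
    """
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < _PSD_FLOOR:
        if vals.min() < 0:
            # static message so the default warning filter shows it once
            warnings.warn(
                "condition covariance not positive definite; eigenvalues clipped "
                f"at {_PSD_FLOOR:g}"
            )
        vals = np.clip(vals, _PSD_FLOOR, None)
        S = (vecs * vals) @ vecs.T
        S = 0.5 * (S + S.T)
    return S


def _delta_matrix(n_regions: int, edges: Sequence[Tuple[int, int]], delta: float) -> np.ndarray:
    D = np.zeros((n_regions, n_regions))
    for i, j in edges:
        D[i, j] = D[j, i] = delta
    return D


def _sample_edges(rng: np.random.Generator, index: EdgeIndex, k: int, exclude: set) -> List[Tuple[int, int]]:
    available = [e for e in range(index.n_edges) if e not in exclude]
    chosen = rng.choice(len(available), size=k, replace=False)
    return [index.pair(available[c]) for c in chosen]


def _confounds(rng: np.random.Generator, n_frames: int, config: CohortConfig, parcels: np.ndarray) -> Tuple[np.ndarray, Confounds]:
    """Motion random walk + AR(1) tissue series; returns leakage and Confounds."""
    motion = np.cumsum(rng.normal(0.0, config.motion_step_sd, size=(n_frames, 6)), axis=0)

    def ar1(rho: float) -> np.ndarray:
        w = rng.normal(size=n_frames)
        x = np.empty(n_frames)
        x[0] = w[0]
        for t in range(1, n_frames):
            x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * w[t]
        return x

    wm, csf = ar1(0.5), ar1(0.5)
    load_m = rng.normal(size=(config.n_regions, 6))
    load_w = rng.normal(size=config.n_regions)
    load_c = rng.normal(size=config.n_regions)
    leak = config.confound_leak * (motion @ load_m.T + np.outer(wm, load_w) + np.outer(csf, load_c))
    leaked = parcels + leak
    global_signal = leaked.mean(axis=1) + rng.normal(0.0, 0.05, size=n_frames)
    return leaked, Confounds(motion=motion, white_matter=wm, csf=csf, global_signal=global_signal)


def _simulate_run(
    rng: np.random.Generator,
    config: CohortConfig,
    design: Optional[TaskDesign],
    sigma0: np.ndarray,
    deltas: Dict[str, np.ndarray],
    amplitudes: Dict[str, np.ndarray],
    subject_gain: float,
    subject_id: str,
    run_id: str,
) -> SubjectRun:
    n_frames = design.n_frames if design is not None else config.rest_frames
    rho = config.ar1_rho

    if design is None:
        chol = {None: np.linalg.cholesky(_clip_psd(sigma0))}
        states = [None] * n_frames
        mean = np.zeros((n_frames, config.n_regions))
    else:
        boxcars = {c: design.boxcar(c) for c in CONDITIONS}
        if config.hrf_gate:
            gates = {
                c: hrf_triplet(design, c)[0][:, 0] for c in CONDITIONS
            }
            gates = {c: np.clip(g / max(g.max(), 1e-12), 0.0, 1.0) for c, g in gates.items()}
        else:
            gates = boxcars
        states = []
        chol = {}
        for t in range(n_frames):
            key = tuple(round(float(gates[c][t]), 6) for c in CONDITIONS)
            states.append(key)
            if key not in chol:
                S = sigma0.copy()
                for c_i, c in enumerate(CONDITIONS):
                    S = S + key[c_i] * subject_gain * deltas[c]
                chol[key] = np.linalg.cholesky(_clip_psd(S))
        mean = np.zeros((n_frames, config.n_regions))
        for c in CONDITIONS:
            conv = hrf_triplet(design, c)[0][:, 0]
            mean += np.outer(conv, subject_gain * amplitudes[c])

    noise = np.empty((n_frames, config.n_regions))
    w = rng.standard_normal((n_frames, config.n_regions))
    noise[0] = chol[states[0]] @ w[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_frames):
        noise[t] = rho * noise[t - 1] + scale * (chol[states[t]] @ w[t])

    parcels = mean + noise
    leaked, confounds = _confounds(rng, n_frames, config, parcels)
    series = ParcelSeries(leaked, tr=config.tr, systems=config.systems)
    return SubjectRun(parcels=series, confounds=confounds, design=design, subject_id=subject_id, run_id=run_id)


def generate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate task A, task B and rest runs for every subject.

    With ``config.dissociation`` (default) the two tasks share the evoked
    amplitude vectors but their condition-dependent covariance changes
    live on disjoint planted edge sets; otherwise task B reuses task A's
    edge sets.
    """
    config = config or CohortConfig()
    config.validate()
    if config.n_active_regions > config.n_regions:
        raise ValueError("more active regions than regions")
    n_edges_total = config.n_regions * (config.n_regions - 1) // 2
    if 4 * config.n_modulated_edges > n_edges_total:
        raise ValueError(
            "cannot plant 4 disjoint sets of "
            f"{config.n_modulated_edges} edges among {n_edges_total} edges"
        )
    root = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    index = EdgeIndex(config.n_regions)

    sigma0 = _modular_correlation(config)
    # every region carries a weak evoked response (positive or negative),
    # with a strongly active subset on top — both tasks evoke widespread,
    # heterogeneous responses, not activity confined to a few regions
    active = cohort_rng.choice(config.n_regions, size=config.n_active_regions, replace=False)
    base = cohort_rng.normal(0.0, config.amp_background_sd, size=config.n_regions)
    base[active] += cohort_rng.uniform(0.5, 1.5, size=config.n_active_regions) * config.amp_active
    amplitudes = {
        "congruent": base * config.amp_congruent,
        "incongruent": base * config.amp_incongruent,
    }

    edges_a_inc = _sample_edges(cohort_rng, index, config.n_modulated_edges, set())
    used = {index.position(i, j) for i, j in edges_a_inc}
    edges_a_con = _sample_edges(cohort_rng, index, config.n_modulated_edges, used)
    used |= {index.position(i, j) for i, j in edges_a_con}
    if config.dissociation:
        edges_b_inc = _sample_edges(cohort_rng, index, config.n_modulated_edges, used)
        used |= {index.position(i, j) for i, j in edges_b_inc}
        edges_b_con = _sample_edges(cohort_rng, index, config.n_modulated_edges, used)
    else:
        edges_b_inc, edges_b_con = edges_a_inc, edges_a_con

    edge_sets = {
        "task_a": {"incongruent": edges_a_inc, "congruent": edges_a_con},
        "task_b": {"incongruent": edges_b_inc, "congruent": edges_b_con},
    }
    delta_mats = {
        task: {
            "incongruent": _delta_matrix(config.n_regions, sets["incongruent"], config.delta_incongruent),
            "congruent": _delta_matrix(config.n_regions, sets["congruent"], config.delta_congruent),
        }
        for task, sets in edge_sets.items()
    }

    subject_seeds = root.spawn(config.n_subjects + 1)[1:]
    task_a: List[SubjectRun] = []
    task_b: List[SubjectRun] = []
    rest: List[SubjectRun] = []
    designs: Dict[str, List[TaskDesign]] = {"task_a": [], "task_b": []}
    for s, seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seq)
        gain = max(0.1, 1.0 + config.subject_sd * rng.standard_normal())
        sid = f"sub-{s + 1:02d}"
        for task in ("task_a", "task_b"):
            design = generate_task_design(config, rng=rng)
            designs[task].append(design)
            run = _simulate_run(
                rng, config, design, sigma0, delta_mats[task], amplitudes, gain, sid, task
            )
            (task_a if task == "task_a" else task_b).append(run)
        rest.append(
            _simulate_run(rng, config, None, sigma0, {}, {}, gain, sid, "rest")
        )

    truth = SyntheticTruth(
        config=config,
        sigma_intrinsic=sigma0,
        amplitudes=amplitudes,
        modulated_edges=edge_sets,
        deltas={
            task: {"incongruent": config.delta_incongruent, "congruent": config.delta_congruent}
            for task in edge_sets
        },
        designs=designs,
        rho=config.ar1_rho,
        seed=config.seed,
    )
    return Cohort(task_a=task_a, task_b=task_b, rest=rest, truth=truth)


def generate_rest_run(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
    n_frames: Optional[int] = None,
) -> SubjectRun:
    """One resting run: intrinsic covariance only, no evoked mean."""
    config = config or CohortConfig()
    if n_frames is not None:
        from dataclasses import replace

        config = replace(config, rest_frames=n_frames)
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma0 = _modular_correlation(config)
    return _simulate_run(rng, config, None, sigma0, {}, {}, 1.0, "sub-01", "rest")


# resting-state frames are "planted" with intrinsic structure only
plant_rest_frames = generate_rest_run


def block_alternation_frequency(design: TaskDesign) -> float:
    """Block-fixation alternation rate of a schedule, in Hz.

    One alternation cycle is a fixation followed by a block; the
    fundamental is the reciprocal of the mean spacing between
    consecutive block onsets (exact for a deterministic schedule).
    """
    onsets = np.array([b[1] for b in design.blocks])
    if onsets.size < 2:
        raise ValueError("need at least two blocks")
    return 1.0 / float(np.mean(np.diff(onsets)))
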