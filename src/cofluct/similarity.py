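"""Between-task and between-subject similarity of statistical maps.

Implements the full similarity battery: Spearman correlation and Dice
coefficient between group maps, similarity as a function of group size,
edge-subsampling distributions, region-wise profile similarity,
subject-level beta-map similarity with a paired t test and Cohen's d,
a Mantel test with subsampled confidence intervals, and group-level
SNR (Cohen's d) filtering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .edges import EdgeIndex, vector_to_matrix
from .group import bh_fdr, holm, one_sample_map

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityReport",
    "spearman_map",
    "dice",
    "similarity_vs_n",
    "edge_subsample_similarity",
    "regionwise_similarity",
    "subject_similarities",
    "paired_similarity_test",
    "subject_level_similarity",
    "cohens_d",
    "distance_matrix",
    "mantel",
    "snr_filter",
    "activation_filter",
]


@dataclass
class SimilarityReport:
    """Spearman rho and Dice coefficients (per alpha) between two maps."""

    rho: float
    dice_by_alpha: Dict[float, float] = field(default_factory=dict)
    n_elements: int = 0
    seed: Optional[int] = None
    n_reps: Optional[int] = None


def spearman_map(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 elements")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def dice(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    signs_a: Optional[np.ndarray] = None,
    signs_b: Optional[np.ndarray] = None,
) -> float:
    """Dice similarity coefficient 2|A & B| / (|A| + |B|).

    Masks encode significance only; the non-default signed variant
    (pass ``signs_a``/``signs_b``) additionally requires sign agreement
    for an element to count as shared.  Defined as 1.0 when both masks
    are empty (identical trivially).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal length")
    shared = a & b
    if signs_a is not None or signs_b is not None:
        if signs_a is None or signs_b is None:
            raise ValueError("signed Dice needs signs for both maps")
        shared = shared & (np.sign(signs_a) == np.sign(signs_b))
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(shared) / denom)


def similarity_vs_n(
    subject_maps_a: np.ndarray,
    subject_maps_b: np.ndarray,
    n_grid: Sequence[int],
    n_repeats: int = 10,
    alphas: Sequence[float] = (0.05,),
    correction: str = "holm",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Between-map similarity as a function of the number of subjects.

    For each n in ``n_grid``, draws n subjects without replacement
    (``n_repeats`` times), recomputes both group t maps on that subset,
    and records the Spearman rho between them, plus a Dice coefficient
    for each alpha after the chosen multiple-comparison correction.
    Returns one row per (n, statistic) with mean and sd over repeats.
    """
    a = np.asarray(subject_maps_a, dtype=float)
    b = np.asarray(subject_maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("both tasks need the same subjects x elements shape")
    n_subjects = a.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n < 3:
            raise ValueError("group maps need at least 3 subjects")
        if n > n_subjects:
            raise ValueError("n exceeds the available subjects")
        rhos, dices = [], {alpha: [] for alpha in alphas}
        for _ in range(n_repeats):
            idx = rng.choice(n_subjects, size=n, replace=False) if n < n_subjects else np.arange(n_subjects)
            ga = one_sample_map(a[idx])
            gb = one_sample_map(b[idx])
            rhos.append(spearman_map(ga.t, gb.t))
            for alpha in alphas:
                ma = ga.significant(correction, alpha).mask
                mb = gb.significant(correction, alpha).mask
                dices[alpha].append(dice(ma, mb))
        row = {"n": n, "rho_mean": float(np.mean(rhos)), "rho_sd": float(np.std(rhos, ddof=0))}
        for alpha in alphas:
            row[f"dice_mean_alpha{alpha}"] = float(np.mean(dices[alpha]))
            row[f"dice_sd_alpha{alpha}"] = float(np.std(dices[alpha], ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def edge_subsample_similarity(
    map_a: np.ndarray,
    map_b: np.ndarray,
    k: int,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Distribution of Spearman rho over random k-subsets of elements."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    if not (3 <= k <= a.size):
        raise ValueError("k must be between 3 and the number of elements")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(a.size, size=k, replace=False)
        out[r] = spearman_map(a[idx], b[idx])
    return out


def regionwise_similarity(
    edge_map_a: np.ndarray,
    edge_map_b: np.ndarray,
    edge_index: EdgeIndex,
) -> np.ndarray:
    """Per-region Spearman similarity of whole-brain edge profiles.

    Each region's profile is its row of the symmetric edge-statistic
    matrix with the diagonal removed (length n_regions - 1).
    """
    A = vector_to_matrix(np.asarray(edge_map_a, dtype=float), edge_index)
    B = vector_to_matrix(np.asarray(edge_map_b, dtype=float), edge_index)
    n = edge_index.n_regions
    out = np.empty(n)
    for r in range(n):
        keep = np.arange(n) != r
        out[r] = spearman_map(A[r, keep], B[r, keep])
    return out


def subject_similarities(maps_task_a: np.ndarray, maps_task_b: np.ndarray) -> np.ndarray:
    """Per-subject Spearman rho between the two tasks' contrast maps."""
    a = np.asarray(maps_task_a, dtype=float)
    b = np.asarray(maps_task_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("both tasks need the same subjects x elements shape")
    return np.array([spearman_map(a[s], b[s]) for s in range(a.shape[0])])


def cohens_d(differences: np.ndarray) -> float:
    """Paired Cohen's d: mean of differences over their sample sd (ddof=1).

    Returns signed infinity (or nan for an all-zero vector) when the
    differences have zero variance, with a warning.
    """
    d = np.asarray(differences, dtype=float)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        warnings.warn("zero variance of differences; Cohen's d is a sentinel")
        return float(np.sign(mean) * np.inf) if mean != 0 else float("nan")
    return float(mean / sd)


def paired_similarity_test(
    rho_a: np.ndarray, rho_b: np.ndarray, fisher_z: bool = False
) -> Dict[str, float]:
    """Paired t test and Cohen's d between two per-subject similarity sets.

    By default the test runs on raw rho values (mean rho is the quantity
    of interest); ``fisher_z`` applies arctanh first.
    """
    rho_a = np.asarray(rho_a, dtype=float)
    rho_b = np.asarray(rho_b, dtype=float)
    if rho_a.shape != rho_b.shape:
        raise ValueError("paired comparison needs equal-length vectors")
    if fisher_z:
        rho_a, rho_b = np.arctanh(rho_a), np.arctanh(rho_b)
    diff = rho_a - rho_b
    if diff.std(ddof=1) == 0:
        warnings.warn("identical similarity distributions; paired t is a sentinel")
        t_stat, p_val = (float("nan"), float("nan"))
    else:
        t_stat, p_val = stats.ttest_rel(rho_a, rho_b)
    return {
        "mean_a": float(rho_a.mean()),
        "mean_b": float(rho_b.mean()),
        "t": float(t_stat),
        "p": float(p_val),
        "cohens_d": cohens_d(diff),
        "n": int(rho_a.size),
    }


def subject_level_similarity(
    beta_maps: Dict[str, Tuple[np.ndarray, np.ndarray]],
) -> Dict[str, object]:
    """Subject-level between-task similarity for each map kind.

    ``beta_maps`` maps a kind name (e.g. "activation", "network") to a
    (subjects x elements task A, subjects x elements task B) pair of
    subject beta maps.  Returns per-kind per-subject rho vectors and,
    when exactly two kinds are supplied, the paired comparison between
    them (first kind minus second).
    """
    rhos = {kind: subject_similarities(a, b) for kind, (a, b) in beta_maps.items()}
    out: Dict[str, object] = {"rho": rhos}
    kinds = list(beta_maps)
    if len(kinds) == 2:
        out["paired"] = paired_similarity_test(rhos[kinds[0]], rhos[kinds[1]])
    return out


def distance_matrix(subject_maps: np.ndarray) -> np.ndarray:
    """Subject-by-subject distance d_ij = 1 - spearman_rho_ij."""
    m = np.asarray(subject_maps, dtype=float)
    n = m.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - spearman_map(m[i], m[j])
            D[i, j] = D[j, i] = d
    return D


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 9999,
    n_resample: int = 1000,
    resample_ratio: float = 0.135,
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Mantel test between two subject distance matrices.

    r is the Pearson correlation of the upper-triangular entries; the
    permutation p applies the same random subject relabelling to the rows
    and columns of one matrix (two-sided, add-one rule).  The confidence
    interval is the 2.5/97.5 percentile range of r recomputed on
    ``n_resample`` subject subsets of size ceil(resample_ratio * n),
    drawn without replacement.
    """
    A = np.asarray(dist_a, dtype=float)
    B = np.asarray(dist_b, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or B.shape != (n, n):
        raise ValueError("distance matrices must be square and same size")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if not np.allclose(A, A.T) or not np.allclose(B, B.T):
        raise ValueError("distance matrices must be symmetric")

    rng = np.random.default_rng(seed)
    va, vb = _upper(A), _upper(B)
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(_upper(A[np.ix_(perm, perm)]), vb)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)

    k = max(4, math.ceil(resample_ratio * n))
    rs = np.empty(n_resample)
    for i in range(n_resample):
        idx = rng.choice(n, size=k, replace=False)
        rs[i] = np.corrcoef(_upper(A[np.ix_(idx, idx)]), _upper(B[np.ix_(idx, idx)]))[0, 1]
    ci = (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5)))
    return {"r": r_obs, "p": float(p), "ci": ci, "n_perm": n_perm, "n_resample": n_resample, "subsample_size": k}


def snr_filter(
    subject_betas: Dict[str, np.ndarray],
    threshold: float = 0.5,
) -> Dict[str, object]:
    """Group-level SNR (Cohen's d) per element, with joint-task filtering.

    The SNR of an element is the across-subject mean of the contrast
    divided by its across-subject sd — a group-level Cohen's d.  Elements
    whose sd is zero are excluded (logged).  ``retained`` holds the
    indices whose SNR exceeds ``threshold`` in every supplied task.
    """
    snrs: Dict[str, np.ndarray] = {}
    medians: Dict[str, float] = {}
    retained_masks = []
    for task, betas in subject_betas.items():
        b = np.asarray(betas, dtype=float)
        if b.ndim != 2 or b.shape[0] < 3:
            raise ValueError("need subjects x elements with >= 3 subjects")
        sd = b.std(axis=0, ddof=1)
        excluded = sd == 0
        if np.any(excluded):
            logger.info("snr_filter: %d zero-sd elements excluded in %s", int(excluded.sum()), task)
        snr = np.full(b.shape[1], np.nan)
        snr[~excluded] = b.mean(axis=0)[~excluded] / sd[~excluded]
        snrs[task] = snr
        medians[task] = float(np.nanmedian(snr))
        retained_masks.append(np.where(np.isnan(snr), False, snr > threshold))
    joint = np.logical_and.reduce(retained_masks)
    return {
        "snr": snrs,
        "median": medians,
        "retained": np.where(joint)[0],
        "threshold": threshold,
    }


def activation_filter(
    subject_betas: Dict[str, np.ndarray],
    d_threshold: float = 0.8,
) -> np.ndarray:
    """Regions with |group-level Cohen's d| above threshold in every task."""
    masks = []
    for betas in subject_betas.values():
        b = np.asarray(betas, dtype=float)
        sd = b.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(sd > 0, b.mean(axis=0) / np.where(sd > 0, sd, 1.0), np.nan)
        masks.append(np.where(np.isnan(d), False, np.abs(d) > d_threshold))
    return np.where(np.logical_and.reduce(masks))[0]
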