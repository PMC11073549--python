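"""End-to-end validation: analytic identities and ground-truth recovery.

The pipeline cannot be validated against its motivating dataset (the
cohort is not publicly deposited), so correctness is established through
a battery of exact identities, brute-force oracles and parameter
recovery on synthetic cohorts with known ground truth:

* exact combinatorial and algebraic identities (edge counts, drift-term
  counts, the Pearson decomposition of edge time series, the t-to-r
  transform, normal-equations solutions);
* error control of the multiple-testing procedures under simulation;
* recovery of planted condition-dependent covariance edges;
* the dissociation phenomenon: cohorts built with identical evoked
  activations but different covariance modulation must show higher
  between-task activation similarity than network similarity;
* the spectral signature of task-locked cofluctuations;
* concordance between the edge-GLM and gPPI estimates of task-modulated
  coupling.

Every function recomputes its quantity from scratch and is deterministic
given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .edges import EdgeIndex, edge_series, periodogram, rss, standardize_columns
from .glm import ols_fit
from .group import bh_fdr, holm, one_sample_map, t_to_r
from .pipelines import GPPI, ActivationGLM, Denoiser, EdgeGLM
from .similarity import paired_similarity_test, spearman_map, subject_similarities
from .synthetic import (
    Cohort,
    CohortConfig,
    block_alternation_frequency,
    generate_cohort,
)

__all__ = [
    "pearson_identity_error",
    "glm_oracle_error",
    "t_to_r_identity_error",
    "multiplicity_error_rates",
    "cohort_contrast_maps",
    "planted_edge_auc",
    "dissociation_replicates",
    "rss_spectral_peak",
    "gppi_concordance",
]


def pearson_identity_error(n_pairs: int = 100, n_frames: int = 80, seed: int = 0) -> float:
    """Max |sum(edge series)/(T-1) - Pearson r| over random series pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        Z = standardize_columns(rng.normal(size=(n_frames, 2)))
        E = edge_series(Z)
        r = np.corrcoef(Z[:, 0], Z[:, 1])[0, 1]
        worst = max(worst, abs(E.values[:, 0].sum() / (n_frames - 1) - r))
    return worst


def glm_oracle_error(n_problems: int = 50, seed: int = 0) -> float:
    """Max |pipeline betas - explicit (X'X)^-1 X'y| over random problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        n = int(rng.integers(12, 40))
        p = int(rng.integers(2, 6))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=(n, 3))
        fit = ols_fit(y, X)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        worst = max(worst, float(np.max(np.abs(fit.betas - oracle))))
    return worst


def t_to_r_identity_error() -> float:
    """Max |r^2 + (N-1)/(t^2+N-1) - 1| over a (t, N) grid."""
    t = np.linspace(-30, 30, 121)
    worst = 0.0
    for n in (2, 5, 10, 50, 242):
        r = t_to_r(t, n)
        worst = max(worst, float(np.max(np.abs(r**2 + (n - 1) / (t**2 + n - 1) - 1.0))))
    return worst


def multiplicity_error_rates(
    n_sims: int = 1000, n_elements: int = 200, alpha: float = 0.05, seed: int = 0
) -> Dict[str, float]:
    """Empirical FWER of Holm and FDR of BH over null simulations.

    Holm runs on global-null p-values; BH on a half-null/half-signal mix
    (its FDR under the global null coincides with FWER, so a mixture is
    the informative regime).
    """
    rng = np.random.default_rng(seed)
    fw_errors = 0
    fdrs = []
    for _ in range(n_sims):
        p_null = rng.uniform(size=n_elements)
        fw_errors += bool(holm(p_null, alpha).any())
        p_mix = np.concatenate(
            [rng.uniform(size=n_elements // 2), rng.uniform(size=n_elements // 2) * 1e-4]
        )
        rej = bh_fdr(p_mix, alpha)
        n_rej = int(rej.sum())
        fdrs.append(rej[: n_elements // 2].sum() / n_rej if n_rej else 0.0)
    return {"holm_fwer": fw_errors / n_sims, "bh_fdr": float(np.mean(fdrs))}


def cohort_contrast_maps(cohort: Cohort) -> Dict[str, np.ndarray]:
    """Subject-level incongruent-vs-congruent beta maps for both levels."""
    out = {}
    for task, runs in (("a", cohort.task_a), ("b", cohort.task_b)):
        out[f"act_{task}"] = np.vstack([ActivationGLM().fit(r).beta_ for r in runs])
        out[f"net_{task}"] = np.vstack([EdgeGLM().fit(r).contrast_.effect for r in runs])
    return out


def planted_edge_auc(cohort: Cohort, maps: Optional[Dict[str, np.ndarray]] = None) -> float:
    """AUC for ranking planted covariance-modulated edges above null edges.

    Ranks by the group-level t of the edge contrast for task A;
    congruent-set edges are excluded from the null pool.
    """
    from sklearn.metrics import roc_auc_score

    if maps is None:
        maps = cohort_contrast_maps(cohort)
    idx = EdgeIndex(cohort.truth.config.n_regions)
    sets = cohort.truth.modulated_edges["task_a"]
    planted = sorted({idx.position(i, j) for i, j in sets["incongruent"]})
    excluded = {idx.position(i, j) for i, j in sets["congruent"]}
    null = [e for e in range(idx.n_edges) if e not in set(planted) and e not in excluded]
    t = one_sample_map(maps["net_a"]).t
    labels = [1] * len(planted) + [0] * len(null)
    scores = np.concatenate([t[planted], t[null]])
    return float(roc_auc_score(labels, scores))


def dissociation_replicates(
    n_replicates: int = 50,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> Dict[str, object]:
    """Replicate the activation-vs-network similarity dissociation.

    Each replicate generates a fresh dissociation cohort (identical
    planted activations across tasks, different covariance-modulated
    edge sets), fits the full subject pipelines, and compares the
    between-task Spearman similarity of group activation t maps with
    that of group network t maps.  Also runs the subject-level beta-map
    comparison (per-subject between-task rho for both kinds, paired t).
    """
    base = config or CohortConfig()
    rng = np.random.default_rng(seed)
    act_rhos, net_rhos, paired = [], [], []
    first_maps = None
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = generate_cohort(dataclasses.replace(base, seed=rep_seed))
        maps = cohort_contrast_maps(cohort)
        if first_maps is None:
            first_maps = (cohort, maps)
        act_rhos.append(
            spearman_map(one_sample_map(maps["act_a"]).t, one_sample_map(maps["act_b"]).t)
        )
        net_rhos.append(
            spearman_map(one_sample_map(maps["net_a"]).t, one_sample_map(maps["net_b"]).t)
        )
        paired.append(
            paired_similarity_test(
                subject_similarities(maps["act_a"], maps["act_b"]),
                subject_similarities(maps["net_a"], maps["net_b"]),
            )
        )
    act = np.array(act_rhos)
    net = np.array(net_rhos)
    return {
        "activation_rho_mean": float(act.mean()),
        "network_rho_mean": float(net.mean()),
        "fraction_activation_exceeds_network": float(np.mean(act > net)),
        "paired_t_p_first": float(paired[0]["p"]),
        "paired_cohens_d_first": float(paired[0]["cohens_d"]),
        "subject_activation_rho_mean": float(np.mean([p["mean_a"] for p in paired])),
        "subject_network_rho_mean": float(np.mean([p["mean_b"] for p in paired])),
        "fraction_paired_significant": float(np.mean([p["p"] < 0.05 for p in paired])),
        "first_cohort_maps": first_maps,
        "n_replicates": n_replicates,
    }


def rss_spectral_peak(config: Optional[CohortConfig] = None, seed: int = 0) -> Dict[str, float]:
    """Locate the spectral peak of the cohort's mean RSS series.

    Uses a deterministic (jitter-free) block schedule so the
    block-alternation fundamental is exactly known, keeps task effects in
    the denoised series, averages the demeaned RSS time series across
    subjects (cofluctuation events are schedule-locked, hence
    synchronized across subjects), and returns the peak frequency
    alongside the schedule's alternation fundamental.
    """
    if config is None:
        config = CohortConfig(seed=seed, jitter_blocks=False)
    cohort = generate_cohort(config)
    series = []
    for run in cohort.task_a:
        cleaned = Denoiser(remove_task=False).transform(run)
        Z = standardize_columns(cleaned.data)
        r = rss(edge_series(Z, tr=run.parcels.tr))
        series.append(r - r.mean())
    freqs, power = periodogram(np.mean(series, axis=0), cohort.task_a[0].parcels.tr)
    peak = float(freqs[1:][np.argmax(power[1:])])
    fundamental = block_alternation_frequency(cohort.truth.designs["task_a"][0])
    return {
        "peak_frequency_hz": peak,
        "fundamental_hz": float(fundamental),
        "frequency_resolution_hz": float(freqs[1] - freqs[0]),
        "peak_to_fundamental_ratio": peak / float(fundamental),
    }


def gppi_concordance(cohort: Cohort, maps: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, float]:
    """Spearman concordance of group gPPI and edge-GLM contrast maps."""
    gppi = np.vstack([GPPI().fit(r).contrast_ for r in cohort.task_a])
    if maps is None:
        maps = cohort_contrast_maps(cohort)
    rho, p = stats.spearmanr(gppi.mean(axis=0), maps["net_a"].mean(axis=0))
    return {"rho": float(rho), "p": float(p)}
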