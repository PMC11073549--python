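"""Group-level inference across subjects.

One-sample and paired t maps over node or edge elements, family-wise
(Holm-Bonferroni) and false-discovery-rate (Benjamini-Hochberg)
correction, the t-to-r conversion r^2 = t^2 / (t^2 + N - 1), system-level
summaries of significant edges, and the Fisher's-exact comparison of
edge signs among the largest-|t| edges of two maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .edges import EdgeIndex

logger = logging.getLogger(__name__)

__all__ = [
    "GroupMap",
    "one_sample_map",
    "paired_map",
    "holm",
    "bh_fdr",
    "t_to_r",
    "top_fraction_sign_test",
    "system_summaries",
]


@dataclass
class GroupMap:
    """Per-element group statistics with an optional significance mask."""

    mean_effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_subjects: int
    mask: Optional[np.ndarray] = None
    correction: str = "none"
    alpha: float = 0.05

    @property
    def dof(self) -> int:
        return self.n_subjects - 1

    @property
    def n_elements(self) -> int:
        return self.mean_effect.shape[0]

    def r(self) -> np.ndarray:
        """Effect size as a correlation via the t-to-r transform."""
        return t_to_r(self.t, self.n_subjects)

    def significant(self, correction: str = "holm", alpha: float = 0.05) -> "GroupMap":
        """Copy with the significance mask from the chosen correction."""
        if correction == "holm":
            mask = holm(self.p, alpha)
        elif correction == "bh":
            mask = bh_fdr(self.p, alpha)
        elif correction == "none":
            mask = self.p <= alpha
        else:
            raise ValueError(f"unknown correction {correction!r}")
        return GroupMap(self.mean_effect, self.t, self.p, self.n_subjects, mask, correction, alpha)

    def to_frame(self, element_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "effect": self.mean_effect,
                "t": self.t,
                "p": self.p,
                "r": self.r(),
            }
        )
        if self.mask is not None:
            df["significant"] = self.mask
        if element_ids is not None:
            df.insert(0, "element", list(element_ids))
        return df


def one_sample_map(subject_maps: np.ndarray) -> GroupMap:
    """Classical one-sample t test of subject effects against zero.

    ``subject_maps`` is subjects x elements.  Elements with zero
    across-subject variance get the sentinel t = +/-inf (p = 0) when the
    mean is nonzero, or t = 0 (p = 1) when it is zero.
    """
    m = np.asarray(subject_maps, dtype=float)
    if m.ndim != 2:
        raise ValueError("subject_maps must be subjects x elements")
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(m)):
        raise ValueError("subject maps contain missing values")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 1)
    bad = ~ok & (mean != 0)
    if np.any(~ok):
        warnings.warn("zero across-subject variance for some elements; sentinel t used")
    t[bad] = np.sign(mean[bad]) * np.inf
    p[bad] = 0.0
    return GroupMap(mean, t, p, n)


def paired_map(maps_a: np.ndarray, maps_b: np.ndarray) -> GroupMap:
    """Paired t map: one-sample test on per-subject differences a - b."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired maps require identical subjects x elements shapes")
    return one_sample_map(a - b)


def holm(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection mask at family-wise level alpha."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level alpha."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def t_to_r(t: np.ndarray, n_subjects: int) -> np.ndarray:
    """Convert group t statistics to signed correlations.

    r^2 = t^2 / (t^2 + N - 1); the sign of t is preserved.  Infinite t
    maps to +/-1.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.sign(t) * np.sqrt(t**2 / (t**2 + n_subjects - 1))
    r = np.where(np.isinf(t), np.sign(t), r)
    return np.where(np.isnan(t), np.nan, r)


def top_fraction_sign_test(
    t_a: np.ndarray,
    t_b: np.ndarray,
    fraction: float = 0.01,
) -> Tuple[np.ndarray, float, float]:
    """Compare positive/negative sign counts among each map's largest-|t| edges.

    Selects the floor(fraction * E) edges with the largest |t| per map
    (ties broken by lower edge index), cross-tabulates positive vs
    negative signs between the two maps, and returns the 2x2 table
    ``[[a_pos, a_neg], [b_pos, b_neg]]``, the sample odds ratio
    (a_pos * b_neg) / (a_neg * b_pos) and Fisher's exact two-sided p.
    Zero-sign edges are excluded from the counts (logged); a zero cell
    triggers the Haldane 0.5 continuity correction for the odds ratio
    (logged), while p remains exact.
    """
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if t_a.shape != t_b.shape:
        raise ValueError("maps must have equal length")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    m = int(np.floor(fraction * t_a.size))
    if m < 1:
        raise ValueError("fraction selects no edges")

    def _signs(t: np.ndarray) -> Tuple[int, int]:
        order = np.lexsort((np.arange(t.size), -np.abs(t)))
        top = t[order[:m]]
        n_zero = int(np.sum(top == 0))
        if n_zero:
            logger.info("top-fraction selection: %d zero-t edges excluded", n_zero)
        return int(np.sum(top > 0)), int(np.sum(top < 0))

    a_pos, a_neg = _signs(t_a)
    b_pos, b_neg = _signs(t_b)
    table = np.array([[a_pos, a_neg], [b_pos, b_neg]])
    if np.any(table == 0):
        logger.info("zero cell in sign table; odds ratio uses 0.5 continuity correction")
        ct = table + 0.5
        odds = (ct[0, 0] * ct[1, 1]) / (ct[0, 1] * ct[1, 0])
    else:
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def system_summaries(
    mask: np.ndarray,
    edge_index: EdgeIndex,
    system_labels: Sequence[str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of significant edges by region and by system pair.

    Returns (per_region, per_system_pair):
    per_region has the count of significant incident edges (degree);
    per_system_pair has the significant count divided by the total number
    of possible edges between (or within) the two systems.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != edge_index.n_edges:
        raise ValueError("mask length does not match edge index")
    labels = list(map(str, system_labels))
    if len(labels) != edge_index.n_regions:
        raise ValueError("every region needs a system label")

    degree = np.zeros(edge_index.n_regions, dtype=int)
    systems = sorted(set(labels))
    sig_counts: Dict[Tuple[str, str], int] = {}
    tot_counts: Dict[Tuple[str, str], int] = {}
    for pos, (i, j) in enumerate(edge_index.pairs):
        key = tuple(sorted((labels[i], labels[j])))
        tot_counts[key] = tot_counts.get(key, 0) + 1
        if mask[pos]:
            degree[i] += 1
            degree[j] += 1
            sig_counts[key] = sig_counts.get(key, 0) + 1

    per_region = pd.DataFrame(
        {"region": np.arange(edge_index.n_regions), "system": labels, "degree": degree}
    )
    rows = []
    for s_i, sa in enumerate(systems):
        for sb in systems[s_i:]:
            key = (sa, sb)
            total = tot_counts.get(key, 0)
            sig = sig_counts.get(key, 0)
            rows.append(
                {
                    "system_a": sa,
                    "system_b": sb,
                    "n_significant": sig,
                    "n_possible": total,
                    "normalized": sig / total if total else np.nan,
                }
            )
    return per_region, pd.DataFrame(rows)
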