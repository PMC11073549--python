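"""Subject-level estimators: denoising, activation GLM, edge GLM, gPPI.

All four are scikit-learn style estimators (``BaseEstimator`` subclasses
with ``fit`` and trailing-underscore fitted attributes) whose inputs are
:class:`~cofluct.data.SubjectRun` objects.  Module-level functions wrap
them for one-shot use.

The configuration axes mirror the robustness toggles of the analysis:

* ``remove_task`` — regress FIR task terms out of the parcel series
  before edge formation (default) or keep task effects in.
* ``hrf_model`` — "double-gamma" triplets (default) or raw "boxcar"
  task regressors.
* ``gsr`` — include the global (whole-brain mean) signal as a nuisance
  regressor.
* ``standardize`` — z-score the response and non-constant design columns
  inside the GLM.
* ``prewhiten`` — AR(1) prewhitening of both sides of the regression.

Defaults correspond to the main pipeline: FIR removal, double-gamma HRF,
GSR on, GLM-level standardization off, prewhitening on.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import regressors as regr
from .data import Confounds, ParcelSeries, SubjectRun
from .edges import EdgeIndex, EdgeMatrix, edge_series, standardize_columns
from .glm import ContrastResult, RankDeficientError, contrast, fit_glm, ols_fit
from .regressors import CONDITIONS, DesignMatrix, TaskDesign

logger = logging.getLogger(__name__)

__all__ = [
    "Denoiser",
    "ActivationGLM",
    "EdgeGLM",
    "GPPI",
    "denoise",
    "run_activation_glm",
    "run_edge_glm",
    "run_gppi",
]


def _main_column(condition: str, hrf_model: str) -> str:
    return condition if hrf_model == "double-gamma" else f"{condition}_box"


class Denoiser(BaseEstimator):
    """Single-step nuisance (and optionally task) regression of parcel series.

    Residualizes every region's series on the denoise design (FIR task
    terms when ``remove_task``, 24 motion parameters, WM, CSF, global
    signal when ``gsr``, cosine drift, intercept) in one regression, so
    removed artifacts cannot be reintroduced by sequential filtering.
    """

    def __init__(
        self,
        remove_task: bool = True,
        gsr: bool = True,
        n_fir: int = 12,
        cosine_cutoff: float = 187.0,
    ):
        self.remove_task = remove_task
        self.gsr = gsr
        self.n_fir = n_fir
        self.cosine_cutoff = cosine_cutoff

    def _design(self, run: SubjectRun) -> DesignMatrix:
        if run.is_rest:
            return regr.rest_denoise_design(
                run.confounds, run.parcels.tr, gsr=self.gsr, cosine_cutoff=self.cosine_cutoff
            )
        return regr.denoise_design(
            run.design,
            run.confounds,
            remove_task=self.remove_task,
            gsr=self.gsr,
            n_fir=self.n_fir,
            cosine_cutoff=self.cosine_cutoff,
        )

    def fit(self, run: SubjectRun, y=None) -> "Denoiser":
        X = self._design(run)
        self.design_matrix_ = X
        self.fit_ = ols_fit(run.parcels.data, X)
        return self

    def transform(self, run: SubjectRun) -> ParcelSeries:
        X = self._design(run)
        fit = ols_fit(run.parcels.data, X)
        resid = run.parcels.data - X.values @ fit.betas
        return run.parcels.with_data(resid)

    def fit_transform(self, run: SubjectRun, y=None) -> ParcelSeries:
        return self.fit(run).transform(run)


class ActivationGLM(BaseEstimator):
    """Region-level activation GLM with the incongruent-vs-congruent contrast.

    One GLM per parcel on the node-activation design (HRF triplets per
    condition plus the full nuisance set), AR(1)-prewhitened by default.
    """

    def __init__(
        self,
        hrf_model: str = "double-gamma",
        gsr: bool = True,
        prewhiten: bool = True,
        standardize: bool = False,
        cosine_cutoff: float = 187.0,
    ):
        self.hrf_model = hrf_model
        self.gsr = gsr
        self.prewhiten = prewhiten
        self.standardize = standardize
        self.cosine_cutoff = cosine_cutoff

    def fit(self, run: SubjectRun, y=None) -> "ActivationGLM":
        if run.is_rest:
            raise ValueError("activation GLM requires a task run")
        X = regr.activation_design(
            run.design,
            run.confounds,
            hrf_model=self.hrf_model,
            gsr=self.gsr,
            cosine_cutoff=self.cosine_cutoff,
        )
        try:
            fit = fit_glm(
                run.parcels.data,
                X,
                prewhiten=self.prewhiten,
                standardize=self.standardize,
            )
        except RankDeficientError as err:
            raise RankDeficientError(f"subject {run.subject_id}: {err}") from err
        c = X.contrast_vector(
            {
                _main_column("incongruent", self.hrf_model): 1.0,
                _main_column("congruent", self.hrf_model): -1.0,
            }
        )
        self.design_matrix_ = X
        self.glm_fit_ = fit
        self.contrast_ = contrast(fit, c)
        self.beta_ = self.contrast_.effect
        self.t_ = self.contrast_.t
        self.p_ = self.contrast_.p
        self.dof_ = self.contrast_.dof
        return self


class EdgeGLM(BaseEstimator):
    """Edge time-series GLM: intrinsic and task-dependent correlations.

    Parcel series are denoised, z-scored (whole run, T - 1 denominator)
    and multiplied pairwise into edge time series, which are then
    regressed on an intercept plus HRF task regressors.  The intercept
    estimates the intrinsic (task-free) correlation; condition betas give
    condition-specific correlation changes; the reported contrast is
    incongruent minus congruent on the main HRF columns.  Rest runs use
    an intercept-only design.
    """

    def __init__(
        self,
        remove_task: bool = True,
        gsr: bool = True,
        hrf_model: str = "double-gamma",
        prewhiten: bool = True,
        standardize: bool = False,
        n_fir: int = 12,
        cosine_cutoff: float = 187.0,
    ):
        self.remove_task = remove_task
        self.gsr = gsr
        self.hrf_model = hrf_model
        self.prewhiten = prewhiten
        self.standardize = standardize
        self.n_fir = n_fir
        self.cosine_cutoff = cosine_cutoff

    def fit(self, run: SubjectRun, y=None) -> "EdgeGLM":
        denoiser = Denoiser(
            remove_task=(self.remove_task and not run.is_rest),
            gsr=self.gsr,
            n_fir=self.n_fir,
            cosine_cutoff=self.cosine_cutoff,
        )
        cleaned = denoiser.transform(run)
        Z = standardize_columns(cleaned.data)
        E = edge_series(Z, tr=run.parcels.tr)
        self.edge_index_ = E.index
        self.edge_matrix_ = E

        if run.is_rest:
            X = regr.intercept_only(E.n_frames)
            fit = fit_glm(E.values, X, prewhiten=self.prewhiten, standardize=self.standardize)
            self.design_matrix_ = X
            self.glm_fit_ = fit
            self.results_ = {"intercept": contrast(fit, np.array([1.0]))}
            self.contrast_ = None
            return self

        X = regr.edge_design(run.design, hrf_model=self.hrf_model)
        try:
            fit = fit_glm(E.values, X, prewhiten=self.prewhiten, standardize=self.standardize)
        except RankDeficientError as err:
            raise RankDeficientError(f"subject {run.subject_id}: {err}") from err
        self.design_matrix_ = X
        self.glm_fit_ = fit
        inc = _main_column("incongruent", self.hrf_model)
        con = _main_column("congruent", self.hrf_model)
        self.results_ = {
            "intercept": contrast(fit, X.contrast_vector({"intercept": 1.0})),
            "congruent": contrast(fit, X.contrast_vector({con: 1.0})),
            "incongruent": contrast(fit, X.contrast_vector({inc: 1.0})),
            "contrast": contrast(fit, X.contrast_vector({inc: 1.0, con: -1.0})),
        }
        self.contrast_ = self.results_["contrast"]
        return self


class GPPI(BaseEstimator):
    """Generalized psychophysiological interaction comparator.

    For each ordered region pair (seed j -> target i) the raw target
    series is regressed on an intercept, the raw seed series (background
    coupling), the task regressors (HRF triplets for both conditions),
    the interaction of the seed with each condition's main HRF regressor,
    and the nuisance covariates.  The pair's task-modulated coupling is
    the incongruent-minus-congruent difference of the interaction betas;
    the directed matrix is symmetrized by averaging its upper and lower
    triangles.  Interactions use the observed (not deconvolved) seed
    series; derivative columns stay in the task block but are not
    interacted.
    """

    def __init__(
        self,
        gsr: bool = True,
        hrf_model: str = "double-gamma",
        prewhiten: bool = True,
        cosine_cutoff: float = 187.0,
    ):
        self.gsr = gsr
        self.hrf_model = hrf_model
        self.prewhiten = prewhiten
        self.cosine_cutoff = cosine_cutoff

    def fit(self, run: SubjectRun, y=None) -> "GPPI":
        if run.is_rest:
            raise ValueError("gPPI requires a task run")
        design, confounds = run.design, run.confounds
        data = run.parcels.data
        n_frames, n_regions = data.shape

        task_parts = [regr.hrf_triplet(design, c, model=self.hrf_model) for c in CONDITIONS]
        task_values = np.hstack([p[0] for p in task_parts])
        main_cols = [regr.hrf_triplet(design, c, model=self.hrf_model)[0][:, 0] for c in CONDITIONS]
        cov = regr.build_design(
            regr._confound_blocks(confounds, self.gsr, n_frames, design.tr, self.cosine_cutoff),
            include_intercept=True,
        )

        # column layout: [seed, ppi_congruent, ppi_incongruent, task..., cov...]
        p = 3 + task_values.shape[1] + cov.n_columns
        X = np.empty((n_frames, p))
        X[:, 3 : 3 + task_values.shape[1]] = task_values
        X[:, 3 + task_values.shape[1] :] = cov.values
        c_vec = np.zeros(p)
        c_vec[1], c_vec[2] = -1.0, 1.0  # incongruent ppi minus congruent ppi

        directed = np.full((n_regions, n_regions), np.nan)
        directed_t = np.full((n_regions, n_regions), np.nan)
        skipped: List[Tuple[int, int]] = []
        for j in range(n_regions):  # seed
            seed = data[:, j]
            X[:, 0] = seed
            X[:, 1] = seed * main_cols[0]
            X[:, 2] = seed * main_cols[1]
            targets = [i for i in range(n_regions) if i != j]
            try:
                fit = fit_glm(data[:, targets], X, prewhiten=self.prewhiten)
            except RankDeficientError:
                skipped.extend((i, j) for i in targets)
                logger.warning("gPPI: rank-deficient design for seed %d; pairs skipped", j)
                continue
            res = contrast(fit, c_vec)
            directed[targets, j] = res.effect
            directed_t[targets, j] = res.t
        np.fill_diagonal(directed, 0.0)
        np.fill_diagonal(directed_t, 0.0)

        sym = 0.5 * (directed + directed.T)
        self.directed_contrast_ = directed
        self.directed_t_ = directed_t
        self.contrast_matrix_ = sym
        self.edge_index_ = EdgeIndex(n_regions)
        iu = np.triu_indices(n_regions, k=1)
        self.contrast_ = sym[iu]
        self.skipped_ = skipped
        return self


def denoise(run: SubjectRun, remove_task: bool = True, gsr: bool = True, **kwargs) -> ParcelSeries:
    """Residualize a run's parcel series on the denoise design."""
    return Denoiser(remove_task=remove_task, gsr=gsr, **kwargs).transform(run)


def run_activation_glm(run: SubjectRun, **kwargs) -> ContrastResult:
    """Incongruent-vs-congruent activation contrast per region."""
    return ActivationGLM(**kwargs).fit(run).contrast_


def run_edge_glm(run: SubjectRun, **kwargs) -> Dict[str, ContrastResult]:
    """Edge-GLM coefficient maps (intercept / congruent / incongruent / contrast)."""
    return EdgeGLM(**kwargs).fit(run).results_


def run_gppi(run: SubjectRun, gsr: bool = True, **kwargs) -> np.ndarray:
    """Symmetrized gPPI incongruent-vs-congruent contrast matrix."""
    return GPPI(gsr=gsr, **kwargs).fit(run).contrast_matrix_
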