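"""Readers and writers for the standard on-disk formats.

Tabular inputs are TSV: parcel series (frames x regions with a JSON
sidecar holding TR and system labels), BIDS-style events files (onset,
duration, trial_type) and fMRIPrep-style confounds.  Volumetric input
(4D BOLD + integer-label atlas NIfTI) is supported through nibabel for
parcel extraction.  Synthetic cohorts are written in exactly these
formats so end-to-end tests exercise the real I/O path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import Confounds, ParcelSeries, SubjectRun
from .regressors import TaskDesign
from .synthetic import Cohort

__all__ = [
    "RunManifest",
    "parcellate",
    "read_parcels",
    "write_parcels",
    "read_events",
    "write_events",
    "read_confounds",
    "write_confounds",
    "read_run",
    "write_cohort",
    "load_cohort_runs",
]

#: canonical confound column names; alternative dialects map onto these
CONFOUND_COLUMNS = [
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "white_matter",
    "csf",
    "global_signal",
]


class MissingColumnError(ValueError):
    """A required column is absent from an input table."""


def _check_nan(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: NaN cell at row {row}")


def parcellate(image, atlas) -> ParcelSeries:
    """Average voxel signal within each atlas label of a 4D image.

    ``image`` and ``atlas`` are nibabel images (or paths); the atlas is an
    integer-label volume on the same grid, 0 = background, labels
    ascending in the output.  An atlas label with no voxels raises.
    """
    import nibabel as nib

    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    if isinstance(atlas, (str, Path)):
        atlas = nib.load(str(atlas))
    data = np.asarray(image.dataobj, dtype=float)
    labels_vol = np.asarray(atlas.dataobj)
    labels_vol = np.rint(labels_vol).astype(int)
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    if labels_vol.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match the BOLD image")
    labels = sorted(int(l) for l in np.unique(labels_vol) if l > 0)
    if not labels:
        raise ValueError("atlas contains no positive labels")
    n_frames = data.shape[3]
    out = np.empty((n_frames, len(labels)))
    flat = data.reshape(-1, n_frames)
    flat_labels = labels_vol.reshape(-1)
    for k, lab in enumerate(labels):
        voxels = flat_labels == lab
        if not voxels.any():
            raise ValueError(f"atlas label {lab} has no voxels")
        out[:, k] = flat[voxels].mean(axis=0)
    tr = float(image.header.get_zooms()[3]) if len(image.header.get_zooms()) > 3 else 1.0
    return ParcelSeries(out, tr=tr if tr > 0 else 1.0, region_ids=[str(l) for l in labels])


def write_parcels(series: ParcelSeries, path) -> None:
    path = Path(path)
    series.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {"tr": series.tr, "systems": series.systems}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_parcels(path, tr: Optional[float] = None) -> ParcelSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_nan(df, path)
    systems = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr = tr if tr is not None else meta.get("tr")
        systems = meta.get("systems")
    if tr is None:
        raise ValueError(f"{path}: TR not given and no JSON sidecar found")
    return ParcelSeries(df.to_numpy(dtype=float), tr=float(tr), region_ids=list(df.columns), systems=systems)


def write_events(design: TaskDesign, path) -> None:
    rows = [
        {"onset": onset, "duration": dur, "trial_type": cond}
        for cond, onset, dur in design.blocks
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(
    path,
    n_frames: int,
    tr: float,
    condition_map: Optional[Dict[str, str]] = None,
) -> TaskDesign:
    """BIDS events.tsv -> TaskDesign; trial_type labels mapped via config."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    _check_nan(df[["onset", "duration", "trial_type"]], path)
    condition_map = condition_map or {}
    blocks = [
        (condition_map.get(str(r.trial_type), str(r.trial_type)), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    return TaskDesign(blocks, n_frames=n_frames, tr=tr)


def write_confounds(confounds: Confounds, path) -> None:
    confounds.to_frame().to_csv(path, sep="\t", index=False)


def read_confounds(path, column_map: Optional[Dict[str, str]] = None) -> Confounds:
    """fMRIPrep-style confounds TSV; ``column_map`` maps dialect names.

    ``column_map`` takes {canonical_name: actual_name}, e.g.
    ``{"white_matter": "wm_avg"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    column_map = column_map or {}
    resolved = {}
    missing = []
    for canon in CONFOUND_COLUMNS:
        actual = column_map.get(canon, canon)
        if actual not in df.columns:
            missing.append(actual)
        else:
            resolved[canon] = actual
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    sub = df[[resolved[c] for c in CONFOUND_COLUMNS]]
    _check_nan(sub, path)
    vals = sub.to_numpy(dtype=float)
    return Confounds(
        motion=vals[:, :6],
        white_matter=vals[:, 6],
        csf=vals[:, 7],
        global_signal=vals[:, 8],
    )


@dataclass
class RunManifest:
    """Paths of one run's inputs; files are checked for existence at load."""

    subject_id: str
    run_id: str
    parcels: Union[str, Path]
    confounds: Union[str, Path]
    events: Optional[Union[str, Path]] = None  # None for rest
    tr: Optional[float] = None
    condition_map: Optional[Dict[str, str]] = None
    confound_map: Optional[Dict[str, str]] = None

    def load(self) -> SubjectRun:
        for p in (self.parcels, self.confounds, self.events):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(str(p))
        parcels = read_parcels(self.parcels, tr=self.tr)
        confounds = read_confounds(self.confounds, column_map=self.confound_map)
        design = None
        if self.events is not None:
            design = read_events(
                self.events, n_frames=parcels.n_frames, tr=parcels.tr, condition_map=self.condition_map
            )
        return SubjectRun(
            parcels=parcels,
            confounds=confounds,
            design=design,
            subject_id=self.subject_id,
            run_id=self.run_id,
        )


def read_run(parcels_path, confounds_path, events_path=None, **kwargs) -> SubjectRun:
    """Convenience one-run loader."""
    manifest = RunManifest(
        subject_id=kwargs.pop("subject_id", "sub-01"),
        run_id=kwargs.pop("run_id", "run-01"),
        parcels=parcels_path,
        confounds=confounds_path,
        events=events_path,
        **kwargs,
    )
    return manifest.load()


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write a synthetic cohort in the pipeline's input formats.

    Layout: ``<dir>/<subject>/<run>_parcels.tsv`` (+ .json sidecar),
    ``<run>_events.tsv`` for task runs, ``<run>_confounds.tsv``, plus a
    cohort-level ``truth.json`` and ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: List[Dict[str, Optional[str]]] = []
    for task, runs in cohort.runs().items():
        for run in runs:
            sub_dir = directory / run.subject_id
            sub_dir.mkdir(exist_ok=True)
            stem = sub_dir / task
            write_parcels(run.parcels, stem.with_name(f"{task}_parcels.tsv"))
            write_confounds(run.confounds, stem.with_name(f"{task}_confounds.tsv"))
            entry = {
                "subject_id": run.subject_id,
                "run_id": task,
                "parcels": f"{run.subject_id}/{task}_parcels.tsv",
                "confounds": f"{run.subject_id}/{task}_confounds.tsv",
                "events": None,
            }
            if run.design is not None:
                write_events(run.design, stem.with_name(f"{task}_events.tsv"))
                entry["events"] = f"{run.subject_id}/{task}_events.tsv"
            manifest.append(entry)
    truth = cohort.truth
    truth_payload = {
        "seed": truth.seed,
        "rho": truth.rho,
        "sigma_intrinsic": truth.sigma_intrinsic.tolist(),
        "amplitudes": {k: v.tolist() for k, v in truth.amplitudes.items()},
        "modulated_edges": {
            task: {cond: [list(e) for e in edges] for cond, edges in sets.items()}
            for task, sets in truth.modulated_edges.items()
        },
        "deltas": truth.deltas,
    }
    (directory / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_cohort_runs(directory) -> Dict[str, List[SubjectRun]]:
    """Load every run listed in a cohort directory's manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out: Dict[str, List[SubjectRun]] = {}
    for entry in manifest:
        run = RunManifest(
            subject_id=entry["subject_id"],
            run_id=entry["run_id"],
            parcels=directory / entry["parcels"],
            confounds=directory / entry["confounds"],
            events=directory / entry["events"] if entry["events"] else None,
        ).load()
        out.setdefault(entry["run_id"], []).append(run)
    return out
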