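"""Persistent study containers.

A :class:`StudyContainer` bundles everything a group analysis needs — one
posterior/prior pair per subject, the covariate table and provenance — in
a single file.  HDF5 is the primary on-disk format (arrays stay float64,
round trips are bit exact); JSON is provided as a portable fallback for
small studies.  Format choice is by file extension (.h5/.hdf5 vs .json).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .densities import FirstLevelUnit, GaussianDensity

__all__ = ["FORMAT_VERSION", "StudyContainer", "read_container", "write_container"]

FORMAT_VERSION = "1.0"


@dataclass
class StudyContainer:
    """Subjects' first-level densities plus covariates and provenance."""

    units: list[FirstLevelUnit]
    covariates: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("a study container needs at least one subject")
        labels = self.units[0].labels
        for u in self.units:
            if u.labels != labels:
                raise ValueError(
                    f"subject {u.subject_id}: parameter labels differ from "
                    "the first subject's"
                )
        ids = [u.subject_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        if self.covariates.shape[0] != len(self.units):
            raise ValueError(
                f"covariate table has {self.covariates.shape[0]} rows for "
                f"{len(self.units)} subjects"
            )

    @property
    def parameter_labels(self) -> tuple[str, ...]:
        return self.units[0].labels

    @property
    def n_subjects(self) -> int:
        return len(self.units)

    @classmethod
    def from_study(cls, study, extra_provenance: Optional[dict] = None):
        """Build a container from a :class:`pebglm.simulate.SimulatedStudy`."""
        prov = {"seed": study.seed, "generator": "pebglm.simulate"}
        prov.update(extra_provenance or {})
        return cls(units=list(study.units), covariates=study.covariates, provenance=prov)


def write_container(obj: StudyContainer, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(obj, path)
    elif path.suffix == ".json":
        _write_json(obj, path)
    else:
        raise ValueError(f"unknown container extension {path.suffix!r}")


def read_container(path) -> StudyContainer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    if path.suffix == ".json":
        return _read_json(path)
    raise ValueError(f"unknown container extension {path.suffix!r}")


def _write_h5(obj: StudyContainer, path: Path) -> None:
    str_dtype = h5py.string_dtype("utf-8")

    def ds(group, name, data):
        # track_times=False keeps same-seed writes byte-identical.
        group.create_dataset(name, data=data, track_times=False)

    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["version"] = obj.version
        f.attrs["provenance"] = json.dumps(obj.provenance, sort_keys=True)
        ds(f, "parameter_labels", np.array(obj.parameter_labels, dtype=str_dtype))
        ds(f, "subject_order", np.array(
            [u.subject_id for u in obj.units], dtype=str_dtype
        ))
        subs = f.create_group("subjects", track_order=True)
        for u in obj.units:
            g = subs.create_group(u.subject_id, track_order=True)
            ds(g, "posterior_mean", u.posterior.mean)
            ds(g, "posterior_cov", u.posterior.cov)
            ds(g, "prior_mean", u.prior.mean)
            ds(g, "prior_cov", u.prior.cov)
            g.attrs["free_energy"] = (
                np.nan if u.free_energy is None else u.free_energy
            )
        cov = f.create_group("covariates", track_order=True)
        cov.attrs["columns"] = json.dumps(list(map(str, obj.covariates.columns)))
        ds(cov, "subject_id", np.array(
            [str(s) for s in obj.covariates.index], dtype=str_dtype
        ))
        for col in obj.covariates.columns:
            ds(cov, str(col), obj.covariates[col].to_numpy(dtype=float))


def _read_h5(path: Path) -> StudyContainer:
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise ValueError(f"{path}: not a readable HDF5 container ({err})") from err
    with f:
        version = f.attrs.get("version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"{path}: container version {version!r} is not supported "
                f"(expected {FORMAT_VERSION}); re-export the study"
            )
        labels = tuple(x.decode() for x in f["parameter_labels"][()])
        order = [x.decode() for x in f["subject_order"][()]]
        units = []
        for sid in order:
            try:
                g = f["subjects"][sid]
                units.append(
                    FirstLevelUnit(
                        subject_id=sid,
                        posterior=GaussianDensity(
                            labels, g["posterior_mean"][()], g["posterior_cov"][()]
                        ),
                        prior=GaussianDensity(
                            labels, g["prior_mean"][()], g["prior_cov"][()]
                        ),
                        free_energy=(
                            None
                            if np.isnan(g.attrs["free_energy"])
                            else float(g.attrs["free_energy"])
                        ),
                    )
                )
            except (KeyError, ValueError) as err:
                raise ValueError(
                    f"{path}: subject {sid!r} is malformed: {err}"
                ) from err
        cov = f["covariates"]
        columns = json.loads(cov.attrs["columns"])
        index = [x.decode() for x in cov["subject_id"][()]]
        covariates = pd.DataFrame(
            {c: cov[c][()] for c in columns},
            index=pd.Index(index, name="subject_id"),
        )
        provenance = json.loads(f.attrs.get("provenance", "{}"))
    return StudyContainer(
        units=units, covariates=covariates, provenance=provenance, version=version
    )


def _write_json(obj: StudyContainer, path: Path) -> None:
    payload = {
        "version": obj.version,
        "provenance": obj.provenance,
        "parameter_labels": list(obj.parameter_labels),
        "subjects": [
            {
                "subject_id": u.subject_id,
                "posterior_mean": u.posterior.mean.tolist(),
                "posterior_cov": u.posterior.cov.tolist(),
                "prior_mean": u.prior.mean.tolist(),
                "prior_cov": u.prior.cov.tolist(),
                "free_energy": u.free_energy,
            }
            for u in obj.units
        ],
        "covariates": {
            "subject_id": [str(s) for s in obj.covariates.index],
            "columns": {
                str(c): obj.covariates[c].to_numpy(dtype=float).tolist()
                for c in obj.covariates.columns
            },
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _read_json(path: Path) -> StudyContainer:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: truncated or invalid JSON container") from err
    version = payload.get("version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path}: container version {version!r} is not supported "
            f"(expected {FORMAT_VERSION})"
        )
    labels = tuple(payload["parameter_labels"])
    units = []
    for sub in payload["subjects"]:
        try:
            units.append(
                FirstLevelUnit(
                    subject_id=sub["subject_id"],
                    posterior=GaussianDensity(
                        labels, sub["posterior_mean"], sub["posterior_cov"]
                    ),
                    prior=GaussianDensity(
                        labels, sub["prior_mean"], sub["prior_cov"]
                    ),
                    free_energy=sub.get("free_energy"),
                )
            )
        except (KeyError, ValueError) as err:
            raise ValueError(
                f"{path}: subject {sub.get('subject_id')!r} is malformed: {err}"
            ) from err
    cov = payload["covariates"]
    covariates = pd.DataFrame(
        {c: np.asarray(v, dtype=float) for c, v in cov["columns"].items()},
        index=pd.Index(cov["subject_id"], name="subject_id"),
    )
    return StudyContainer(
        units=units,
        covariates=covariates,
        provenance=payload.get("provenance", {}),
        version=version,
    )
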