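"""Labeled-TSV input/output for every table the pipeline reads or writes.

One matrix dialect everywhere: tab-separated, one header row of column
labels, one leading column of row labels, full-precision floats (17
significant digits, decimal point enforced regardless of locale).  Readers
re-index by label and fail loudly on duplicates, ragged rows or
non-numeric cells, with the offending line number in the message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .structural import HarmonicBasis
from .synth import Cohort, CohortSpec, Parcellation

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_basis",
    "read_basis",
    "write_cohort",
    "read_cohort",
]


def write_matrix_tsv(
    values: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    path: str | Path,
) -> None:
    """Write a labeled matrix as TSV with full float precision."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_labels), len(col_labels)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(row_labels)} row and {len(col_labels)} column labels"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["label", *map(str, col_labels)]) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write(str(lab) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled TSV matrix written by :func:`write_matrix_tsv`.

    Returns (values, row_labels, col_labels).  Parsing uses ``float()``
    directly, so a comma-decimal locale cannot corrupt values.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: header must contain a label column and data columns")
        col_labels = header[1:]
        if len(set(col_labels)) != len(col_labels):
            dup = next(c for c in col_labels if col_labels.count(c) > 1)
            raise ValueError(f"{path}:1: duplicate column label '{dup}'")
        row_labels: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            label = parts[0]
            if label in seen:
                raise ValueError(f"{path}:{lineno}: duplicate row label '{label}'")
            seen.add(label)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            row_labels.append(label)
    return np.array(rows), row_labels, col_labels


def write_basis(basis: HarmonicBasis, directory: str | Path) -> None:
    """Serialize a harmonic basis (eigenvalues + eigenvectors + metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = basis.n_regions
    labels = [f"h{k + 1}" for k in range(n)]
    regions = [f"r{k + 1}" for k in range(n)]
    write_matrix_tsv(basis.eigenvalues[None, :], ["eigenvalue"], labels,
                     directory / "eigenvalues.tsv")
    write_matrix_tsv(basis.eigenvectors, regions, labels, directory / "eigenvectors.tsv")
    meta = {"cutoff": basis.cutoff, "source": basis.source, "n_regions": n}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_basis(directory: str | Path) -> HarmonicBasis:
    directory = Path(directory)
    lam, _, _ = read_matrix_tsv(directory / "eigenvalues.tsv")
    U, _, _ = read_matrix_tsv(directory / "eigenvectors.tsv")
    meta = json.loads((directory / "meta.json").read_text())
    return HarmonicBasis(
        eigenvectors=U,
        eigenvalues=lam.ravel(),
        cutoff=meta.get("cutoff"),
        source=meta.get("source", ""),
    )


def _region_labels(parcellation: Parcellation) -> list[str]:
    return [str(r) for r in parcellation.region_id]


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort directory: parcellation, subjects, signals, connectomes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = cohort.parcellation
    parc = pd.DataFrame(
        {
            "region_id": p.region_id,
            "name": p.name,
            "hemisphere": p.hemisphere,
            "x": p.centroid[:, 0],
            "y": p.centroid[:, 1],
            "z": p.centroid[:, 2],
            "volume": p.volume,
        }
    )
    parc.to_csv(directory / "parcellation.tsv", sep="\t", index=False, float_format="%.17g")
    subj = pd.DataFrame(
        {
            "subject_id": cohort.subject_id,
            "group": cohort.group,
            "gender": cohort.gender,
            "mean_fd": cohort.mean_fd,
            "severity": cohort.severity,
        }
    )
    subj.to_csv(directory / "subjects.tsv", sep="\t", index=False, float_format="%.17g")
    regions = _region_labels(p)
    (directory / "timeseries").mkdir(exist_ok=True)
    (directory / "connectome").mkdir(exist_ok=True)
    for sid, ts, sc in zip(cohort.subject_id, cohort.timeseries, cohort.connectome):
        tlabels = [f"t{k + 1}" for k in range(ts.shape[1])]
        write_matrix_tsv(ts, regions, tlabels, directory / "timeseries" / f"{sid}.tsv")
        write_matrix_tsv(sc, regions, regions, directory / "connectome" / f"{sid}.tsv")
    spec = cohort.spec
    meta = {
        "seed": spec.seed,
        "n_regions": spec.n_regions,
        "n_timepoints": spec.n_timepoints,
        "n_per_group": list(spec.n_per_group),
        "effect_regions": list(spec.effect_regions),
        "effect_size": spec.effect_size,
        "severity_link_regions": list(spec.severity_link_regions),
        "severity_rho": spec.severity_rho,
        "base_high_gain": spec.base_high_gain,
        "cutoff_fraction": spec.cutoff_fraction,
    }
    (directory / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    return Parcellation(
        region_id=df["region_id"].to_numpy(dtype=int),
        name=df["name"].astype(str).tolist(),
        hemisphere=df["hemisphere"].to_numpy(dtype="<U1"),
        centroid=df[["x", "y", "z"]].to_numpy(dtype=float),
        volume=df["volume"].to_numpy(dtype=float),
    )


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Region order is canonical (parcellation order); matrices are
    re-indexed by row label and a label mismatch is an error.
    """
    directory = Path(directory)
    parc = read_parcellation(directory / "parcellation.tsv")
    subj = pd.read_csv(directory / "subjects.tsv", sep="\t")
    meta = json.loads((directory / "cohort.json").read_text())
    spec = CohortSpec(
        n_regions=meta["n_regions"],
        n_timepoints=meta["n_timepoints"],
        n_per_group=tuple(meta["n_per_group"]),
        effect_regions=tuple(meta["effect_regions"]),
        effect_size=meta["effect_size"],
        severity_link_regions=tuple(meta["severity_link_regions"]),
        severity_rho=meta["severity_rho"],
        base_high_gain=meta.get("base_high_gain", 1.0),
        cutoff_fraction=meta.get("cutoff_fraction", 0.5),
        seed=meta["seed"],
    )
    expected = [str(r) for r in parc.region_id]
    timeseries, connectomes = [], []
    for sid in subj["subject_id"]:
        ts, rlab, _ = read_matrix_tsv(directory / "timeseries" / f"{sid}.tsv")
        if rlab != expected:
            order = _reindex(rlab, expected, directory / "timeseries" / f"{sid}.tsv")
            ts = ts[order]
        timeseries.append(ts)
        sc, rlab, clab = read_matrix_tsv(directory / "connectome" / f"{sid}.tsv")
        if rlab != expected or clab != expected:
            order = _reindex(rlab, expected, directory / "connectome" / f"{sid}.tsv")
            corder = _reindex(clab, expected, directory / "connectome" / f"{sid}.tsv")
            sc = sc[np.ix_(order, corder)]
        connectomes.append(sc)
    # the generating basis is not stored; rebuild lazily when needed
    from . import structural

    sc_all = structural.group_average(connectomes)
    sc_norm = structural.volume_normalize(sc_all, parc.volume)
    A, _ = structural.symmetric_normalize(sc_norm)
    basis = structural.harmonics(A, source="pooled").with_cutoff(
        max(1, int(round(spec.cutoff_fraction * spec.n_regions)))
    )
    return Cohort(
        spec=spec,
        parcellation=parc,
        subject_id=subj["subject_id"].astype(str).tolist(),
        group=subj["group"].to_numpy(dtype=int),
        gender=subj["gender"].to_numpy(dtype=int),
        mean_fd=subj["mean_fd"].to_numpy(dtype=float),
        severity=subj["severity"].to_numpy(dtype=float),
        timeseries=timeseries,
        connectome=connectomes,
        basis=basis,
        truth_high_gain=np.ones((len(subj), spec.n_regions)),
    )


def _reindex(labels: list[str], expected: list[str], path: Path) -> np.ndarray:
    pos = {lab: k for k, lab in enumerate(labels)}
    missing = [lab for lab in expected if lab not in pos]
    if missing:
        raise ValueError(f"{path}: region label(s) {missing[:3]} missing from file")
    return np.array([pos[lab] for lab in expected])
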