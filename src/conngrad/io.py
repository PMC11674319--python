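"""Plain-text (TSV) readers and writers for all pipeline artifacts.

Inputs are parcellated, so everything round-trips through delimited text:
square connectivity matrices with a one-line parcel-id header, a
parcellation table, a subject covariate table, and gradient tables with
an eigenvalue sidecar. Readers validate shapes and reject non-finite
entries with the offending location.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .embedding import GradientSet
from .parcellation import ParcellationScheme

_FLOAT_FMT = "%.17g"  # full round-trip precision for float64


def write_matrix(matrix: np.ndarray, path: str | Path, parcel_ids=None) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got {m.shape}")
    ids = np.arange(m.shape[0]) if parcel_ids is None else np.asarray(parcel_ids)
    header = "\t".join(str(i) for i in ids)
    np.savetxt(path, m, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")


def read_matrix(path: str | Path, n_parcels: int | None = None) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    m = np.loadtxt(path, delimiter="\t", skiprows=1)
    m = np.atleast_2d(m)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape}, expected square")
    if n_parcels is not None and m.shape[0] != n_parcels:
        raise ValueError(f"{path}: {m.shape[0]} parcels, expected {n_parcels}")
    bad = np.argwhere(~np.isfinite(m))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: non-finite entry at row {i + 1}, column {j + 1}")
    return m


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    write_matrix(cm.values, path)


def read_connectivity(
    path: str | Path, modality: str, transform_state: str, n_parcels=None
) -> ConnectivityMatrix:
    return ConnectivityMatrix(
        read_matrix(path, n_parcels), modality=modality, transform_state=transform_state
    )


PARCELLATION_COLUMNS = [
    "parcel_id", "hemisphere", "x", "y", "z", "community", "hierarchy", "homologue",
]


def write_parcellation(scheme: ParcellationScheme, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": scheme.parcel_id,
            "hemisphere": scheme.hemisphere,
            "x": scheme.centroids[:, 0],
            "y": scheme.centroids[:, 1],
            "z": scheme.centroids[:, 2],
            "community": scheme.community,
            "hierarchy": scheme.hierarchy,
            "homologue": scheme.homologue,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_parcellation(path: str | Path) -> ParcellationScheme:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parcellation table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PARCELLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    # ParcellationScheme.validate enforces unit centroids and the
    # homologue involution on construction
    return ParcellationScheme(
        parcel_id=df["parcel_id"].to_numpy(int),
        hemisphere=df["hemisphere"].to_numpy(object),
        centroids=df[["x", "y", "z"]].to_numpy(float),
        community=df["community"].to_numpy(object),
        hierarchy=df["hierarchy"].to_numpy(object),
        homologue=df["homologue"].to_numpy(int),
    )


COVARIATE_COLUMNS = ["subject_id", "group", "age", "sex", "site", "motion"]


def write_covariates(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "site": r.site,
                "motion": r.motion,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_gradients(g: GradientSet, path: str | Path) -> None:
    """Gradient table plus a JSON sidecar of eigenvalues and variance."""
    path = Path(path)
    cols = {"parcel_id": np.arange(g.n_parcels)}
    for j in range(g.k):
        cols[f"G{j + 1}"] = g.components[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "eigenvalues": g.eigenvalues.tolist(),
        "variance_explained": g.variance_explained.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_gradients(path: str | Path) -> GradientSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gradient table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    gcols = [c for c in df.columns if c.startswith("G")]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        eigenvalues = np.asarray(sidecar["eigenvalues"])
        variance = np.asarray(sidecar["variance_explained"])
    else:
        eigenvalues = np.full(len(gcols), np.nan)
        variance = np.full(len(gcols), np.nan)
    return GradientSet(
        components=df[gcols].to_numpy(float),
        eigenvalues=eigenvalues,
        variance_explained=variance,
    )


def write_ground_truth(truth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "affected_parcel": truth.affected_parcels,
            "effect_size": truth.effect_size,
            "seed": truth.seed,
        }
    ).to_csv(path, sep="\t", index=False)


def write_effects(effects, path: str | Path) -> None:
    effects.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
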