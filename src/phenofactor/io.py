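"""Plain-text input/output: encounter CSVs, matrices, factors, manifests.

Formats
-------
* Encounter CSV: one row per encounter with the fixed header
  ``encounter_id, patient_id, gender, age_years, discharge_status, apr_drg,
  admitting_dx, secondary_dx, principal_dx, principal_proc,
  secondary_procs, free_text``; list-valued columns use semicolon-delimited
  codes.
* Dense matrices: CSV (header row optional on read, written without one).
* Sparse matrices: coordinate-triplet text ``row,col,value`` (0-based).
* Run manifests: JSON with the full configuration, seed, package version
  and SHA-256 checksums of the inputs, sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .features import EncounterRecord, TermEncounterMatrix, TermVocabulary
from .simulate import SyntheticCohort

ENCOUNTER_COLUMNS = [
    "encounter_id", "patient_id", "gender", "age_years", "discharge_status",
    "apr_drg", "admitting_dx", "secondary_dx", "principal_dx",
    "principal_proc", "secondary_procs", "free_text",
]

_LIST_COLUMNS = {"admitting_dx", "secondary_dx", "principal_dx",
                 "secondary_procs"}


def _join(codes) -> str:
    return ";".join(str(c) for c in codes)


def _split(cell) -> list:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    s = str(cell).strip()
    return [c.strip() for c in s.split(";") if c.strip()] if s else []


def write_encounters(records: Sequence[EncounterRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "encounter_id": r.encounter_id,
            "patient_id": r.patient_id,
            "gender": r.gender,
            "age_years": repr(r.age_years),
            "discharge_status": r.discharge_status,
            "apr_drg": r.apr_drg,
            "admitting_dx": _join(r.admitting_dx),
            "secondary_dx": _join(r.secondary_dx),
            "principal_dx": _join(r.principal_dx),
            "principal_proc": r.principal_proc or "",
            "secondary_procs": _join(r.secondary_procs),
            "free_text": r.free_text or "",
        })
    pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS).to_csv(path, index=False)


def read_encounters(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ENCOUNTER_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"encounter CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(EncounterRecord(
            encounter_id=row["encounter_id"],
            patient_id=row["patient_id"],
            gender=row["gender"],
            age_years=float(row["age_years"]),
            discharge_status=row["discharge_status"],
            apr_drg=int(row["apr_drg"]),
            admitting_dx=_split(row["admitting_dx"]),
            secondary_dx=_split(row["secondary_dx"]),
            principal_dx=_split(row["principal_dx"]),
            principal_proc=row["principal_proc"].strip() or None,
            secondary_procs=_split(row["secondary_procs"]),
            free_text=(row.get("free_text", "") or "").strip() or None,
        ))
    return records


def write_labels(cohort: SyntheticCohort, path) -> None:
    df = pd.DataFrame({
        "encounter_id": [r.encounter_id for r in cohort.records],
        "label": cohort.labels,
        "profile": [cohort.profile_assignments[r.encounter_id]
                    for r in cohort.records],
    })
    df.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"encounter_id": str, "label": int,
                                    "profile": str})


def write_dense_matrix(X: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(X, dtype=float), delimiter=",", fmt="%.17g")


def read_dense_matrix(path) -> np.ndarray:
    # tolerate an optional header row of non-numeric labels
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", ndmin=2))
    except ValueError:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1,
                                        ndmin=2))


def write_triplets(X: np.ndarray, path) -> None:
    X = np.asarray(X, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# shape {X.shape[0]} {X.shape[1]}\n")
        for i, j in zip(*np.nonzero(X)):
            fh.write(f"{i},{j},{X[i, j]:.17g}\n")


def read_triplets(path) -> np.ndarray:
    shape = None
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) >= 4 and parts[1] == "shape":
                    shape = (int(parts[2]), int(parts[3]))
                continue
            i, j, v = line.split(",")
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    if shape is None:
        shape = (max(rows) + 1, max(cols) + 1)
    X = np.zeros(shape)
    X[rows, cols] = vals
    return X


def write_vocabulary(vocab: TermVocabulary, path) -> None:
    Path(path).write_text("\n".join(vocab.terms) + "\n")


def read_vocabulary(path) -> TermVocabulary:
    terms = [t for t in Path(path).read_text().splitlines() if t.strip()]
    return TermVocabulary(terms)


def write_term_matrix(tm: TermEncounterMatrix, outdir) -> None:
    outdir = Path(outdir)
    write_triplets(tm.matrix, outdir / "matrix.txt")
    write_vocabulary(tm.vocabulary, outdir / "vocabulary.txt")
    Path(outdir / "encounter_ids.txt").write_text(
        "\n".join(tm.encounter_ids) + "\n")


def sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, config: dict,
                   inputs: Optional[Sequence] = None) -> None:
    manifest = {
        "config": config,
        "phenofactor_version": __version__,
        "input_checksums": {str(p): sha256(p) for p in (inputs or [])},
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
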