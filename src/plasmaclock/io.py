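"""Readers and writers for the formats the pipeline touches.

Cohorts travel as two/three CSV (or TSV) tables aligned by explicit IDs,
pathway collections as standard GMT, fitted clocks as versioned JSON.
Readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortSpec, GroundTruth, PathwayCollection, ProteomicCohort

logger = logging.getLogger("plasmaclock")

CLOCK_SCHEMA_VERSION = 1

__all__ = [
    "CohortFormatError",
    "DuplicateIDError",
    "DimensionMismatchError",
    "GMTParseError",
    "ClockSchemaError",
    "read_cohort_table",
    "write_cohort_table",
    "read_gmt",
    "write_gmt",
    "write_clock_model",
    "read_clock_model",
    "write_ground_truth",
    "read_ground_truth",
    "write_spec",
    "read_spec",
]


class CohortFormatError(ValueError):
    """Malformed cohort tables."""


class DuplicateIDError(CohortFormatError):
    """Duplicated subject or analyte identifiers."""


class DimensionMismatchError(CohortFormatError):
    """Matrix and metadata tables disagree on subjects or analytes."""


class GMTParseError(ValueError):
    """Malformed GMT line; the message carries the line number."""


class ClockSchemaError(ValueError):
    """Serialized clock has an unsupported schema or violates invariants."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def write_cohort_table(cohort: ProteomicCohort, prefix: str | Path) -> dict[str, Path]:
    """Write matrix, subject metadata and analyte metadata next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_name(prefix.name + ".matrix.csv"),
        "subjects": prefix.with_name(prefix.name + ".subjects.csv"),
        "analytes": prefix.with_name(prefix.name + ".analytes.csv"),
    }
    cohort.intensities.to_csv(paths["matrix"])
    cohort.subject_meta.to_csv(paths["subjects"])
    cohort.analyte_meta.to_csv(paths["analytes"])
    return paths


def read_cohort_table(
    matrix: str | Path, subjects: str | Path, analytes: str | Path
) -> ProteomicCohort:
    """Read and validate a cohort; alignment is by explicit IDs, never position."""
    matrix, subjects, analytes = Path(matrix), Path(subjects), Path(analytes)
    # pandas mangles duplicated header names, so check the raw header first
    with open(matrix, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n\r").split(_sep_for(matrix))[1:]
    if len(header) != len(set(header)):
        seen: set[str] = set()
        dups = sorted({h for h in header if h in seen or seen.add(h)})
        raise DuplicateIDError(f"duplicated analyte ids in matrix header: {dups[:5]}")
    intens = pd.read_csv(matrix, sep=_sep_for(matrix), index_col=0)
    smeta = pd.read_csv(subjects, sep=_sep_for(subjects), index_col=0)
    ameta = pd.read_csv(analytes, sep=_sep_for(analytes), index_col=0)
    for name, idx in (
        ("subject ids in matrix", intens.index),
        ("analyte ids in matrix", intens.columns),
        ("subject ids in metadata", smeta.index),
        ("analyte ids in metadata", ameta.index),
    ):
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise DuplicateIDError(f"duplicated {name}: {dups}")
    if set(intens.index) != set(smeta.index):
        missing = set(intens.index).symmetric_difference(smeta.index)
        raise DimensionMismatchError(
            f"matrix and subject metadata disagree on subjects: {sorted(missing)[:5]}"
        )
    if set(intens.columns) != set(ameta.index):
        missing = set(intens.columns).symmetric_difference(ameta.index)
        raise DimensionMismatchError(
            f"matrix and analyte metadata disagree on analytes: {sorted(missing)[:5]}"
        )
    vals = intens.to_numpy()
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise CohortFormatError("intensities must be finite and strictly positive")
    # align metadata to matrix order
    cohort = ProteomicCohort(
        intens, smeta.loc[intens.index], ameta.loc[intens.columns]
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: name <TAB> description <TAB> member [<TAB> member ...]."""
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise GMTParseError(f"{path}: line {lineno}: pathway {name!r} has no members")
            if name in entries:
                raise GMTParseError(f"{path}: line {lineno}: duplicate pathway id {name!r}")
            entries[name] = (desc, members)
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (desc, members) in collection.entries.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# clock JSON
# ---------------------------------------------------------------------------

def write_clock_model(model, path: str | Path) -> None:
    """Serialize a fitted clock (see clock.ClockModel) to versioned JSON."""
    if model.standardization is None:
        raise ValueError("model carries no standardization parameters; cannot serialize")
    std = model.standardization
    payload = {
        "schema_version": CLOCK_SCHEMA_VERSION,
        "alpha": model.alpha,
        "lambda": model.lam,
        "lambda_path": list(map(float, model.lambda_path)),
        "intercept": float(model.intercept),
        "coefficients": {k: float(v) for k, v in model.weights.items()},
        "standardization": {
            k: [float(std.means[k]), float(std.sds[k])] for k in model.weights.index
        },
        "training": {
            "n": int(model.n_train),
            "seed": model.seed,
            "split_fraction": model.split_fraction,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_clock_model(path: str | Path):
    """Read a serialized clock back into a ClockModel; validates invariants."""
    from .clock import ClockModel, StandardizationParams

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != CLOCK_SCHEMA_VERSION:
        raise ClockSchemaError(
            f"unsupported clock schema_version {version!r}; expected {CLOCK_SCHEMA_VERSION}"
        )
    coefs = payload["coefficients"]
    std = payload["standardization"]
    if set(coefs) != set(std):
        raise ClockSchemaError("coefficient and standardization maps have different key sets")
    feats = list(coefs.keys())
    means = pd.Series({k: std[k][0] for k in feats})
    sds = pd.Series({k: std[k][1] for k in feats})
    if (sds <= 0).any():
        bad = sds.index[sds <= 0].tolist()[:5]
        raise ClockSchemaError(f"standardization sd must be > 0; offending analytes: {bad}")
    training = payload.get("training", {})
    return ClockModel(
        alpha=float(payload["alpha"]),
        lam=float(payload["lambda"]),
        lambda_path=np.asarray(payload["lambda_path"], dtype=float),
        intercept=float(payload["intercept"]),
        weights=pd.Series(coefs, index=feats, dtype=float),
        standardization=StandardizationParams(means=means, sds=sds),
        n_train=int(training.get("n", 0)),
        seed=training.get("seed"),
        split_fraction=training.get("split_fraction"),
    )


# ---------------------------------------------------------------------------
# ground truth & spec round-trips
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    tbl = truth.table.copy()
    tbl.attrs = {}
    tbl.insert(0, "age_center", truth.age_center)
    tbl.to_csv(path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    tbl = pd.read_csv(path, index_col=0)
    center = float(tbl.pop("age_center").iloc[0])
    tbl["informative"] = tbl["informative"].astype(bool)
    return GroundTruth(tbl, age_center=center)


def write_spec(spec: CohortSpec, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in spec.__dict__.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_spec(path: str | Path) -> CohortSpec:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("age_range", "beta_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    spec = CohortSpec(**data)
    spec.validate()
    return spec
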