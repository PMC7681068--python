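"""Synthetic plasma-proteome aging cohorts with known ground truth.

Emulates SOMAscan-style subject x analyte intensity matrices (relative
fluorescence units, RFU) in which a known subset of analytes drifts
linearly with age on the log10 scale:

    log10(x_ip) = mu_p + beta_p * (age_i - a0) + gamma_p * sex_i + eps_ip

with eps_ip ~ Normal(0, sigma_p^2) and a0 the expected mean age of the
sampling distribution.  Every stochastic operation is driven by an explicit
seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("plasmaclock")

__all__ = [
    "CohortSpec",
    "ProteomicCohort",
    "GroundTruth",
    "PathwayCollection",
    "SpecValidationError",
    "generate_cohort",
    "resample_cohort",
    "inject_aging_shift",
    "apply_platform_mask",
    "generate_pathway_collection",
]


class SpecValidationError(ValueError):
    """A cohort specification field is out of range; the message names it."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the reference study conditions: ~3000 subjects aged
    18-76, 3000 analytes of which 15% carry a true age trend, 75.84% of
    trends increasing, per-year log10 coefficients spanning the printed
    extremes [3.24e-4, 1.64e-2], and homoscedastic log10 noise of 0.05.
    """

    n_subjects: int = 3000
    n_analytes: int = 3000
    age_range: tuple[float, float] = (18.0, 76.0)
    frac_informative: float = 0.15
    frac_increasing: float = 0.7584
    beta_range: tuple[float, float] = (3.24e-4, 1.64e-2)
    noise_sd: float = 0.05
    sex_effect_sd: float = 0.0
    baseline_mean: float = 3.0
    baseline_sd: float = 0.5
    age_distribution: str = "uniform"  # "uniform" or "triangular"
    triangular_median: float = 45.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise SpecValidationError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if self.n_analytes < 1:
            raise SpecValidationError(f"n_analytes must be >= 1, got {self.n_analytes}")
        lo, hi = self.age_range
        if not lo < hi:
            raise SpecValidationError(f"age_range must satisfy min < max, got {self.age_range}")
        for name in ("frac_informative", "frac_increasing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must lie in [0, 1], got {v}")
        blo, bhi = self.beta_range
        if not (0.0 < blo <= bhi):
            raise SpecValidationError(
                f"beta_range bounds must be positive and ordered, got {self.beta_range}"
            )
        if self.noise_sd < 0:
            raise SpecValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sex_effect_sd < 0:
            raise SpecValidationError(f"sex_effect_sd must be >= 0, got {self.sex_effect_sd}")
        if self.age_distribution not in ("uniform", "triangular"):
            raise SpecValidationError(
                f"age_distribution must be 'uniform' or 'triangular', got {self.age_distribution!r}"
            )
        if self.age_distribution == "triangular" and not lo < self.triangular_median < hi:
            raise SpecValidationError(
                f"triangular_median must lie inside age_range, got {self.triangular_median}"
            )

    def age_center(self) -> float:
        """Expected mean age of the sampling distribution (the generative a0)."""
        lo, hi = self.age_range
        if self.age_distribution == "uniform":
            return 0.5 * (lo + hi)
        return (lo + self.triangular_mode() + hi) / 3.0

    def triangular_mode(self) -> float:
        """Mode c of Triangular(lo, c, hi) whose median equals triangular_median."""
        lo, hi = self.age_range
        m = self.triangular_median
        c_left = lo + 2.0 * (m - lo) ** 2 / (hi - lo)
        if m <= c_left:
            return c_left
        return hi - 2.0 * (hi - m) ** 2 / (hi - lo)


@dataclass
class ProteomicCohort:
    """Subject x analyte intensity matrix with subject and analyte metadata.

    ``intensities`` is indexed by subject_id with analyte_id columns;
    ``subject_meta`` carries age (years), sex (0/1) and a group label;
    ``analyte_meta`` carries protein_id and gene_symbol per analyte.
    """

    intensities: pd.DataFrame
    subject_meta: pd.DataFrame
    analyte_meta: pd.DataFrame

    def validate(self) -> None:
        if not self.intensities.index.equals(self.subject_meta.index):
            raise ValueError("intensity rows and subject_meta rows disagree")
        if not self.intensities.columns.equals(self.analyte_meta.index):
            raise ValueError("intensity columns and analyte_meta rows disagree")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate analyte ids")
        vals = self.intensities.to_numpy()
        if vals.size and not (vals > 0).all():
            raise ValueError("intensities must be strictly positive (log10 must be defined)")

    @property
    def n_subjects(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.intensities.shape[1]

    @property
    def ages(self) -> pd.Series:
        return self.subject_meta["age"]

    def log10(self) -> pd.DataFrame:
        return np.log10(self.intensities)

    def copy(self) -> "ProteomicCohort":
        return ProteomicCohort(
            self.intensities.copy(), self.subject_meta.copy(), self.analyte_meta.copy()
        )


@dataclass
class GroundTruth:
    """Per-analyte generative parameters of a synthetic cohort.

    ``table`` is indexed by analyte_id with columns true_beta (per-year
    log10 slope), informative (bool), direction (-1/0/+1), baseline (mu),
    sex_effect (gamma) and noise_sd (sigma).  ``age_center`` is the a0 the
    cohort was generated around, kept so that independent cohorts can be
    resampled from the same generative line.
    """

    table: pd.DataFrame
    age_center: float

    @property
    def true_beta(self) -> pd.Series:
        return self.table["true_beta"]

    @property
    def informative_flag(self) -> pd.Series:
        return self.table["informative"]

    @property
    def true_direction(self) -> pd.Series:
        return self.table["direction"]

    @property
    def informative_ids(self) -> list[str]:
        return list(self.table.index[self.table["informative"]])


@dataclass
class PathwayCollection:
    """Ordered mapping pathway_id -> (description, set of member ids)."""

    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.entries[pathway_id][1]

    def description(self, pathway_id: str) -> str:
        return self.entries[pathway_id][0]

    def sizes(self) -> dict[str, int]:
        return {pid: len(mem) for pid, (_, mem) in self.entries.items()}

    def validate(self) -> None:
        for pid, (_, members) in self.entries.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        return rng.uniform(lo, hi, spec.n_subjects)
    return rng.triangular(lo, spec.triangular_mode(), hi, spec.n_subjects)


def generate_cohort(spec: CohortSpec) -> tuple[ProteomicCohort, GroundTruth]:
    """Draw a cohort and its ground truth from the generative model.

    Exactly ``round(frac_informative * n_analytes)`` analytes receive a
    nonzero per-year log10 slope; of those, a ``frac_increasing`` share
    (rounded) is positive.  Slope magnitudes are log-uniform over
    ``beta_range``.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_analytes

    ages = _sample_ages(spec, rng)
    sex = rng.integers(0, 2, n)

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, p)
    n_inf = int(round(spec.frac_informative * p))
    inf_idx = rng.choice(p, size=n_inf, replace=False) if n_inf else np.array([], dtype=int)
    blo, bhi = spec.beta_range
    mags = 10.0 ** rng.uniform(math.log10(blo), math.log10(bhi), n_inf)
    n_pos = int(round(spec.frac_increasing * n_inf))
    signs = np.full(n_inf, -1.0)
    if n_inf:
        pos_slots = rng.choice(n_inf, size=n_pos, replace=False) if n_pos else np.array([], dtype=int)
        signs[pos_slots] = 1.0
    beta = np.zeros(p)
    beta[inf_idx] = signs * mags
    gamma = rng.normal(0.0, spec.sex_effect_sd, p) if spec.sex_effect_sd > 0 else np.zeros(p)

    a0 = spec.age_center()
    log10x = (
        mu[None, :]
        + np.outer(ages - a0, beta)
        + np.outer(sex, gamma)
    )
    if spec.noise_sd > 0:
        log10x = log10x + rng.normal(0.0, spec.noise_sd, (n, p))

    subject_ids = [f"S{i:05d}" for i in range(n)]
    analyte_ids = [f"A{j:05d}" for j in range(p)]
    intensities = pd.DataFrame(10.0 ** log10x, index=subject_ids, columns=analyte_ids)
    intensities.index.name = "subject_id"
    intensities.columns.name = "analyte_id"

    subject_meta = pd.DataFrame(
        {"age": ages, "sex": sex, "group": "none"},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    analyte_meta = pd.DataFrame(
        {
            "protein_id": [f"P{j:05d}" for j in range(p)],
            "gene_symbol": [f"G{j:05d}" for j in range(p)],
        },
        index=pd.Index(analyte_ids, name="analyte_id"),
    )

    informative = np.zeros(p, dtype=bool)
    informative[inf_idx] = True
    truth_table = pd.DataFrame(
        {
            "true_beta": beta,
            "informative": informative,
            "direction": np.sign(beta).astype(int),
            "baseline": mu,
            "sex_effect": gamma,
            "noise_sd": spec.noise_sd,
        },
        index=pd.Index(analyte_ids, name="analyte_id"),
    )

    cohort = ProteomicCohort(intensities, subject_meta, analyte_meta)
    cohort.validate()
    truth = GroundTruth(truth_table, age_center=a0)
    logger.info(
        "generated cohort: n=%d subjects, p=%d analytes, %d informative, seed=%d",
        n, p, n_inf, spec.seed,
    )
    return cohort, truth


def resample_cohort(
    spec: CohortSpec,
    truth: GroundTruth,
    seed: int,
    n_subjects: int | None = None,
) -> ProteomicCohort:
    """Draw a new, independent set of subjects from a frozen ground truth.

    Analyte parameters (mu, beta, gamma, sigma) and the generative age
    center come from ``truth``; ages, sexes and noise are redrawn.  Used to
    build validation cohorts that share the generative process of a
    training cohort.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects if n_subjects is None else int(n_subjects)
    tbl = truth.table
    p = len(tbl)
    spec_n = replace(spec, n_subjects=n)
    ages = _sample_ages(spec_n, rng)
    sex = rng.integers(0, 2, n)
    log10x = (
        tbl["baseline"].to_numpy()[None, :]
        + np.outer(ages - truth.age_center, tbl["true_beta"].to_numpy())
        + np.outer(sex, tbl["sex_effect"].to_numpy())
    )
    sigma = tbl["noise_sd"].to_numpy()
    if (sigma > 0).any():
        log10x = log10x + rng.normal(0.0, 1.0, (n, p)) * sigma[None, :]
    subject_ids = [f"R{i:05d}" for i in range(n)]
    intensities = pd.DataFrame(10.0 ** log10x, index=subject_ids, columns=tbl.index)
    intensities.index.name = "subject_id"
    subject_meta = pd.DataFrame(
        {"age": ages, "sex": sex, "group": "none"},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    analyte_meta = pd.DataFrame(
        {
            "protein_id": [f"P{j:05d}" for j in range(p)],
            "gene_symbol": [f"G{j:05d}" for j in range(p)],
        },
        index=tbl.index.copy(),
    )
    cohort = ProteomicCohort(intensities, subject_meta, analyte_meta)
    cohort.validate()
    return cohort


def inject_aging_shift(
    cohort: ProteomicCohort,
    truth: GroundTruth,
    subject_ids: Sequence[str],
    delta_years: float,
) -> ProteomicCohort:
    """Shift selected subjects' proteomes along the aging axis.

    Each analyte's log10 value moves by ``true_beta * delta_years`` for the
    selected subjects, emulating a group whose proteome looks ``delta_years``
    older (or younger) than its chronological age.  Ages are untouched.
    """
    unknown = set(subject_ids) - set(cohort.intensities.index)
    if unknown:
        raise KeyError(f"unknown subject ids: {sorted(unknown)[:5]}")
    out = cohort.copy()
    beta = truth.table.loc[cohort.intensities.columns, "true_beta"].to_numpy()
    factor = 10.0 ** (beta * delta_years)
    ids = list(subject_ids)
    out.intensities.loc[ids] = out.intensities.loc[ids].to_numpy() * factor[None, :]
    return out


def apply_platform_mask(
    cohort: ProteomicCohort, keep_analytes: Sequence[str]
) -> ProteomicCohort:
    """Restrict the cohort to an analyte panel (order preserved)."""
    keep = list(keep_analytes)
    if not keep:
        raise ValueError("keep_analytes must be non-empty")
    missing = set(keep) - set(cohort.intensities.columns)
    if missing:
        raise KeyError(f"unknown analyte ids: {sorted(missing)[:5]}")
    masked = ProteomicCohort(
        cohort.intensities.loc[:, keep].copy(),
        cohort.subject_meta.copy(),
        cohort.analyte_meta.loc[keep].copy(),
    )
    masked.validate()
    return masked


def generate_pathway_collection(
    analyte_meta: pd.DataFrame,
    truth: GroundTruth,
    n_pathways: int,
    size_range: tuple[int, int],
    n_enriched: int,
    seed: int,
    enriched_informative_frac: float = 0.8,
) -> PathwayCollection:
    """Synthesize a pathway collection over the cohort's analytes.

    The first ``n_enriched`` pathways draw ~``enriched_informative_frac`` of
    their members from informative analytes; the rest are uniform draws.
    """
    lo, hi = size_range
    n_analytes = len(analyte_meta)
    if not 1 <= lo <= hi:
        raise ValueError(f"size_range must satisfy 1 <= min <= max, got {size_range}")
    if hi > n_analytes:
        raise ValueError(f"size_range max {hi} exceeds analyte count {n_analytes}")
    if n_enriched > n_pathways:
        raise ValueError("n_enriched cannot exceed n_pathways")
    rng = np.random.default_rng(seed)
    all_ids = np.asarray(analyte_meta.index)
    inf_ids = np.asarray(truth.table.index[truth.table["informative"]])
    other_ids = np.asarray(truth.table.index[~truth.table["informative"]])
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched and len(inf_ids):
            k_inf = min(int(round(enriched_informative_frac * size)), len(inf_ids))
            k_oth = min(size - k_inf, len(other_ids))
            members = np.concatenate(
                [
                    rng.choice(inf_ids, size=k_inf, replace=False),
                    rng.choice(other_ids, size=k_oth, replace=False)
                    if k_oth
                    else np.array([], dtype=inf_ids.dtype),
                ]
            )
            desc = "synthetic enriched pathway"
        else:
            members = rng.choice(all_ids, size=size, replace=False)
            desc = "synthetic pathway"
        entries[f"PW{i:04d}"] = (desc, frozenset(members.tolist()))
    coll = PathwayCollection(entries)
    coll.validate()
    return coll
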