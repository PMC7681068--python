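"""Pathway-restricted clock screening.

Each pathway in a collection is resolved to the analytes the cohort
measures, pathways with too few analytes are excluded, and a ridge plus a
LASSO clock is fitted per pathway with one shared train/test split so that
test-set performance is comparable across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .clock import ClockEvaluation, TrainTestSplit, build_clock, split_train_test
from .simulate import PathwayCollection, ProteomicCohort

logger = logging.getLogger("plasmaclock")

__all__ = [
    "PathwayClockResult",
    "resolve_collection",
    "screen_pathways",
    "rank_clocks",
    "results_table",
]


@dataclass
class PathwayClockResult:
    pathway_id: str
    n_analytes_full: int
    n_analytes_sparse: int
    evaluations: dict[tuple[str, str], ClockEvaluation] = field(default_factory=dict)
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def resolve_collection(
    collection: PathwayCollection, analyte_meta: pd.DataFrame
) -> dict[str, list[str]]:
    """Map pathway members (analyte ids or gene symbols) to analyte ids.

    Gene symbols resolve through analyte_meta; when several analytes carry
    one symbol the first annotation listed wins.  Unmapped members are
    dropped with a logged count.
    """
    analyte_ids = set(analyte_meta.index)
    by_symbol: dict[str, str] = {}
    if "gene_symbol" in analyte_meta.columns:
        for aid, sym in analyte_meta["gene_symbol"].items():
            if pd.notna(sym) and sym not in by_symbol:
                by_symbol[sym] = aid  # first annotation wins
    resolved: dict[str, list[str]] = {}
    n_dropped = 0
    for pid in collection:
        hits: list[str] = []
        seen: set[str] = set()
        for member in sorted(collection.members(pid)):
            aid = member if member in analyte_ids else by_symbol.get(member)
            if aid is None:
                n_dropped += 1
            elif aid not in seen:
                seen.add(aid)
                hits.append(aid)
        resolved[pid] = hits
    if n_dropped:
        logger.info("dropped %d pathway members not measured by the panel", n_dropped)
    return resolved


def screen_pathways(
    cohort: ProteomicCohort,
    collection: PathwayCollection,
    min_analytes: int = 2,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    split: TrainTestSplit | None = None,
    n_lambda: int = 100,
    n_folds: int = 10,
) -> tuple[list[PathwayClockResult], list[str]]:
    """Fit ridge and LASSO clocks per pathway; returns (results, excluded ids).

    Pathways mapping to fewer than ``min_analytes`` measured analytes are
    excluded.  A fit error marks that pathway failed rather than aborting
    the screen.
    """
    resolved = resolve_collection(collection, cohort.analyte_meta)
    if split is None:
        split = split_train_test(cohort, fraction=fraction, seed=seed)
    excluded = [pid for pid, feats in resolved.items() if len(feats) < min_analytes]
    if excluded:
        logger.info(
            "excluded %d/%d pathways with < %d measured analytes",
            len(excluded), len(resolved), min_analytes,
        )
    results: list[PathwayClockResult] = []
    for pid, feats in resolved.items():
        if len(feats) < min_analytes:
            continue
        res = PathwayClockResult(pathway_id=pid, n_analytes_full=len(feats), n_analytes_sparse=0)
        try:
            for name, alpha in (("ridge", 0.0), ("lasso", 1.0)):
                fit = build_clock(
                    cohort, features=feats, alpha=alpha, seed=seed, split=split,
                    n_lambda=n_lambda, n_folds=n_folds,
                )
                res.evaluations[(name, "train")] = fit.train_eval
                res.evaluations[(name, "test")] = fit.test_eval
                if name == "lasso":
                    res.n_analytes_sparse = fit.model.active_set_size
        except Exception as exc:  # a bad pathway must not kill the screen
            res.error = f"{type(exc).__name__}: {exc}"
            logger.warning("pathway %s failed: %s", pid, res.error)
        results.append(res)
    return results, excluded


def rank_clocks(
    results: list[PathwayClockResult],
    by: str = "test_r",
    top_k: int | None = None,
    model: str = "ridge",
) -> list[PathwayClockResult]:
    """Stable ranking by test r (descending) or test MAE (ascending).

    Ties break toward fewer analytes, then pathway id.  Failed pathways are
    dropped from the ranking.
    """
    if by not in ("test_r", "test_mae"):
        raise ValueError(f"unknown sort key {by!r}; use 'test_r' or 'test_mae'")
    if not results:
        raise ValueError("no pathway results to rank")
    ok = [r for r in results if not r.failed and (model, "test") in r.evaluations]

    def key(res: PathwayClockResult):
        ev = res.evaluations[(model, "test")]
        primary = -ev.r if by == "test_r" else ev.mae
        return (primary, res.n_analytes_full, res.pathway_id)

    ranked = sorted(ok, key=key)
    return ranked if top_k is None else ranked[:top_k]


def results_table(results: list[PathwayClockResult]) -> pd.DataFrame:
    """Flatten screen results to one row per pathway."""
    rows = []
    for r in results:
        row: dict = {
            "pathway_id": r.pathway_id,
            "n_analytes_full": r.n_analytes_full,
            "n_analytes_sparse": r.n_analytes_sparse,
            "error": r.error or "",
        }
        for (model, split_label), ev in r.evaluations.items():
            row[f"{model}_{split_label}_r"] = ev.r
            row[f"{model}_{split_label}_mae"] = ev.mae
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway_id")
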