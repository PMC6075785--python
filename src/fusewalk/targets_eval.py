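"""Top-gene selection, drug-target mapping, synergy filtering, and ROC evaluation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from fusewalk.enrichment import RankedGeneList
from fusewalk.errors import InvalidInputError

__all__ = [
    "DrugTargetTable",
    "BenchmarkSet",
    "select_top_fraction",
    "map_drug_targets",
    "prioritize_synergistic_targets",
    "roc_auc",
]


class DrugTargetTable:
    """Unique (drug, target gene) pairs."""

    def __init__(self, pairs: Iterable[Tuple[str, str]], source: str = ""):
        self.source = source
        self._targets: Dict[str, Set[str]] = {}
        seen = set()
        for drug, gene in pairs:
            if not drug or not gene:
                raise InvalidInputError("empty drug or gene in drug-target table")
            if (drug, gene) in seen:
                continue
            seen.add((drug, gene))
            self._targets.setdefault(drug, set()).add(gene)

    def drugs(self) -> List[str]:
        return list(self._targets)

    def targets_of(self, drug: str) -> Set[str]:
        return set(self._targets.get(drug, set()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._targets.values())


@dataclass
class BenchmarkSet:
    """Positive genes for ROC evaluation; negatives = rest of the ranking."""

    name: str
    positives: Set[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.positives = set(self.positives)
        if not self.positives:
            raise InvalidInputError(f"benchmark set {self.name!r} is empty")


def select_top_fraction(ranked: RankedGeneList, fraction: float) -> List[str]:
    """First ceil(fraction * N) genes of the ranking (order preserved)."""
    if not (0.0 < fraction <= 1.0):
        raise InvalidInputError(f"fraction outside (0, 1]: {fraction}")
    k = math.ceil(fraction * len(ranked))
    return list(ranked.genes[:k])


def map_drug_targets(
    top: Iterable[str],
    table: DrugTargetTable,
    ranked: Optional[RankedGeneList] = None,
) -> pd.DataFrame:
    """Per-drug hit report against the top gene set.

    Columns: drug, n_targets, hits (comma-joined targets in *top*),
    n_hits, best_rank (1-based rank of the best-ranked hit when *ranked*
    is given), mappable.  Sorted by hit count desc then best rank asc.
    """
    top = list(top)
    top_set = set(top)
    order = {g: i + 1 for i, g in enumerate(ranked.genes)} if ranked is not None else {
        g: i + 1 for i, g in enumerate(top)
    }
    rows = []
    for drug in sorted(table.drugs()):
        targets = table.targets_of(drug)
        hits = sorted(targets & top_set, key=lambda g: order.get(g, math.inf))
        best = order.get(hits[0], math.inf) if hits else math.inf
        rows.append(
            {
                "drug": drug,
                "n_targets": len(targets),
                "hits": ",".join(hits),
                "n_hits": len(hits),
                "best_rank": best,
                "mappable": len(hits) > 0,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            by=["n_hits", "best_rank", "drug"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df["best_rank"] = df["best_rank"].replace(math.inf, np.nan)
    return df


def prioritize_synergistic_targets(
    ranked: RankedGeneList,
    de_table: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    top_fraction: float = 0.10,
) -> Set[str]:
    """Genes up-regulated past the fold-change and p cutoffs AND in the top fraction.

    *de_table* is indexed by gene with columns ``fold_change`` and ``p``.
    Top-fraction genes missing from the table are simply excluded; the
    CLI reports them separately.
    """
    if "fold_change" not in de_table.columns or "p" not in de_table.columns:
        raise InvalidInputError("de_table needs 'fold_change' and 'p' columns")
    top = set(select_top_fraction(ranked, top_fraction))
    covered = top & set(de_table.index)
    sub = de_table.loc[sorted(covered)]
    keep = sub[(sub["fold_change"] > fc_threshold) & (sub["p"] < p_threshold)]
    return set(keep.index)


def roc_auc(
    ranked: RankedGeneList,
    benchmark: BenchmarkSet,
    exclude: Iterable[str] = (),
) -> Tuple[pd.DataFrame, float]:
    """ROC curve and AUC of the score ranking against a benchmark set.

    Positives are benchmark genes present in the ranking; every other
    ranked gene is a negative.  Tied scores are handled by the
    probabilistic (Mann-Whitney) convention of ``roc_auc_score``.
    Genes in *exclude* (e.g. the fusion's parents) are removed from the
    universe first.
    """
    exclude = set(exclude)
    mask = np.array([g not in exclude for g in ranked.genes])
    genes = [g for g in ranked.genes if g not in exclude]
    scores = ranked.scores[mask]
    labels = np.array([g in benchmark.positives for g in genes], dtype=int)
    if labels.sum() == 0:
        raise InvalidInputError(f"no positive of {benchmark.name!r} in the ranked universe")
    if labels.sum() == len(labels):
        raise InvalidInputError(f"benchmark {benchmark.name!r} covers the whole universe")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, auc
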