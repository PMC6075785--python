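"""Expression-based deregulation scoring and p-value combination.

Differential expression between fusion-positive (or treated) and control
samples yields a second gene ranking; the same running-sum enrichment then
measures pathway deregulation.  Per pathway, the association and
deregulation p-values are combined with the truncated product method:
only p-values at or below the truncation threshold tau enter the product
score W, whose null tail probability has a closed form for two p-values.

The closed form assumes the two p-values are independent; shared pathway
membership violates that in general and the result is used as a ranking
statistic, not a calibrated error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from fusewalk.enrichment import (
    EnrichmentConfig,
    PathwayCollection,
    RankedGeneList,
    association_analysis,
)
from fusewalk.errors import InvalidInputError

__all__ = [
    "ExpressionDataset",
    "CombinedPathwayResult",
    "differential_ranking",
    "deregulation_analysis",
    "truncated_product_W",
    "truncated_product_pvalue",
    "combine_pathway_results",
]

DEFAULT_TAU = 0.01


class ExpressionDataset:
    """Gene x sample expression matrix with two-group sample labels.

    Values are assumed to be on a log-like scale suitable for a
    two-sample t statistic.  ``group_of`` maps every sample (column) to
    one of exactly two group labels; the *case* group is the one listed
    first in sorted order unless ``case_group`` is given.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        group_of: Mapping[str, str],
        case_group: Optional[str] = None,
    ):
        if matrix.index.has_duplicates:
            raise InvalidInputError("duplicate gene rows in expression matrix")
        missing = [s for s in matrix.columns if s not in group_of]
        if missing:
            raise InvalidInputError(f"samples without a group label: {missing}")
        groups = sorted({group_of[s] for s in matrix.columns})
        if len(groups) != 2:
            raise InvalidInputError(f"expected exactly 2 groups, got {groups}")
        self.matrix = matrix.astype(float)
        self.group_of = dict(group_of)
        self.case_group = case_group if case_group is not None else groups[0]
        if self.case_group not in groups:
            raise InvalidInputError(f"case group {self.case_group!r} not among {groups}")
        self.control_group = next(g for g in groups if g != self.case_group)
        self.case_samples = [s for s in matrix.columns if group_of[s] == self.case_group]
        self.control_samples = [s for s in matrix.columns if group_of[s] == self.control_group]
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise InvalidInputError("each group needs >= 2 samples for the t statistic")

    @property
    def genes(self) -> List[str]:
        return list(self.matrix.index)


def differential_table(data: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Welch t-test (case vs control) on the matrix values.

    Returns columns ``effect`` (case mean - control mean), ``t``, ``p``
    and ``zero_variance``.  Genes with zero variance in both groups get
    p = 1 and effect 0, flagged rather than dropped.
    """
    case = data.matrix[data.case_samples].to_numpy()
    ctrl = data.matrix[data.control_samples].to_numpy()
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    effect = np.where(zero_var, 0.0, effect)
    p = np.nan_to_num(p, nan=1.0)
    t = np.nan_to_num(t, nan=0.0)
    return pd.DataFrame(
        {"effect": effect, "t": t, "p": p, "zero_variance": zero_var},
        index=data.matrix.index,
    )


def differential_ranking(data: ExpressionDataset) -> RankedGeneList:
    """Rank genes by signed -log10(p), sign from the effect direction."""
    table = differential_table(data)
    with np.errstate(divide="ignore"):
        key = -np.log10(np.maximum(table["p"].to_numpy(), 1e-300))
    key = np.sign(table["effect"].to_numpy()) * key
    ordered = sorted(zip(table.index, key), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in ordered]
    vals = np.array([v for _, v in ordered])
    tied = set()
    for i in range(len(vals) - 1):
        if vals[i] == vals[i + 1]:
            tied.update((genes[i], genes[i + 1]))
    return RankedGeneList(genes=genes, scores=vals, tied_genes=tied)


def deregulation_analysis(
    data: ExpressionDataset,
    collection: PathwayCollection,
    config: Optional[EnrichmentConfig] = None,
) -> pd.DataFrame:
    """Enrichment of each pathway against the differential ranking."""
    return association_analysis(differential_ranking(data), collection, config)


def truncated_product_W(p1: float, p2: float, tau: float = DEFAULT_TAU) -> float:
    """Product of the p-values not exceeding *tau*; empty product is 1."""
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise InvalidInputError(f"p-value outside (0, 1]: {p}")
    if not (0.0 < tau < 1.0):
        raise InvalidInputError(f"tau outside (0, 1): {tau}")
    w = 1.0
    if p1 <= tau:
        w *= p1
    if p2 <= tau:
        w *= p2
    return w


def truncated_product_pvalue(w: float, tau: float = DEFAULT_TAU) -> float:
    """Null tail probability Pr(W <= w) for two independent uniform p-values.

    Conditions on the number k of p-values below tau:

        Pr(W <= w) = sum_{k=1,2} C(2,k) (1-tau)^(2-k) *
            ( w * sum_{s=0}^{k-1} (k ln tau - ln w)^s / s!   if w <= tau^k
              tau^k                                          if w >  tau^k )

    W == 1 (no p-value below tau) maps to 1 by convention.
    """
    if not (0.0 < w <= 1.0):
        raise InvalidInputError(f"W outside (0, 1]: {w}")
    if not (0.0 < tau < 1.0):
        raise InvalidInputError(f"tau outside (0, 1): {tau}")
    if w == 1.0:
        return 1.0
    ln_w = math.log(w)
    ln_tau = math.log(tau)
    total = 0.0
    for k in (1, 2):
        coef = math.comb(2, k) * (1.0 - tau) ** (2 - k)
        if w <= tau**k:
            # inner sum in log space: w * e^{s ln(k ln tau - ln w) - ln s!}
            x = k * ln_tau - ln_w  # >= 0 when w <= tau^k
            inner = sum(math.exp(s * math.log(x) - math.lgamma(s + 1)) if x > 0 else (1.0 if s == 0 else 0.0) for s in range(k))
            total += coef * w * inner
        else:
            total += coef * tau**k
    return min(total, 1.0)


@dataclass
class CombinedPathwayResult:
    pathway: str
    p_association: float
    p_deregulation: float
    W: float
    p_combined: float
    tau: float


def combine_pathway_results(
    assoc: pd.DataFrame,
    dereg: pd.DataFrame,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Join the two analyses on pathway name and combine their p-values.

    Pathways present in only one table are excluded from combination and
    listed in ``df.attrs["unmatched"]``.  Output is sorted ascending by
    ``p_combined`` (then pathway name) with a BH q-value column.
    """
    a = assoc.set_index("pathway")["p"]
    d = dereg.set_index("pathway")["p"]
    common = a.index.intersection(d.index)
    if len(common) == 0:
        raise InvalidInputError("no pathway appears in both analyses")
    unmatched = sorted(set(a.index).symmetric_difference(set(d.index)))
    rows = []
    for name in common:
        w = truncated_product_W(float(a[name]), float(d[name]), tau)
        rows.append(
            {
                "pathway": name,
                "p_association": float(a[name]),
                "p_deregulation": float(d[name]),
                "W": w,
                "p_combined": truncated_product_pvalue(w, tau),
                "tau": tau,
            }
        )
    df = pd.DataFrame(rows).sort_values(["p_combined", "pathway"]).reset_index(drop=True)
    df["q_combined"] = stats.false_discovery_control(df["p_combined"], method="bh")
    df.attrs["unmatched"] = unmatched
    return df
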