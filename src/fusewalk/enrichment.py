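"""Rank-based pathway enrichment over fusion-association scores.

Implements the classic running-sum enrichment statistic: walking down the
ranked gene list, members of a gene set increment the sum by their
weighted score share and non-members decrement it by 1/(N - N_hits); the
enrichment score (ES) is the signed maximum deviation from zero.
Significance comes from a gene-set permutation null (random sets of equal
size drawn from the ranked list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from fusewalk.errors import InvalidInputError
from fusewalk.propagation import ScoreVector

__all__ = [
    "RankedGeneList",
    "PathwayCollection",
    "EnrichmentResult",
    "EnrichmentConfig",
    "rank_genes",
    "enrichment_score",
    "gsea_pvalue",
    "association_analysis",
]


@dataclass
class RankedGeneList:
    """Genes ordered by descending score; ties broken lexicographically."""

    genes: List[str]
    scores: np.ndarray
    tied_genes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise InvalidInputError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        """0-based rank of *gene* (0 = best)."""
        return self.genes.index(gene)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(
            genes=list(reversed(self.genes)),
            scores=self.scores[::-1].copy(),
            tied_genes=set(self.tied_genes),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "score": self.scores,
                "rank": np.arange(1, len(self.genes) + 1),
                "tied": [g in self.tied_genes for g in self.genes],
            }
        )


class PathwayCollection:
    """Named, non-empty gene sets (GMT semantics); names unique."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Optional[Mapping[str, str]] = None,
        source: str = "",
    ):
        self._sets: Dict[str, frozenset] = {}
        self.descriptions: Dict[str, str] = {}
        self.source = source
        for name, members in sets.items():
            members = frozenset(members)
            if not name:
                raise InvalidInputError("empty pathway name")
            if not members:
                raise InvalidInputError(f"pathway {name!r} has no members")
            if name in self._sets:
                raise InvalidInputError(f"duplicate pathway name {name!r}")
            self._sets[name] = members
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def names(self) -> List[str]:
        return list(self._sets)

    def items(self):
        return self._sets.items()


@dataclass
class EnrichmentResult:
    pathway: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: List[str]


@dataclass
class EnrichmentConfig:
    """Settings shared by the association and deregulation analyses."""

    weight_exponent: float = 1.0
    n_perm: int = 10_000
    rng_seed: int = 0
    min_size: int = 10
    max_size: int = 500

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise InvalidInputError("n_perm must be >= 100")
        if self.min_size < 1 or self.max_size < self.min_size:
            raise InvalidInputError("invalid set-size filter bounds")


def rank_genes(scores: Union[ScoreVector, Mapping[str, float]]) -> RankedGeneList:
    """Order genes by descending score; ties broken by gene identifier."""
    mapping = scores.scores if isinstance(scores, ScoreVector) else dict(scores)
    if not mapping:
        raise InvalidInputError("cannot rank an empty score vector")
    ordered = sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in ordered]
    vals = np.array([v for _, v in ordered], dtype=float)
    tied: Set[str] = set()
    for i in range(len(vals) - 1):
        if vals[i] == vals[i + 1]:
            tied.add(genes[i])
            tied.add(genes[i + 1])
    return RankedGeneList(genes=genes, scores=vals, tied_genes=tied)


def _hit_weights(ranked: RankedGeneList, hit_mask: np.ndarray, weight_exponent: float) -> np.ndarray:
    w = np.abs(ranked.scores[hit_mask]) ** weight_exponent
    total = w.sum()
    if total == 0:
        # all hit scores zero: fall back to unweighted increments
        return np.full(hit_mask.sum(), 1.0 / hit_mask.sum())
    return w / total


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> Tuple[float, np.ndarray]:
    """Running-sum enrichment score of *gene_set* against *ranked*.

    Returns ``(es, profile)`` where ``profile[i]`` is the running sum
    after processing position ``i``.  The gene set is restricted to the
    ranked genes first; an empty intersection or a set covering the whole
    list is invalid.
    """
    members = set(gene_set) & set(ranked.genes)
    n = len(ranked)
    if not members:
        raise InvalidInputError("gene set does not intersect the ranked list")
    if len(members) == n:
        raise InvalidInputError("gene set covers the entire ranked list")
    hit_mask = np.array([g in members for g in ranked.genes])
    inc = _hit_weights(ranked, hit_mask, weight_exponent)
    miss_dec = 1.0 / (n - len(members))
    steps = np.where(hit_mask, 0.0, -miss_dec)
    steps[hit_mask] = inc
    profile = np.cumsum(steps)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


def leading_edge_genes(
    ranked: RankedGeneList, gene_set: Iterable[str], weight_exponent: float = 1.0
) -> List[str]:
    """Set members at or before (after, for negative ES) the extremum."""
    members = set(gene_set) & set(ranked.genes)
    es, profile = enrichment_score(ranked, members, weight_exponent)
    idx = int(np.argmax(np.abs(profile)))
    if es >= 0:
        return [g for g in ranked.genes[: idx + 1] if g in members]
    return [g for g in ranked.genes[idx:] if g in members]


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many permutations given sorted hit positions.

    ``positions``: (n_perm, m) 0-based sorted indices into the ranked
    list; ``weights``: length-n array of |score|^exponent.  The running
    sum only attains its extrema immediately before or after a hit, so
    each permutation needs O(m) work.
    """
    n_perm, m = positions.shape
    miss = 1.0 / (n - m)
    hw = weights[positions]
    totals = hw.sum(axis=1, keepdims=True)
    # degenerate all-zero weights: unweighted increments
    zero = (totals == 0).ravel()
    if zero.any():
        hw[zero] = 1.0
        totals = hw.sum(axis=1, keepdims=True)
    H = np.cumsum(hw, axis=1) / totals
    j = np.arange(m)
    misses_before = positions - j  # misses strictly before each hit
    after = H - misses_before * miss
    before = np.concatenate([np.zeros((n_perm, 1)), H[:, :-1]], axis=1) - misses_before * miss
    # interleave (before_j, after_j) so ties in |value| resolve to the
    # earliest list position, matching the full-scan argmax convention
    cand = np.empty((n_perm, 2 * m))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def _null_es(
    ranked: RankedGeneList,
    size: int,
    weight_exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight_exponent
    # draw n_perm random subsets of the given size
    positions = np.empty((n_perm, size), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=size, replace=False)
    positions.sort(axis=1)
    return _es_from_positions(positions, weights, n)


def _perm_pvalue(es_obs: float, null: np.ndarray) -> float:
    # condition on the ES sign and normalize by the same-sign null count
    # (standard GSEA convention); this keeps null p-values uniform on (0,1)
    # rather than piling up below 0.5
    if es_obs >= 0:
        same = null[null >= 0]
        hits = int((same >= es_obs).sum())
    else:
        same = null[null < 0]
        hits = int((same <= es_obs).sum())
    return (1 + hits) / (1 + len(same))


def _nes(es_obs: float, null: np.ndarray) -> float:
    same = null[null >= 0] if es_obs >= 0 else null[null < 0]
    if len(same) == 0:
        return float("nan")
    denom = np.abs(same).mean()
    return float(es_obs / denom) if denom > 0 else float("nan")


def gsea_pvalue(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> float:
    """Gene-set permutation p-value for one set (add-one estimator)."""
    if n_perm < 100:
        raise InvalidInputError("n_perm must be >= 100")
    members = set(gene_set) & set(ranked.genes)
    es, _ = enrichment_score(ranked, members, weight_exponent)
    rng = np.random.default_rng(rng_seed)
    null = _null_es(ranked, len(members), weight_exponent, n_perm, rng)
    return _perm_pvalue(es, null)


def association_analysis(
    scores: Union[ScoreVector, RankedGeneList, Mapping[str, float]],
    collection: PathwayCollection,
    config: Optional[EnrichmentConfig] = None,
) -> pd.DataFrame:
    """Permutation enrichment of every pathway against the ranking.

    Returns a frame with one row per retained pathway sorted by
    (p ascending, |ES| descending); skipped pathways and reasons are kept
    in ``df.attrs["skipped"]``.  Null ES distributions are shared across
    pathways of equal restricted size.
    """
    config = config or EnrichmentConfig()
    ranked = scores if isinstance(scores, RankedGeneList) else rank_genes(scores)
    universe = set(ranked.genes)
    rng = np.random.default_rng(config.rng_seed)

    restricted: Dict[str, Set[str]] = {}
    skipped: List[Tuple[str, str]] = []
    for name, members in collection.items():
        inter = set(members) & universe
        if not inter:
            skipped.append((name, "empty_intersection"))
        elif len(inter) == len(universe):
            skipped.append((name, "covers_universe"))
        elif not (config.min_size <= len(inter) <= config.max_size):
            skipped.append((name, f"size_{len(inter)}_outside_filter"))
        else:
            restricted[name] = inter
    if not restricted:
        raise InvalidInputError("all pathways were filtered out")

    null_by_size: Dict[int, np.ndarray] = {}
    for size in sorted({len(s) for s in restricted.values()}):
        null_by_size[size] = _null_es(
            ranked, size, config.weight_exponent, config.n_perm, rng
        )

    rows = []
    for name, members in restricted.items():
        es, profile = enrichment_score(ranked, members, config.weight_exponent)
        null = null_by_size[len(members)]
        idx = int(np.argmax(np.abs(profile)))
        if es >= 0:
            ledge = [g for g in ranked.genes[: idx + 1] if g in members]
        else:
            ledge = [g for g in ranked.genes[idx:] if g in members]
        rows.append(
            {
                "pathway": name,
                "size": len(members),
                "ES": es,
                "NES": _nes(es, null),
                "p": _perm_pvalue(es, null),
                "leading_edge": ",".join(ledge),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = false_discovery_control(df["p"], method="bh")
    df = df.sort_values(
        by=["p", "ES"], key=lambda s: s.abs() if s.name == "ES" else s,
        ascending=[True, False],
    ).reset_index(drop=True)
    df = df[["pathway", "size", "ES", "NES", "p", "q", "leading_edge"]]
    df.attrs["skipped"] = skipped
    return df
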