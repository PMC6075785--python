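"""Predict the molecular interaction partners a fusion inherits.

Two evidence channels:

* protein-protein: a PPI neighbor of either parent is kept iff some
  retained fusion domain and some domain annotated on the neighbor form a
  pair in the domain-domain interaction (DDI) catalog;
* protein-DNA: if the fusion retains at least one DNA-binding domain of a
  parent, that parent's transcriptional-regulation targets are inherited.

Candidates are restricted to the parents' existing neighbors — the method
decides which parental interactions are retained, never predicts new ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from fusewalk.errors import EmptySeedError
from fusewalk.fusion_model import DomainAnnotationTable, FusionSpec

__all__ = [
    "InteractionBundle",
    "PredictedPartners",
    "predict_ppi_partners",
    "predict_tf_targets",
    "predicted_partner_set",
]


def _canon(pair: Tuple[str, str]) -> Tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionBundle:
    """Evidence databases used for partner inference.

    ``ppi`` holds unordered gene pairs, ``ddi`` unordered domain-accession
    pairs (looked up symmetrically), ``tf_targets`` ordered
    ``(regulator, target)`` pairs.
    """

    ppi: Set[Tuple[str, str]]
    ddi: Set[Tuple[str, str]]
    tf_targets: Set[Tuple[str, str]]
    annotations: DomainAnnotationTable
    dna_binding_domains: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        self.ppi = {_canon(p) for p in self.ppi}
        self.ddi = {_canon(p) for p in self.ddi}
        self.tf_targets = set(self.tf_targets)
        self.dna_binding_domains = frozenset(self.dna_binding_domains)

    def ppi_neighbors(self, gene: str) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.ppi:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def has_ddi(self, d1: str, d2: str) -> bool:
        return _canon((d1, d2)) in self.ddi

    def targets_of(self, regulator: str) -> Set[str]:
        return {t for r, t in self.tf_targets if r == regulator}


@dataclass
class PredictedPartners:
    """Predicted interaction partners with per-partner evidence records.

    ``evidence`` maps each partner gene to a list of records: tuples
    ``("ddi", fusion_domain, partner_domain)`` for PPI support or
    ``("tf", parent)`` for inherited regulatory targets.
    """

    ppi_partners: Set[str] = field(default_factory=set)
    tf_target_genes: Set[str] = field(default_factory=set)
    evidence: Dict[str, List[tuple]] = field(default_factory=dict)
    excluded: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def seed_genes(self) -> Set[str]:
        return self.ppi_partners | self.tf_target_genes


def predict_ppi_partners(
    fusion: FusionSpec,
    bundle: InteractionBundle,
    *,
    keep_unannotated: bool = False,
) -> PredictedPartners:
    """Predict which parental PPI partners the fusion keeps.

    A candidate X (PPI neighbor of either parent) is retained iff a
    retained fusion domain pairs with a domain annotated on X in the DDI
    catalog.  Candidates without any domain annotation are dropped and
    recorded in ``excluded`` unless *keep_unannotated* is set.
    """
    result = PredictedPartners()
    retained = fusion.retained
    candidates: Set[str] = set()
    for parent in (fusion.parent5, fusion.parent3):
        neigh = bundle.ppi_neighbors(parent)
        if not neigh:
            warnings.warn(
                f"parent {parent!r} has no PPI neighbors in the network", stacklevel=2
            )
        candidates |= neigh
    candidates -= {fusion.parent5, fusion.parent3}

    for cand in sorted(candidates):
        if cand not in bundle.annotations:
            if keep_unannotated:
                result.ppi_partners.add(cand)
                result.evidence.setdefault(cand, []).append(("unannotated",))
            else:
                result.excluded.append((cand, "no_domain_annotation"))
            continue
        cand_domains = bundle.annotations.domain_set(cand)
        support = [
            ("ddi", df, dx)
            for df in sorted(retained)
            for dx in sorted(cand_domains)
            if bundle.has_ddi(df, dx)
        ]
        if support:
            result.ppi_partners.add(cand)
            result.evidence.setdefault(cand, []).extend(support)
        else:
            result.excluded.append((cand, "no_ddi_support"))
    return result


def predict_tf_targets(fusion: FusionSpec, bundle: InteractionBundle) -> PredictedPartners:
    """Inherit a parent's regulatory targets when its DNA-binding domain is retained."""
    result = PredictedPartners()
    for parent in (fusion.parent5, fusion.parent3):
        retained_dbd = fusion.retained_of(parent) & bundle.dna_binding_domains
        if not retained_dbd:
            continue
        for target in sorted(bundle.targets_of(parent)):
            result.tf_target_genes.add(target)
            result.evidence.setdefault(target, []).append(("tf", parent))
    return result


def predicted_partner_set(
    fusion: FusionSpec,
    bundle: InteractionBundle,
    *,
    keep_unannotated: bool = False,
    include_parents: bool = False,
) -> PredictedPartners:
    """Union of PPI-partner and TF-target predictions with merged evidence.

    Raises :class:`EmptySeedError` when the union is empty, since the
    downstream propagation has nothing to seed.
    """
    ppi = predict_ppi_partners(fusion, bundle, keep_unannotated=keep_unannotated)
    tf = predict_tf_targets(fusion, bundle)
    merged = PredictedPartners(
        ppi_partners=set(ppi.ppi_partners),
        tf_target_genes=set(tf.tf_target_genes),
        excluded=list(ppi.excluded),
    )
    for src in (ppi, tf):
        for gene, records in src.evidence.items():
            merged.evidence.setdefault(gene, []).extend(records)
    if include_parents:
        for parent in (fusion.parent5, fusion.parent3):
            merged.ppi_partners.add(parent)
            merged.evidence.setdefault(parent, []).append(("parent",))
    if not merged.seed_genes:
        raise EmptySeedError(
            "no predicted partners: propagation cannot be seeded "
            "(fusion retains no interaction-supporting domains?)"
        )
    return merged
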