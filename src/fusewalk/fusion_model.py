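"""Fusion domain composition: annotations, fusion specs, and validation.

A fusion joins the 5' part of one parental gene to the 3' part of another.
Each parent contributes a subset of its annotated protein domains; the
caller classifies every domain as retained or lost (breakpoints are not
modeled).  Domains are treated as an unordered multiset per parent, and a
repeated accession counts as retained when at least one copy is retained —
downstream interaction inference only needs presence/absence of a domain
type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

from fusewalk.errors import InconsistentInputError, InvalidInputError, MissingAnnotationError

__all__ = ["DomainAnnotationTable", "FusionSpec", "build_fusion"]


class DomainAnnotationTable:
    """Gene -> ordered list of domain accessions (repeats allowed).

    Parameters
    ----------
    records
        Iterable of ``(gene, domain_accession)`` pairs, one per domain
        instance.  Order of instances per gene is preserved.
    """

    def __init__(self, records: Iterable[Tuple[str, str]]):
        self._domains: Dict[str, List[str]] = {}
        for gene, accession in records:
            if not gene:
                raise InvalidInputError("empty gene identifier in domain annotation")
            if not accession:
                raise InvalidInputError(f"empty domain accession for gene {gene!r}")
            self._domains.setdefault(gene, []).append(accession)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "DomainAnnotationTable":
        return cls((g, d) for g, doms in mapping.items() for d in doms)

    def __contains__(self, gene: str) -> bool:
        return gene in self._domains

    def __len__(self) -> int:
        return len(self._domains)

    def genes(self) -> List[str]:
        return list(self._domains)

    def domains_of(self, gene: str) -> List[str]:
        """Ordered domain instances of *gene*; raises if unannotated."""
        try:
            return list(self._domains[gene])
        except KeyError:
            raise MissingAnnotationError(f"gene {gene!r} has no domain annotation") from None

    def domain_set(self, gene: str) -> frozenset:
        return frozenset(self.domains_of(gene))

    def records(self) -> List[Tuple[str, str]]:
        return [(g, d) for g, doms in self._domains.items() for d in doms]


@dataclass(frozen=True)
class FusionSpec:
    """Domain composition of a fusion between two parental genes.

    ``retained5 | lost5`` equals the 5' parent's annotated domain set and
    the two are disjoint (same for the 3' side).
    """

    parent5: str
    parent3: str
    retained5: frozenset
    retained3: frozenset
    lost5: frozenset
    lost3: frozenset

    def __post_init__(self) -> None:
        if self.parent5 == self.parent3:
            raise InvalidInputError("parental genes of a fusion must be distinct")
        for side in ("5", "3"):
            retained = getattr(self, f"retained{side}")
            lost = getattr(self, f"lost{side}")
            if retained & lost:
                raise InconsistentInputError(
                    f"domains both retained and lost on parent{side}: {sorted(retained & lost)}"
                )

    @property
    def retained(self) -> frozenset:
        """Union of retained domain accessions from both parents."""
        return self.retained5 | self.retained3

    def retained_of(self, parent: str) -> frozenset:
        if parent == self.parent5:
            return self.retained5
        if parent == self.parent3:
            return self.retained3
        raise KeyError(parent)


def build_fusion(
    parent5: str,
    parent3: str,
    retained5: Iterable[str],
    retained3: Iterable[str],
    annotations: DomainAnnotationTable,
) -> FusionSpec:
    """Construct a validated :class:`FusionSpec`.

    Lost sets are computed as the complement of the retained sets within
    each parent's annotated domain set.

    Raises
    ------
    MissingAnnotationError
        If a parent gene is absent from *annotations*.
    InconsistentInputError
        If a retained domain is not annotated on its parent.
    """
    retained5 = frozenset(retained5)
    retained3 = frozenset(retained3)
    ann5 = annotations.domain_set(parent5)
    ann3 = annotations.domain_set(parent3)
    for parent, retained, ann in ((parent5, retained5, ann5), (parent3, retained3, ann3)):
        extra = retained - ann
        if extra:
            raise InconsistentInputError(
                f"retained domains {sorted(extra)} are not annotated on parent {parent!r}"
            )
    return FusionSpec(
        parent5=parent5,
        parent3=parent3,
        retained5=retained5,
        retained3=retained3,
        lost5=ann5 - retained5,
        lost3=ann3 - retained3,
    )
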