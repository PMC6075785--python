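"""Readers and writers for every external file the pipeline touches.

Everything is tab-separated text with ``#`` comment lines; readers reject
malformed input with the offending line number instead of coercing it.
Writers stamp a manifest reference comment at the top of each file so any
output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from fusewalk.enrichment import PathwayCollection, RankedGeneList
from fusewalk.errors import InvalidInputError
from fusewalk.fusion_model import DomainAnnotationTable
from fusewalk.integration import ExpressionDataset
from fusewalk.propagation import ScoreVector

__all__ = [
    "RunManifest",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_gene_list",
    "write_gene_list",
    "read_expression",
    "write_expression",
    "read_fusion_config",
    "write_fusion_config",
    "read_scores",
    "write_scores",
    "read_table",
    "write_table",
]

UNDIRECTED_KINDS = {"ppi", "network"}
DIRECTED_KINDS = {"tf"}


@dataclass
class RunManifest:
    """Provenance record for one pipeline invocation."""

    command: str
    version: str
    config: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: List[str] = field(default_factory=list)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = time.strftime("%Y-%m-%dT%H:%M:%S")

    def record_input(self, path: Union[str, Path]) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.inputs[str(p)] = digest

    def record_output(self, path: Union[str, Path]) -> None:
        self.outputs.append(str(path))

    def write(self, path: Union[str, Path]) -> None:
        payload = {
            "command": self.command,
            "version": self.version,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "created": self.created,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


MANIFEST_REF = "manifest.json"


def _header(manifest_ref: Optional[str]) -> str:
    return f"# manifest: {manifest_ref}\n" if manifest_ref else ""


def _iter_rows(path: Union[str, Path]):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: Union[str, Path], kind: str = "network") -> Set[Tuple]:
    """Parse a TSV edge list; undirected kinds are canonicalized (sorted pair).

    ``network`` rows may carry a third numeric weight column.  Duplicate
    rows collapse; self-loops are kept.
    """
    if kind not in UNDIRECTED_KINDS | DIRECTED_KINDS:
        raise InvalidInputError(f"unknown edge-list kind {kind!r}")
    edges: Set[Tuple] = set()
    n_self = 0
    for lineno, line in _iter_rows(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise InvalidInputError(f"{path}:{lineno}: malformed edge row {line!r}")
        u, v = parts[0], parts[1]
        if u == v:
            n_self += 1
        if kind in UNDIRECTED_KINDS and v < u:
            u, v = v, u
        if kind == "network" and len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            edges.add((u, v, w))
        else:
            edges.add((u, v))
    if not edges:
        raise InvalidInputError(f"{path}: empty edge list")
    return edges


def write_edge_list(
    edges: Iterable[Tuple], path: Union[str, Path], manifest_ref: Optional[str] = MANIFEST_REF
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        for edge in sorted(edges):
            fh.write("\t".join(str(x) for x in edge) + "\n")


def read_gmt(path: Union[str, Path]) -> PathwayCollection:
    """Standard GMT: name, description, then tab-separated members."""
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    first_line: Dict[str, int] = {}
    for lineno, line in _iter_rows(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise InvalidInputError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if not members:
            raise InvalidInputError(f"{path}:{lineno}: pathway {name!r} has no members")
        if name in sets:
            raise InvalidInputError(
                f"{path}: duplicate pathway name {name!r} "
                f"(lines {first_line[name]} and {lineno})"
            )
        sets[name] = members
        descriptions[name] = desc
        first_line[name] = lineno
    if not sets:
        raise InvalidInputError(f"{path}: empty GMT file")
    return PathwayCollection(sets, descriptions, source=str(path))


def write_gmt(collection: PathwayCollection, path: Union[str, Path]) -> None:
    # GMT has no comment convention; no manifest header here
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_domain_annotations(path: Union[str, Path]) -> DomainAnnotationTable:
    """TSV of gene, domain_accession — one row per domain instance."""
    records = []
    for lineno, line in _iter_rows(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise InvalidInputError(f"{path}:{lineno}: malformed annotation row {line!r}")
        records.append((parts[0], parts[1]))
    if not records:
        raise InvalidInputError(f"{path}: empty annotation file")
    return DomainAnnotationTable(records)


def write_domain_annotations(
    table: DomainAnnotationTable, path: Union[str, Path], manifest_ref: Optional[str] = MANIFEST_REF
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        for gene, domain in table.records():
            fh.write(f"{gene}\t{domain}\n")


def read_gene_list(path: Union[str, Path]) -> List[str]:
    """One identifier per line (first column of each row)."""
    genes = []
    for lineno, line in _iter_rows(path):
        genes.append(line.split("\t")[0])
    if not genes:
        raise InvalidInputError(f"{path}: empty gene list")
    return genes


def write_gene_list(
    genes: Iterable[str], path: Union[str, Path], manifest_ref: Optional[str] = MANIFEST_REF
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        for g in genes:
            fh.write(f"{g}\n")


def read_expression(
    matrix_path: Union[str, Path],
    labels_path: Union[str, Path],
    case_group: Optional[str] = None,
) -> ExpressionDataset:
    """Genes x samples TSV with a header row, plus a sample->group TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"{matrix_path}: duplicate gene rows {dup}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise InvalidInputError(
                f"{matrix_path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
    labels: Dict[str, str] = {}
    for lineno, line in _iter_rows(labels_path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise InvalidInputError(f"{labels_path}:{lineno}: malformed label row")
        labels[parts[0]] = parts[1]
    return ExpressionDataset(df.astype(float), labels, case_group=case_group)


def write_expression(
    data: ExpressionDataset,
    matrix_path: Union[str, Path],
    labels_path: Union[str, Path],
    manifest_ref: Optional[str] = MANIFEST_REF,
) -> None:
    with open(matrix_path, "w") as fh:
        fh.write(_header(manifest_ref))
        data.matrix.to_csv(fh, sep="\t", index_label="gene")
    with open(labels_path, "w") as fh:
        fh.write(_header(manifest_ref))
        for sample in data.matrix.columns:
            fh.write(f"{sample}\t{data.group_of[sample]}\n")


def read_fusion_config(path: Union[str, Path]) -> Dict[str, object]:
    """Key-value fusion description.

    Keys: ``parent5``, ``parent3`` (single values) and ``retained5``,
    ``retained3`` (comma-separated accession lists, may be empty).
    """
    out: Dict[str, object] = {}
    for lineno, line in _iter_rows(path):
        if "=" not in line:
            raise InvalidInputError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("retained5", "retained3"):
            out[key] = [v.strip() for v in value.split(",") if v.strip()]
        else:
            out[key] = value
    for req in ("parent5", "parent3", "retained5", "retained3"):
        if req not in out:
            raise InvalidInputError(f"{path}: missing key {req!r}")
    return out


def write_fusion_config(
    parent5: str,
    parent3: str,
    retained5: Iterable[str],
    retained3: Iterable[str],
    path: Union[str, Path],
    manifest_ref: Optional[str] = MANIFEST_REF,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        fh.write(f"parent5 = {parent5}\n")
        fh.write(f"parent3 = {parent3}\n")
        fh.write(f"retained5 = {','.join(sorted(retained5))}\n")
        fh.write(f"retained3 = {','.join(sorted(retained3))}\n")


def write_scores(
    scores: ScoreVector,
    ranked: RankedGeneList,
    path: Union[str, Path],
    manifest_ref: Optional[str] = MANIFEST_REF,
) -> None:
    """TSV of gene, association_score, rank, is_seed."""
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        fh.write("gene\tassociation_score\trank\tis_seed\n")
        for rank, gene in enumerate(ranked.genes, start=1):
            fh.write(
                f"{gene}\t{scores.scores[gene]:.12g}\t{rank}\t"
                f"{int(gene in scores.seed_set)}\n"
            )


def read_scores(path: Union[str, Path]) -> Tuple[Dict[str, float], Set[str]]:
    """Inverse of :func:`write_scores`: (score mapping, seed set)."""
    scores: Dict[str, float] = {}
    seeds: Set[str] = set()
    header_seen = False
    for lineno, line in _iter_rows(path):
        parts = line.split("\t")
        if not header_seen:
            header_seen = True
            if parts[0] == "gene":
                continue
        if len(parts) < 4:
            raise InvalidInputError(f"{path}:{lineno}: malformed score row")
        gene = parts[0]
        if gene in scores:
            raise InvalidInputError(f"{path}:{lineno}: duplicate gene {gene!r}")
        scores[gene] = float(parts[1])
        if parts[3] == "1":
            seeds.add(gene)
    if not scores:
        raise InvalidInputError(f"{path}: empty score file")
    return scores, seeds


def write_table(
    df: pd.DataFrame, path: Union[str, Path], manifest_ref: Optional[str] = MANIFEST_REF
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest_ref))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
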