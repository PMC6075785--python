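"""Deterministic synthetic input bundles with planted ground truth.

``generate_scenario`` builds a complete toy input set — gene network,
domain annotations, DDI catalog, TF edges, pathway collection, two-group
expression matrix, drug-target table and benchmark set — around a planted
dense module that the synthetic fusion's retained domains point into.
Every stage of the pipeline is therefore testable offline: the module
genes should dominate the association ranking, the planted pathway should
win both enrichment analyses, and the planted drug should map.

``worked_example_fixture`` is a hand-wired miniature (two parents, six
domains, eight candidate partners) with a known partner split, used for
exhaustive domain-filter tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from fusewalk.errors import InvalidInputError
from fusewalk.fusion_model import DomainAnnotationTable, FusionSpec, build_fusion
from fusewalk.interaction_inference import InteractionBundle
from fusewalk.integration import ExpressionDataset
from fusewalk.enrichment import PathwayCollection
from fusewalk.targets_eval import BenchmarkSet, DrugTargetTable

__all__ = ["ScenarioParams", "ScenarioBundle", "generate_scenario", "worked_example_fixture", "WorkedExample"]

PARENT5 = "PARENT5"
PARENT3 = "PARENT3"
PLANTED_PATHWAY = "PLANTED_MODULE"


@dataclass
class ScenarioParams:
    """Knobs for the planted-module scenario; defaults give the standard benchmark."""

    n_genes: int = 500
    module_size: int = 40
    p_in: float = 0.30          # edge probability inside the planted module
    p_bg: float = 0.01          # background (Erdos-Renyi) edge probability
    n_anchors: int = 8          # parental PPI neighbors with retained-domain DDI support
    n_lost_neighbors: int = 4   # parental neighbors supported only by a lost domain
    n_unannotated_neighbors: int = 2
    n_tf_targets: int = 5
    n_decoy_pathways: int = 50
    decoy_size_min: int = 20
    decoy_size_max: int = 60
    n_samples_per_group: int = 10
    effect: float = 1.5         # case-group shift on module genes, in units of noise_sd
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.module_size > self.n_genes:
            raise InvalidInputError("module_size exceeds n_genes")
        if self.n_anchors + self.n_tf_targets > self.module_size:
            raise InvalidInputError("anchors + tf targets exceed module size")
        if self.n_lost_neighbors + self.n_unannotated_neighbors > self.n_genes - self.module_size:
            raise InvalidInputError("not enough background genes for decoy neighbors")
        if self.n_samples_per_group < 2:
            raise InvalidInputError("need >= 2 samples per group")


@dataclass
class ScenarioBundle:
    """In-memory synthetic inputs plus the planted ground truth."""

    params: ScenarioParams
    seed: int
    genes: List[str]
    module: List[str]
    fusion: FusionSpec
    annotations: DomainAnnotationTable
    bundle: InteractionBundle
    network_edges: Set[Tuple[str, str]]
    pathways: PathwayCollection
    expression: ExpressionDataset
    drug_targets: DrugTargetTable
    benchmark: BenchmarkSet
    ground_truth: Dict[str, object]

    def write(self, out_dir) -> List[str]:
        """Write the full input bundle as plain TSV/GMT/JSON files."""
        from fusewalk import io_formats as io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, fn):
            path = out / name
            fn(path)
            written.append(str(path))

        _w("network.tsv", lambda p: io.write_edge_list(sorted(self.network_edges), p))
        _w("ppi.tsv", lambda p: io.write_edge_list(sorted(self.bundle.ppi), p))
        _w("ddi.tsv", lambda p: io.write_edge_list(sorted(self.bundle.ddi), p))
        _w("tf_targets.tsv", lambda p: io.write_edge_list(sorted(self.bundle.tf_targets), p))
        _w("domains.tsv", lambda p: io.write_domain_annotations(self.annotations, p))
        _w("dna_binding.txt", lambda p: io.write_gene_list(sorted(self.bundle.dna_binding_domains), p))
        _w("pathways.gmt", lambda p: io.write_gmt(self.pathways, p))
        _w("expression.tsv", lambda p: io.write_expression(self.expression, p, out / "labels.tsv"))
        written.append(str(out / "labels.tsv"))
        _w(
            "drug_targets.tsv",
            lambda p: io.write_edge_list(
                sorted((d, g) for d in self.drug_targets.drugs() for g in self.drug_targets.targets_of(d)),
                p,
            ),
        )
        _w("benchmark.txt", lambda p: io.write_gene_list(sorted(self.benchmark.positives), p))
        _w(
            "fusion.txt",
            lambda p: io.write_fusion_config(
                self.fusion.parent5,
                self.fusion.parent3,
                self.fusion.retained5,
                self.fusion.retained3,
                p,
            ),
        )
        _w(
            "ground_truth.json",
            lambda p: Path(p).write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True) + "\n"),
        )
        readme = out / "GROUND_TRUTH_README.txt"
        readme.write_text(
            "Synthetic planted-module scenario (seed={}).\n"
            "Planted module genes top the association ranking; pathway {!r}\n"
            "is the planted gene set and carries the expression shift.\n".format(
                self.seed, PLANTED_PATHWAY
            )
        )
        written.append(str(readme))
        return written


def _er_edges(rng: np.random.Generator, genes: List[str], p: float) -> Set[Tuple[str, str]]:
    n = len(genes)
    edges: Set[Tuple[str, str]] = set()
    # vectorized upper-triangle Bernoulli draw
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    for i, j in zip(iu[mask], ju[mask]):
        edges.add((genes[i], genes[j]))
    return edges


def generate_scenario(params: ScenarioParams | None = None, seed: int = 0) -> ScenarioBundle:
    """Build the planted-module scenario; fully determined by (params, seed)."""
    params = params or ScenarioParams()
    params.validate()
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(1, params.n_genes + 1)]
    module = sorted(rng.choice(genes, size=params.module_size, replace=False).tolist())
    background = [g for g in genes if g not in set(module)]

    # roles inside / around the module
    picks = rng.permutation(module).tolist()
    anchors = sorted(picks[: params.n_anchors])
    tf_targets = sorted(picks[params.n_anchors : params.n_anchors + params.n_tf_targets])
    bg_picks = rng.permutation(background).tolist()
    lost_neighbors = sorted(bg_picks[: params.n_lost_neighbors])
    unannotated = sorted(
        bg_picks[params.n_lost_neighbors : params.n_lost_neighbors + params.n_unannotated_neighbors]
    )

    # fusion domain wiring
    annotations_records: List[Tuple[str, str]] = [
        (PARENT5, "PF_KIN"),
        (PARENT5, "PF_LOST"),
        (PARENT3, "PF_MOD"),
        (PARENT3, "PF_DBD"),
    ]
    for g in anchors:
        annotations_records.append((g, "PF_ANCH"))
    for g in lost_neighbors:
        annotations_records.append((g, "PF_DEC"))
    for g in background:
        if g not in set(lost_neighbors) and g not in set(unannotated):
            annotations_records.append((g, "PF_BG"))
    for g in module:
        if g not in set(anchors):
            annotations_records.append((g, "PF_BG"))
    annotations = DomainAnnotationTable(annotations_records)

    ddi = {("PF_KIN", "PF_ANCH"), ("PF_LOST", "PF_DEC")}

    # PPI: background ER + dense module block + parental spokes
    ppi = _er_edges(rng, genes, params.p_bg)
    midx = {g: i for i, g in enumerate(module)}
    iu, ju = np.triu_indices(len(module), k=1)
    mask = rng.random(len(iu)) < params.p_in
    for i, j in zip(iu[mask], ju[mask]):
        a, b = module[i], module[j]
        ppi.add((a, b) if a <= b else (b, a))
    half = len(anchors) // 2
    for g in anchors[:half]:
        ppi.add((PARENT5, g))
    for g in anchors[half:]:
        ppi.add((PARENT3, g))
    for g in lost_neighbors:
        ppi.add((PARENT5, g))
    for g in unannotated:
        ppi.add((PARENT3, g))

    tf_edges = {(PARENT3, g) for g in tf_targets}
    bundle = InteractionBundle(
        ppi=ppi,
        ddi=ddi,
        tf_targets=tf_edges,
        annotations=annotations,
        dna_binding_domains=frozenset({"PF_DBD"}),
    )

    fusion = build_fusion(
        PARENT5, PARENT3, retained5={"PF_KIN"}, retained3={"PF_MOD", "PF_DBD"}, annotations=annotations
    )

    # propagation network = PPI union symmetrized TF edges
    network_edges = {tuple(sorted(e)) for e in ppi} | {tuple(sorted(e)) for e in tf_edges}

    # pathways: planted module + random decoys
    sets: Dict[str, List[str]] = {PLANTED_PATHWAY: list(module)}
    for i in range(params.n_decoy_pathways):
        size = int(rng.integers(params.decoy_size_min, params.decoy_size_max + 1))
        sets[f"DECOY_{i + 1:03d}"] = sorted(rng.choice(genes, size=size, replace=False).tolist())
    pathways = PathwayCollection(sets, source="synthetic")

    # expression: case group shifted on module genes
    m = params.n_samples_per_group
    samples = [f"case_{i + 1:02d}" for i in range(m)] + [f"ctrl_{i + 1:02d}" for i in range(m)]
    values = rng.normal(0.0, params.noise_sd, size=(params.n_genes, 2 * m))
    module_rows = [genes.index(g) for g in module]
    values[module_rows, :m] += params.effect * params.noise_sd
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    expression = ExpressionDataset(matrix, labels, case_group="case")

    # drugs: planted module drugs plus background/off-universe decoys
    drug_pairs = (
        [("drug_module_a", g) for g in module[:3]]
        + [("drug_module_b", g) for g in module[3:5]]
        + [("drug_module_b", background[0])]
        + [("drug_background", g) for g in background[1:4]]
        + [("drug_offnet", "OFFNET_GENE")]
    )
    drug_targets = DrugTargetTable(drug_pairs, source="synthetic")

    benchmark = BenchmarkSet(name="planted_module", positives=set(module))

    ground_truth = {
        "seed": seed,
        "params": asdict(params),
        "module": module,
        "anchors": anchors,
        "tf_targets": tf_targets,
        "lost_support_neighbors": lost_neighbors,
        "unannotated_neighbors": unannotated,
        "planted_pathway": PLANTED_PATHWAY,
        "expected_ppi_partners": anchors,
        "expected_tf_target_genes": tf_targets,
    }

    return ScenarioBundle(
        params=params,
        seed=seed,
        genes=genes,
        module=module,
        fusion=fusion,
        annotations=annotations,
        bundle=bundle,
        network_edges=network_edges,
        pathways=pathways,
        expression=expression,
        drug_targets=drug_targets,
        benchmark=benchmark,
        ground_truth=ground_truth,
    )


@dataclass
class WorkedExample:
    """Hand-wired miniature system with a known partner split."""

    annotations: DomainAnnotationTable
    bundle: InteractionBundle
    parent5: str = "GENE_A"
    parent3: str = "GENE_B"
    # partners supported when every domain is retained
    full_blue_ppi: frozenset = frozenset({"P1", "P2", "P3", "P4", "P7", "P8"})
    full_blue_tf: frozenset = frozenset({"T1", "T2"})
    # which retained fusion domain supports which candidate
    support: Dict[str, str] = field(
        default_factory=lambda: {
            "P1": "A1",
            "P2": "A2",
            "P7": "A3",
            "P3": "B1",
            "P4": "B2",
            "P8": "B1",
        }
    )


def worked_example_fixture() -> WorkedExample:
    """Two parents, six domains, eight candidates, two regulatory targets.

    Candidate P5 has a domain with no DDI entry (always white); P6 has no
    annotation at all (always excluded).  B3 is the DNA-binding domain:
    retaining it inherits GENE_B's targets T1 and T2.
    """
    annotations = DomainAnnotationTable(
        [
            ("GENE_A", "A1"),
            ("GENE_A", "A2"),
            ("GENE_A", "A3"),
            ("GENE_B", "B1"),
            ("GENE_B", "B2"),
            ("GENE_B", "B3"),
            ("P1", "X1"),
            ("P2", "X2"),
            ("P3", "X3"),
            ("P4", "X4"),
            ("P5", "X5"),
            ("P7", "X7"),
            ("P8", "X8"),
            ("T1", "X9"),
            ("T2", "X9"),
        ]
    )
    bundle = InteractionBundle(
        ppi={
            ("GENE_A", "P1"),
            ("GENE_A", "P2"),
            ("GENE_A", "P5"),
            ("GENE_A", "P7"),
            ("GENE_B", "P3"),
            ("GENE_B", "P4"),
            ("GENE_B", "P6"),
            ("GENE_B", "P8"),
        },
        ddi={
            ("A1", "X1"),
            ("A2", "X2"),
            ("A3", "X7"),
            ("B1", "X3"),
            ("B2", "X4"),
            ("B1", "X8"),
        },
        tf_targets={("GENE_B", "T1"), ("GENE_B", "T2")},
        annotations=annotations,
        dna_binding_domains=frozenset({"B3"}),
    )
    return WorkedExample(annotations=annotations, bundle=bundle)
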