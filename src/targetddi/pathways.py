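"""Pathway / cellular-process overlap between the target sets of two drugs.

A drug is mapped onto the gene sets (signaling pathways or GO biological
processes) containing any of its target genes; the common sets of a drug
pair are the intersection of the two per-drug unions. For each common set
the supporting target genes of each drug are recorded, distinguishing
overlap via a shared target gene from overlap via two different genes in the
same set (pathway cross-talk).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import (DrugTargetMap, InteractionSet, PathwayCollection,
                 canonical_pair)


def gene_to_sets(gene: str, collection: PathwayCollection) -> frozenset[str]:
    """Ids of all gene sets containing *gene* (case-insensitive)."""
    g = gene.strip().upper()
    return frozenset(sid for sid, genes in collection.sets.items()
                     if g in genes)


def drug_sets(drug: str, targets: DrugTargetMap,
              collection: PathwayCollection,
              max_set_size: int | None = None) -> frozenset[str]:
    """Union of gene_to_sets over the drug's target genes.

    *max_set_size* optionally excludes giant sets (off by default).
    """
    out: set[str] = set()
    for gene in targets.targets(drug):
        out |= gene_to_sets(gene, collection)
    if max_set_size is not None:
        out = {sid for sid in out if len(collection.sets[sid]) <= max_set_size}
    return frozenset(out)


@dataclass(frozen=True)
class OverlapResult:
    """Common gene sets of a drug pair with supporting genes per set."""

    drugs: tuple[str, str]
    kind: str
    #: set id -> (target genes of drugs[0] in the set, of drugs[1] in the set)
    common: Mapping[str, tuple[frozenset[str], frozenset[str]]]

    def __len__(self) -> int:
        return len(self.common)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.common)


def common_sets(drug_a: str, drug_b: str, targets: DrugTargetMap,
                collection: PathwayCollection,
                max_set_size: int | None = None) -> OverlapResult:
    """Gene sets hit by at least one target gene of each drug."""
    sets_a = drug_sets(drug_a, targets, collection, max_set_size)
    sets_b = drug_sets(drug_b, targets, collection, max_set_size)
    ga, gb = targets.targets(drug_a), targets.targets(drug_b)
    common: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for sid in sorted(sets_a & sets_b):
        members = collection.sets[sid]
        common[sid] = (frozenset(ga & members), frozenset(gb & members))
    return OverlapResult(drugs=(drug_a, drug_b), kind=collection.kind,
                         common=common)


def export_overlap_network(result: OverlapResult,
                           targets: DrugTargetMap,
                           nodes_path: str | Path,
                           edges_path: str | Path,
                           allow_empty: bool = False) -> None:
    """Write node/edge TSV tables for network-visualization tools.

    Node types: ``drug``, ``gene`` (targeted by one drug), ``common_gene``
    (targeted by both), ``set``. Edges: drug->gene for each supporting gene,
    gene->set for each common set's supporting genes.
    """
    if len(result) == 0:
        if not allow_empty:
            raise ValueError(f"overlap result for {result.drugs} is empty; pass "
                             "allow_empty=True to export header-only tables")
        with open(nodes_path, "w", encoding="utf-8") as fh:
            fh.write("# id\ttype\n")
        with open(edges_path, "w", encoding="utf-8") as fh:
            fh.write("# source\ttarget\ttype\n")
        return
    d1, d2 = result.drugs
    shared_targets = targets.targets(d1) & targets.targets(d2)
    support = {d1: set(), d2: set()}
    for genes1, genes2 in result.common.values():
        support[d1] |= genes1
        support[d2] |= genes2

    nodes: list[tuple[str, str]] = [(d1, "drug"), (d2, "drug")]
    for gene in sorted(support[d1] | support[d2]):
        node_type = "common_gene" if gene in shared_targets else "gene"
        nodes.append((gene, node_type))
    for sid in sorted(result.common):
        nodes.append((sid, "set"))

    edges: list[tuple[str, str, str]] = []
    for drug in (d1, d2):
        for gene in sorted(support[drug]):
            edges.append((drug, gene, "targets"))
    for sid in sorted(result.common):
        genes1, genes2 = result.common[sid]
        for gene in sorted(genes1 | genes2):
            edges.append((gene, sid, "member_of"))
    # a shared gene supports both drugs but each edge is listed once per drug
    seen = set()
    edges = [e for e in edges if not (e in seen or seen.add(e))]

    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("# id\ttype\n")
        for node_id, node_type in nodes:
            fh.write(f"{node_id}\t{node_type}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\ttype\n")
        for src, dst, etype in edges:
            fh.write(f"{src}\t{dst}\t{etype}\n")


def overlap_summary(interactions: InteractionSet,
                    targets: DrugTargetMap,
                    pathways: PathwayCollection | None = None,
                    processes: PathwayCollection | None = None) -> pd.DataFrame:
    """Per-pair table of common-pathway and common-process counts."""
    interactions.resolve_in(targets)
    rows = []
    for a, b, label in interactions:
        row: dict[str, object] = {"drug_a": a, "drug_b": b, "label": label}
        if pathways is not None:
            row["n_common_pathways"] = len(common_sets(a, b, targets, pathways))
        if processes is not None:
            row["n_common_processes"] = len(common_sets(a, b, targets, processes))
        rows.append(row)
    return pd.DataFrame(rows)
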