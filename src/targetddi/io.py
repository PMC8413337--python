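"""Readers and writers for the tab-separated inputs of the DDI pipeline.

Four external formats are supported, all UTF-8, tab-delimited, with ``#``
comment lines and blank lines skipped:

* drug->target tables: ``drug_id<TAB>gene_symbol`` per line;
* labeled drug-pair lists: ``drug_a<TAB>drug_b[<TAB>label]``;
* undirected PPI edge lists: ``geneA<TAB>geneB``;
* GMT gene-set collections: ``set_id<TAB>description<TAB>gene1<TAB>...``.

Gene symbols are uppercased at ingestion and drug pairs are canonicalized
with the lexicographically smaller identifier first, so that reading a file
twice (or in permuted line order) yields identical in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Label conventions for interacting / non-interacting drug pairs.
POSITIVE = 1
NEGATIVE = -1

_LABEL_TOKENS = {
    "1": POSITIVE,
    "+1": POSITIVE,
    "-1": NEGATIVE,
}


class FormatError(ValueError):
    """An input file violates its dialect (with file/line context)."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = str(path) if path is not None else None
        self.line = line


class UnknownDrugError(KeyError):
    """A drug identifier does not resolve in the drug->target map."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair ({a!r}, {b!r}) is not a valid drug pair")
    return (a, b) if a < b else (b, a)


def _clean_gene(symbol: str) -> str:
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTargetMap:
    """Mapping from drug identifier to its set of targeted gene symbols.

    Only drugs with at least one target gene are representable: the feature
    construction is defined over target profiles, so a drug without any
    known human target gene carries no signal and is rejected at load time.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for drug, genes in self.entries.items():
            cleaned = frozenset(_clean_gene(g) for g in genes if _clean_gene(g))
            if not cleaned:
                raise ValueError(
                    f"drug {drug!r} has no valid target genes; every drug must "
                    "target at least one gene")
            clean[str(drug)] = cleaned
        object.__setattr__(self, "entries", clean)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.entries.values():
            out |= gs
        return frozenset(out)

    def targets(self, drug: str) -> frozenset[str]:
        try:
            return self.entries[drug]
        except KeyError:
            raise UnknownDrugError(f"unknown drug {drug!r}") from None

    def __contains__(self, drug: str) -> bool:
        return drug in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class InteractionSet:
    """A set of labeled unordered drug pairs.

    Pairs are stored canonicalized (smaller id first); ``(a, b)`` and
    ``(b, a)`` denote the same record. Self-pairs and conflicting labels for
    the same unordered pair are rejected.
    """

    pairs: tuple[tuple[str, str, int], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]],
                     path: str | Path | None = None) -> "InteractionSet":
        seen: dict[tuple[str, str], int] = {}
        order: list[tuple[str, str]] = []
        for a, b, label in records:
            if label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"label must be +1 or -1, got {label!r}")
            if a == b:
                raise FormatError(f"self-pair ({a!r}, {a!r}) rejected", path)
            key = canonical_pair(a, b)
            if key in seen:
                if seen[key] != label:
                    raise FormatError(
                        f"conflicting labels for pair {key}", path)
                continue
            seen[key] = label
            order.append(key)
        return cls(tuple((a, b, seen[(a, b)]) for a, b in order))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(self.pairs)

    @property
    def drugs(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b, _ in self.pairs:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def pair_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b, _ in self.pairs)

    def labels(self) -> tuple[int, ...]:
        return tuple(label for _, _, label in self.pairs)

    def subset(self, labels: Iterable[int]) -> "InteractionSet":
        wanted = set(labels)
        return InteractionSet(tuple(p for p in self.pairs if p[2] in wanted))

    def positives(self) -> "InteractionSet":
        return self.subset({POSITIVE})

    def negatives(self) -> "InteractionSet":
        return self.subset({NEGATIVE})

    def resolve_in(self, targets: DrugTargetMap) -> None:
        """Raise if any drug id in this set is absent from *targets*."""
        missing = sorted(d for d in self.drugs if d not in targets)
        if missing:
            raise UnknownDrugError(
                f"drugs not present in the drug->target map: {missing}")


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph over gene symbols (physical PPIs)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"PPI network contains self-loops: {loops[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets: signaling pathways or GO biological-process terms."""

    sets: Mapping[str, frozenset[str]]
    kind: str = "pathway"

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "process"):
            raise ValueError(f"kind must be 'pathway' or 'process', got {self.kind!r}")
        clean: dict[str, frozenset[str]] = {}
        for sid, genes in self.sets.items():
            cleaned = frozenset(_clean_gene(g) for g in genes if _clean_gene(g))
            if not cleaned:
                raise ValueError(f"gene set {sid!r} is empty")
            clean[str(sid)] = cleaned
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))


# ---------------------------------------------------------------------------
# Line-level plumbing
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields) for data lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a two-column ``drug_id<TAB>gene_symbol`` table."""
    entries: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise FormatError(
                f"expected 2 tab-separated fields, got {len(fields)}",
                path, lineno)
        drug, gene = fields[0].strip(), _clean_gene(fields[1])
        if not drug:
            raise FormatError("empty drug identifier", path, lineno)
        if not gene:
            raise FormatError(f"empty gene symbol for drug {drug!r}", path, lineno)
        entries.setdefault(drug, set()).add(gene)
    return DrugTargetMap({d: frozenset(g) for d, g in entries.items()})


def read_interactions(path: str | Path,
                      default_label: int = POSITIVE) -> InteractionSet:
    """Read a drug-pair list, optionally with a third label column.

    Lines are ``drug_a<TAB>drug_b`` (labeled with *default_label*) or
    ``drug_a<TAB>drug_b<TAB>label`` with label in {+1, -1, 1}.
    """
    if default_label not in (POSITIVE, NEGATIVE):
        raise ValueError("default_label must be +1 or -1")
    records: list[tuple[str, str, int]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise FormatError(
                f"expected 2 or 3 tab-separated fields, got {len(fields)}",
                path, lineno)
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise FormatError("empty drug identifier", path, lineno)
        if a == b:
            raise FormatError(f"self-pair ({a!r}, {b!r})", path, lineno)
        if len(fields) == 3:
            token = fields[2].strip()
            if token not in _LABEL_TOKENS:
                raise FormatError(f"unparseable label {token!r}", path, lineno)
            label = _LABEL_TOKENS[token]
        else:
            label = default_label
        records.append((a, b, label))
    return InteractionSet.from_records(records, path=path)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read an undirected PPI edge list; self-loops are dropped (logged)."""
    g = nx.Graph()
    dropped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise FormatError(
                f"expected 2 tab-separated fields, got {len(fields)}",
                path, lineno)
        a, b = _clean_gene(fields[0]), _clean_gene(fields[1])
        if not a or not b:
            raise FormatError("empty gene symbol", path, lineno)
        if a == b:
            dropped += 1
            continue
        g.add_edge(a, b)
    if dropped:
        logger.info("dropped %d self-loop edge(s) while reading %s", dropped, path)
    return PPINetwork(g)


def read_gene_sets(path: str | Path, kind: str = "pathway") -> PathwayCollection:
    """Read a GMT file (set id, description, member genes)."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(
                f"GMT line needs >= 3 tab-separated fields, got {len(fields)}",
                path, lineno)
        sid = fields[0].strip()
        if not sid:
            raise FormatError("empty gene-set identifier", path, lineno)
        if sid in sets:
            raise FormatError(f"duplicate gene-set id {sid!r}", path, lineno)
        genes = frozenset(_clean_gene(g) for g in fields[2:] if _clean_gene(g))
        if not genes:
            raise FormatError(f"gene set {sid!r} has no genes", path, lineno)
        sets[sid] = genes
    return PathwayCollection(sets, kind=kind)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_drug_targets(targets: DrugTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tgene_symbol\n")
        for drug in targets.drugs:
            for gene in sorted(targets.targets(drug)):
                fh.write(f"{drug}\t{gene}\n")


def write_interactions(interactions: InteractionSet, path: str | Path,
                       with_labels: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if with_labels:
            fh.write("# drug_a\tdrug_b\tlabel\n")
            for a, b, label in interactions:
                fh.write(f"{a}\t{b}\t{label:+d}\n")
        else:
            fh.write("# drug_a\tdrug_b\n")
            for a, b, _ in interactions:
                fh.write(f"{a}\t{b}\n")


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_gene_sets(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in collection.ids:
            genes = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.kind}\t{genes}\n")


def write_predictions(pairs: Sequence[tuple[str, str]],
                      probabilities: Sequence[float],
                      labels: Sequence[int],
                      path: str | Path) -> None:
    """Write scored drug pairs as TSV, probabilities at 6 decimal places."""
    if not (len(pairs) == len(probabilities) == len(labels)):
        raise ValueError(
            f"length mismatch: {len(pairs)} pairs, {len(probabilities)} "
            f"probabilities, {len(labels)} labels")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_a\tdrug_b\tprobability\tpredicted_label\n")
        for (a, b), p, label in zip(pairs, probabilities, labels):
            fh.write(f"{a}\t{b}\t{p:.6f}\t{label:+d}\n")
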