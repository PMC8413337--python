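"""Interaction-intensity statistics over target sets and PPI networks.

Three families of statistics quantify how strongly two drugs may perturb one
another:

* **Jaccard index** of the two target gene sets — direct overlap; ``Sim_U``
  is the fraction of pairs in a pair set U whose Jaccard index reaches a
  threshold xi. With xi = min over U of 1/|union|, Sim_U equals the fraction
  of pairs sharing at least one target gene.
* **Path statistics**: for every cross gene pair (g_i in G_d1, g_j in G_d2)
  all simple paths up to a length cap are enumerated in the PPI network;
  aggregated per drug pair into Avg (mean path count over the
  |G_d1| x |G_d2| cross pairs — interaction intensity), S (minimum shortest
  length — interaction efficiency) and L (maximum capped longest length —
  action range). A shared gene counts as one path of length 0, so S = 0
  exactly when the drugs share a target.

Simple-path enumeration is exponential in general; it is bounded by the
length cap (default 8) and a per-gene-pair count ceiling, with an explicit
``truncated`` flag rather than silently wrong counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io import DrugTargetMap, InteractionSet, PPINetwork, POSITIVE, NEGATIVE

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 8
DEFAULT_COUNT_CAP = 10 ** 6

#: Rendering of an undefined (unreachable-within-cap) path length.
UNREACHABLE = "unreachable"


def jaccard(drug_a: str, drug_b: str, targets: DrugTargetMap) -> float:
    """|G_a intersect G_b| / |G_a union G_b|."""
    ga, gb = targets.targets(drug_a), targets.targets(drug_b)
    return len(ga & gb) / len(ga | gb)


def min_xi(interactions: InteractionSet, targets: DrugTargetMap) -> float:
    """min over pairs of 1/|G_a union G_b| — the threshold at which Sim_U
    counts exactly the pairs sharing at least one target gene."""
    if len(interactions) == 0:
        raise ValueError("empty interaction set")
    return min(1.0 / len(targets.targets(a) | targets.targets(b))
               for a, b, _ in interactions)


def sim_u(interactions: InteractionSet, targets: DrugTargetMap,
          xi: float) -> float:
    """Fraction of pairs whose Jaccard index is >= xi."""
    if len(interactions) == 0:
        raise ValueError("empty interaction set")
    if not 0.0 < xi <= 1.0:
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    hits = sum(1 for a, b, _ in interactions
               if jaccard(a, b, targets) >= xi)
    return hits / len(interactions)


@dataclass(frozen=True)
class PathEnumeration:
    """Simple-path census between one gene pair, within the length cap."""

    count: int
    shortest: int | None
    longest: int | None
    truncated: bool = False


class _CountCapReached(Exception):
    pass


def enumerate_paths(gene_a: str, gene_b: str, ppi: PPINetwork,
                    max_len: int = DEFAULT_MAX_LEN,
                    count_cap: int = DEFAULT_COUNT_CAP) -> PathEnumeration:
    """Count all simple paths of length <= max_len between two genes.

    Lengths are in edges. ``gene_a == gene_b`` counts as one path of length
    0. A gene absent from the network is an isolated node (zero paths,
    logged). Enumeration is depth-first with distance-to-target pruning;
    exceeding *count_cap* stops the search and sets ``truncated``.
    """
    if max_len < 0:
        raise ValueError("max_len must be >= 0")
    if gene_a == gene_b:
        return PathEnumeration(1, 0, 0)
    g = ppi.graph
    for gene in (gene_a, gene_b):
        if gene not in g:
            logger.warning("gene %s absent from the PPI network; treated as "
                           "isolated", gene)
            return PathEnumeration(0, None, None)
    if max_len == 0:
        return PathEnumeration(0, None, None)
    # distance from every node to the target bounds the remaining budget
    dist = nx.single_source_shortest_path_length(g, gene_b, cutoff=max_len)
    if dist.get(gene_a, math.inf) > max_len:
        return PathEnumeration(0, None, None)

    count = 0
    shortest: int | None = None
    longest: int | None = None
    on_path = {gene_a}

    def _dfs(node: str, length: int) -> None:
        nonlocal count, shortest, longest
        for nb in g[node]:
            nl = length + 1
            if nb == gene_b:
                count += 1
                if shortest is None or nl < shortest:
                    shortest = nl
                if longest is None or nl > longest:
                    longest = nl
                if count >= count_cap:
                    raise _CountCapReached
                continue
            if nl >= max_len or nb in on_path:
                continue
            if dist.get(nb, math.inf) > max_len - nl:
                continue
            on_path.add(nb)
            _dfs(nb, nl)
            on_path.remove(nb)

    truncated = False
    try:
        _dfs(gene_a, 0)
    except _CountCapReached:
        truncated = True
    return PathEnumeration(count, shortest, longest, truncated)


@dataclass(frozen=True)
class PathStats:
    """Aggregated path statistics for one drug pair."""

    drugs: tuple[str, str]
    avg_paths: float
    shortest: int | None
    longest: int | None
    max_len: int
    truncated: bool
    detail: Mapping[tuple[str, str], PathEnumeration]

    @property
    def reachable(self) -> bool:
        return self.avg_paths > 0


def pair_path_stats(drug_a: str, drug_b: str, targets: DrugTargetMap,
                    ppi: PPINetwork,
                    max_len: int = DEFAULT_MAX_LEN,
                    count_cap: int = DEFAULT_COUNT_CAP) -> PathStats:
    """Avg/S/L path statistics between the target sets of two drugs.

    Averages over the |G_a| x |G_b| ordered-as-written cross gene pairs; the
    census per unordered gene pair is computed once (paths are undirected).
    """
    ga = sorted(targets.targets(drug_a))
    gb = sorted(targets.targets(drug_b))
    cache: dict[frozenset[str], PathEnumeration] = {}
    detail: dict[tuple[str, str], PathEnumeration] = {}
    total = 0
    shortest: int | None = None
    longest: int | None = None
    truncated = False
    for gi in ga:
        for gj in gb:
            key = frozenset((gi, gj))
            if key not in cache:
                cache[key] = enumerate_paths(gi, gj, ppi, max_len=max_len,
                                             count_cap=count_cap)
            res = cache[key]
            detail[(gi, gj)] = res
            total += res.count
            truncated = truncated or res.truncated
            if res.shortest is not None and (shortest is None
                                             or res.shortest < shortest):
                shortest = res.shortest
            if res.longest is not None and (longest is None
                                            or res.longest > longest):
                longest = res.longest
    avg = total / (len(ga) * len(gb))
    return PathStats(drugs=(drug_a, drug_b), avg_paths=avg, shortest=shortest,
                     longest=longest, max_len=max_len, truncated=truncated,
                     detail=detail)


def _length_bucket(value: int | None) -> str:
    return UNREACHABLE if value is None else str(value)


def cohort_path_summary(interactions: InteractionSet,
                        targets: DrugTargetMap,
                        ppi: PPINetwork,
                        max_len: int = DEFAULT_MAX_LEN,
                        count_cap: int = DEFAULT_COUNT_CAP) -> dict[str, pd.DataFrame]:
    """Distribution tables of S, L and mean Avg per label class.

    Returns DataFrames ``shortest`` and ``longest`` (histograms with class
    columns) and ``avg`` (mean path count per class) for
    interacting-vs-non-interacting comparison.
    """
    interactions.resolve_in(targets)
    class_names = {POSITIVE: "interacting", NEGATIVE: "non_interacting"}
    s_hist: dict[str, dict[str, int]] = {}
    l_hist: dict[str, dict[str, int]] = {}
    avg_acc: dict[str, list[float]] = {name: [] for name in class_names.values()}
    for a, b, label in interactions:
        stats = pair_path_stats(a, b, targets, ppi, max_len=max_len,
                                count_cap=count_cap)
        cname = class_names[label]
        s_hist.setdefault(_length_bucket(stats.shortest), {}).setdefault(cname, 0)
        s_hist[_length_bucket(stats.shortest)][cname] += 1
        l_hist.setdefault(_length_bucket(stats.longest), {}).setdefault(cname, 0)
        l_hist[_length_bucket(stats.longest)][cname] += 1
        avg_acc[cname].append(stats.avg_paths)

    def _hist_frame(hist: dict[str, dict[str, int]]) -> pd.DataFrame:
        order = sorted((k for k in hist if k != UNREACHABLE), key=int)
        if UNREACHABLE in hist:
            order.append(UNREACHABLE)
        rows = [{"length": k,
                 "interacting": hist[k].get("interacting", 0),
                 "non_interacting": hist[k].get("non_interacting", 0)}
                for k in order]
        return pd.DataFrame(rows, columns=["length", "interacting",
                                           "non_interacting"])

    avg_rows = [{"class": name,
                 "mean_avg_paths": (sum(vals) / len(vals)) if vals else NA_FLOAT,
                 "n_pairs": len(vals)}
                for name, vals in avg_acc.items()]
    return {"shortest": _hist_frame(s_hist),
            "longest": _hist_frame(l_hist),
            "avg": pd.DataFrame(avg_rows)}


NA_FLOAT = float("nan")


def write_pair_stats(rows: Iterable[tuple[str, str, float, PathStats]],
                     path: str) -> None:
    """Per-pair TSV: drug_a, drug_b, jaccard, avg_paths, S, L, truncated."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_a\tdrug_b\tjaccard\tavg_paths\tshortest\tlongest"
                 "\ttruncated\n")
        for a, b, jac, stats in rows:
            fh.write(f"{a}\t{b}\t{jac:.6f}\t{stats.avg_paths:.6f}\t"
                     f"{_length_bucket(stats.shortest)}\t"
                     f"{_length_bucket(stats.longest)}\t"
                     f"{int(stats.truncated)}\n")
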