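"""Drug target-profile feature construction.

The feature space is the *gene universe* G: the union of target genes over a
drug roster, with a fixed position per gene. A drug d is represented by the
binary indicator vector V_d over G (1 where the gene is targeted), and a drug
pair (d1, d2) by the elementwise sum V_d1 + V_d2, so entries take values in
{0, 1, 2} and a 2 marks a common target gene. Genes outside the universe are
discarded, which keeps train- and test-time feature descriptors identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .io import DrugTargetMap, InteractionSet, UnknownDrugError, canonical_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered gene universe fixing feature positions (0-based, contiguous)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicate symbols")
        if not self.genes:
            raise ValueError("gene universe is empty")

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def fingerprint(self) -> str:
        """SHA-256 of the ordered gene list; identifies the feature space."""
        payload = "\n".join(self.genes).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index


@dataclass(frozen=True)
class DrugProfile:
    """Binary target profile of one drug as sparse (position, value) entries."""

    drug: str
    entries: tuple[tuple[int, int], ...]
    n_genes: int

    def dense(self) -> np.ndarray:
        v = np.zeros(self.n_genes, dtype=np.int8)
        for pos, val in self.entries:
            v[pos] = val
        return v


@dataclass(frozen=True)
class PairProfile:
    """Combined target profile of a drug pair; entries in {1, 2} at nonzeros."""

    drugs: tuple[str, str]
    entries: tuple[tuple[int, int], ...]
    n_genes: int

    def dense(self) -> np.ndarray:
        v = np.zeros(self.n_genes, dtype=np.int8)
        for pos, val in self.entries:
            v[pos] = val
        return v


def build_universe(targets: DrugTargetMap,
                   drugs: Iterable[str] | None = None) -> GeneUniverse:
    """Union of target gene sets over *drugs* (default: all), sorted.

    Lexicographic ordering makes feature positions independent of input file
    line order.
    """
    roster = list(drugs) if drugs is not None else list(targets.drugs)
    if not roster:
        raise ValueError("cannot build a gene universe from an empty drug list")
    union: set[str] = set()
    for drug in roster:
        union |= targets.targets(drug)
    if not union:
        raise ValueError("drug roster yields an empty gene universe")
    return GeneUniverse(tuple(sorted(union)))


def vectorize_drug(drug: str, targets: DrugTargetMap,
                   universe: GeneUniverse) -> DrugProfile:
    """Binary indicator vector of *drug* over the universe order.

    Target genes absent from the universe are discarded; a drug whose targets
    all fall outside yields an all-zero profile (logged).
    """
    index = universe.index
    positions = sorted(index[g] for g in targets.targets(drug) if g in index)
    if not positions:
        logger.warning(
            "drug %s has no target genes inside the universe; zero profile", drug)
    return DrugProfile(drug, tuple((p, 1) for p in positions), len(universe))


def vectorize_pair(drug_a: str, drug_b: str, targets: DrugTargetMap,
                   universe: GeneUniverse) -> PairProfile:
    """Elementwise sum of the two drug profiles (symmetric in its arguments)."""
    if drug_a == drug_b:
        raise ValueError(f"self-pair ({drug_a!r}, {drug_a!r}) cannot be vectorized")
    pa = vectorize_drug(drug_a, targets, universe)
    pb = vectorize_drug(drug_b, targets, universe)
    combined: dict[int, int] = {}
    for pos, val in pa.entries + pb.entries:
        combined[pos] = combined.get(pos, 0) + val
    entries = tuple(sorted(combined.items()))
    return PairProfile(canonical_pair(drug_a, drug_b), entries, len(universe))


def build_design_matrix(
    pairs: InteractionSet | Sequence[tuple[str, str, int]],
    targets: DrugTargetMap,
    universe: GeneUniverse,
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse row-per-pair feature matrix (CSR) with aligned label vector.

    Row order follows the input pair order.
    """
    records = list(pairs)
    if not records:
        raise ValueError("cannot build a design matrix from an empty pair list")
    unresolved = sorted({d for a, b, _ in records for d in (a, b)
                         if d not in targets})
    if unresolved:
        raise UnknownDrugError(
            f"pairs reference drugs absent from the drug->target map: {unresolved}")

    index = universe.index
    profile_cache: dict[str, list[int]] = {}

    def _positions(drug: str) -> list[int]:
        if drug not in profile_cache:
            profile_cache[drug] = sorted(
                index[g] for g in targets.targets(drug) if g in index)
        return profile_cache[drug]

    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    labels = np.empty(len(records), dtype=np.int64)
    for row, (a, b, label) in enumerate(records):
        combined: dict[int, int] = {}
        for pos in _positions(a):
            combined[pos] = combined.get(pos, 0) + 1
        for pos in _positions(b):
            combined[pos] = combined.get(pos, 0) + 1
        for pos in sorted(combined):
            indices.append(pos)
            data.append(combined[pos])
        indptr.append(len(indices))
        labels[row] = label
    X = sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64),
         np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(records), len(universe)))
    return X, labels
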