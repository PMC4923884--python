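"""Adaptive partitioning of a gene network into functional modules.

The algorithm is hub-seeded: the k highest-degree genes (hubs) each
define an initialized module — the hub plus its direct neighbors. Every
maximal collection of pairwise-disjoint initialized modules is a seed
module set. For each seed set, the remaining initialized modules are
merged one by one into the seed-derived module with which they overlap
most (the target is updated after every merge). Each candidate partition
is scored by the average pairwise intersection cardinality E; the
partition(s) with minimal E — the best-separated modules — are returned.
All orderings and tie-breaks are deterministic so a run is reproducible
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import DataError, NoSeedSetError
from .network import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InitializedModule:
    """A hub gene together with its direct network neighbors."""

    hub: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.hub not in self.members:
            raise DataError(f"hub {self.hub!r} must be a member of its own module")

    @property
    def hub_degree(self) -> int:
        return len(self.members) - 1


@dataclass(frozen=True)
class SeedModuleSet:
    """At least two pairwise-disjoint initialized modules."""

    seeds: tuple[InitializedModule, ...]

    def __post_init__(self) -> None:
        if len(self.seeds) < 2:
            raise DataError("a seed module set needs at least 2 modules")
        for a, b in combinations(self.seeds, 2):
            if a.members & b.members:
                raise DataError(
                    f"seed modules of hubs {a.hub!r} and {b.hub!r} are not disjoint"
                )

    @property
    def hubs(self) -> tuple[str, ...]:
        return tuple(m.hub for m in self.seeds)


@dataclass(frozen=True)
class MergeStep:
    merged_hub: str
    target_hub: str | None  # None => became a standalone module
    overlap: float


@dataclass(frozen=True)
class ModulePartition:
    """A candidate partition: final modules, provenance, and score E."""

    modules: tuple[frozenset[str], ...]
    module_hubs: tuple[str, ...]
    source_seed_set: SeedModuleSet
    avg_overlap: float
    merge_log: tuple[MergeStep, ...]

    def module_key(self) -> frozenset[frozenset[str]]:
        return frozenset(self.modules)


def select_hubs(net: GeneNetwork, k: int = 20) -> list[str]:
    """The k genes of largest degree, sorted by (degree desc, id asc)."""
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    deg = net.degree()
    positive = [g for g, d in deg.items() if d >= 1]
    if len(positive) < k:
        raise DataError(
            f"only {len(positive)} nodes have degree >= 1; reduce k from {k}"
        )
    ranked = sorted(positive, key=lambda g: (-deg[g], g))
    if len(ranked) > k and deg[ranked[k - 1]] == deg[ranked[k]]:
        logger.info(
            "select_hubs: degree tie at rank %d (degree %d) broken lexicographically",
            k, deg[ranked[k - 1]],
        )
    return ranked[:k]


def initialize_modules(net: GeneNetwork, hubs: Sequence[str]) -> list[InitializedModule]:
    """One module per hub: the hub plus its direct neighbors, in hub order."""
    missing = [h for h in hubs if h not in net.graph]
    if missing:
        raise DataError(f"hubs absent from network: {missing}")
    return [
        InitializedModule(hub=h, members=frozenset({h}) | frozenset(net.graph.neighbors(h)))
        for h in hubs
    ]


def enumerate_seed_sets(
    mods: Sequence[InitializedModule],
    maximal: bool = True,
) -> list[SeedModuleSet]:
    """All collections of >=2 pairwise-disjoint initialized modules.

    By default only maximal collections (maximal cliques of the
    disjointness graph over the modules) are returned, so redundant
    sub-collections do not inflate the candidate list. With
    ``maximal=False`` every disjoint collection of size >=2 is returned,
    for sensitivity analysis. Ordering is deterministic by sorted hub ids.
    An empty result means "no seed set".
    """
    if len(mods) < 2:
        raise DataError("seed-set enumeration needs at least 2 initialized modules")
    g = nx.Graph()
    g.add_nodes_from(range(len(mods)))
    for i, j in combinations(range(len(mods)), 2):
        if not (mods[i].members & mods[j].members):
            g.add_edge(i, j)
    if maximal:
        cliques = [c for c in nx.find_cliques(g) if len(c) >= 2]
    else:
        cliques = [c for c in nx.enumerate_all_cliques(g) if len(c) >= 2]
    sets = []
    for c in cliques:
        seeds = tuple(sorted((mods[i] for i in c), key=lambda m: m.hub))
        sets.append(SeedModuleSet(seeds=seeds))
    sets.sort(key=lambda s: s.hubs)
    return sets


def _overlap(a: frozenset[str], b: frozenset[str] | set[str], measure: str) -> float:
    inter = len(a & b)
    if measure == "cardinality":
        return float(inter)
    if measure == "jaccard":
        union = len(a | b)
        return inter / union if union else 0.0
    raise DataError(f"unknown overlap measure {measure!r}")


def merge_remaining(
    seed_set: SeedModuleSet,
    all_mods: Sequence[InitializedModule],
    orphan_policy: str = "merge",
    overlap: str = "cardinality",
) -> ModulePartition:
    """Merge every non-seed initialized module into the seed-derived modules.

    Remainder modules are processed in deterministic order (hub degree
    descending, then hub id); each is absorbed by set-union into the
    current module with maximal overlap, ties going to the module whose
    seed hub has the higher degree, then the smaller hub id. The targets
    are updated after every merge. A remainder overlapping nothing is
    still merged into the tie-break module under the default policy, or
    kept as a standalone module under ``orphan_policy="standalone"``.
    """
    if orphan_policy not in {"merge", "standalone"}:
        raise DataError(f"unknown orphan policy {orphan_policy!r}")
    for seed in seed_set.seeds:
        if seed not in all_mods:
            raise DataError(f"seed module of hub {seed.hub!r} is not among the initialized modules")

    current: list[set[str]] = [set(m.members) for m in seed_set.seeds]
    hub_of: list[str] = list(seed_set.hubs)
    degree_of: list[int] = [m.hub_degree for m in seed_set.seeds]
    remainder = sorted(
        (m for m in all_mods if m not in seed_set.seeds),
        key=lambda m: (-m.hub_degree, m.hub),
    )
    log: list[MergeStep] = []
    for r in remainder:
        scores = [_overlap(r.members, cur, overlap) for cur in current]
        best = max(scores)
        if best == 0 and orphan_policy == "standalone":
            logger.warning(
                "merge_remaining: module of hub %r overlaps no seed module; kept standalone",
                r.hub,
            )
            current.append(set(r.members))
            hub_of.append(r.hub)
            degree_of.append(r.hub_degree)
            log.append(MergeStep(merged_hub=r.hub, target_hub=None, overlap=0.0))
            continue
        tied = [i for i, sc in enumerate(scores) if sc == best]
        target = min(tied, key=lambda i: (-degree_of[i], hub_of[i]))
        if best == 0:
            logger.warning(
                "merge_remaining: module of hub %r overlaps no seed module; "
                "merged into %r by tie-break", r.hub, hub_of[target],
            )
        current[target] |= r.members
        log.append(MergeStep(merged_hub=r.hub, target_hub=hub_of[target], overlap=best))

    modules = tuple(frozenset(m) for m in current)
    return ModulePartition(
        modules=modules,
        module_hubs=tuple(hub_of),
        source_seed_set=seed_set,
        avg_overlap=average_overlap(modules),
        merge_log=tuple(log),
    )


def average_overlap(modules: Sequence[frozenset[str]] | Sequence[set[str]]) -> float:
    """E = sum of pairwise intersection cardinalities / C(alpha, 2)."""
    alpha = len(modules)
    if alpha < 2:
        raise DataError(f"average overlap needs >= 2 modules, got {alpha}")
    total = sum(len(set(a) & set(b)) for a, b in combinations(modules, 2))
    return total / comb(alpha, 2)


@dataclass
class PartitionResult:
    best: list[ModulePartition]
    all_partitions: list[ModulePartition]
    e_table: pd.DataFrame

    def write_e_table(self, path: str | Path) -> None:
        self.e_table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def partition_network(
    net: GeneNetwork,
    k: int = 20,
    orphan_policy: str = "merge",
    overlap: str = "cardinality",
    maximal_seed_sets: bool = True,
) -> PartitionResult:
    """Run the full partition: hubs -> modules -> seed sets -> merge -> min E.

    Every seed set is grown into a candidate partition; all partitions
    attaining the minimal average overlap E are returned (distinct seed
    sets can yield the same minimal E and even identical module sets;
    duplicates by module-set equality are removed).
    """
    hubs = select_hubs(net, k=k)
    mods = initialize_modules(net, hubs)
    seed_sets = enumerate_seed_sets(mods, maximal=maximal_seed_sets)
    if not seed_sets:
        raise NoSeedSetError(
            "no pairwise-disjoint initialized modules: the network admits no seed "
            "set; re-run the penalty scan with a different grid"
        )
    parts = [
        merge_remaining(ss, mods, orphan_policy=orphan_policy, overlap=overlap)
        for ss in seed_sets
    ]
    e_table = pd.DataFrame(
        {
            "seed_hubs": [";".join(p.source_seed_set.hubs) for p in parts],
            "n_modules": [len(p.modules) for p in parts],
            "avg_overlap_E": [p.avg_overlap for p in parts],
        }
    )
    e_min = min(p.avg_overlap for p in parts)
    best, seen = [], set()
    for p in parts:
        if p.avg_overlap > e_min + 1e-12:
            continue
        key = p.module_key()
        if key in seen:
            continue
        seen.add(key)
        best.append(p)
    return PartitionResult(best=best, all_partitions=parts, e_table=e_table)


def write_modules_gmt(partition: ModulePartition, path: str | Path, prefix: str = "module") -> None:
    """Write final modules as a GMT gene-set file (name, seed hub, genes)."""
    with open(path, "w") as fh:
        for i, (module, hub) in enumerate(zip(partition.modules, partition.module_hubs), 1):
            genes = "\t".join(sorted(module))
            fh.write(f"{prefix}_{i}\tseed_hub={hub}\t{genes}\n")


def read_modules_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file back as {module name: gene list}."""
    modules: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise DataError(f"GMT line {i + 1} has fewer than 3 fields")
            modules[parts[0]] = parts[2:]
    return modules


def write_merge_log(partition: ModulePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("merged_hub\ttarget_hub\toverlap\n")
        for step in partition.merge_log:
            target = step.target_hub if step.target_hub is not None else "<standalone>"
            fh.write(f"{step.merged_hub}\t{target}\t{step.overlap:.6g}\n")
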