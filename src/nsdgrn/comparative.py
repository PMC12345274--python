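"""Cross-species target comparison and the merged rewiring network.

Two species' regulator-associated gene sets are partitioned into
ortholog-shared targets and species-specific targets. Sharedness
requires the ortholog PAIR to have both ends associated: a gene whose
ortholog exists but is not a regulator target in the other species
counts as species-specific. Many-to-many ortholog relations are dropped
rather than expanded, so the partition counts pairs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .models import NsdgrnError

logger = logging.getLogger("nsdgrn.comparative")


def filter_one_to_one(pairs: Iterable[Tuple[str, str]]) -> List[Tuple[str, str]]:
    """Reduce a raw ortholog list to its one-to-one core.

    Every pair involving an id that occurs in more than one pair (on
    either side) is dropped; the dropped count is logged.
    """
    pairs = list(pairs)
    count_a = Counter(a for a, _ in pairs)
    count_b = Counter(b for _, b in pairs)
    kept = [(a, b) for a, b in pairs if count_a[a] == 1 and count_b[b] == 1]
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("filter_one_to_one: dropped %d pairs involved in many-to-many relations", dropped)
    return kept


@dataclass(frozen=True)
class TargetPartition:
    shared_pairs: Tuple[Tuple[str, str], ...]
    specific_a: frozenset
    specific_b: frozenset

    @property
    def n_shared(self) -> int:
        return len(self.shared_pairs)


def partition_targets(
    associated_a: Iterable[str],
    associated_b: Iterable[str],
    ortholog_map: Sequence[Tuple[str, str]],
) -> TargetPartition:
    """Partition two associated-gene sets into shared and specific targets.

    shared = ortholog pairs with both ends associated; specific_A =
    associated_A minus the A-side of shared (and symmetrically for B), so
    |shared| + |specific_A| = |associated_A| always holds.
    """
    _require_one_to_one(ortholog_map)
    set_a, set_b = set(associated_a), set(associated_b)
    shared = tuple(
        sorted((a, b) for a, b in ortholog_map if a in set_a and b in set_b)
    )
    shared_a = {a for a, _ in shared}
    shared_b = {b for _, b in shared}
    partition = TargetPartition(
        shared_pairs=shared,
        specific_a=frozenset(set_a - shared_a),
        specific_b=frozenset(set_b - shared_b),
    )
    logger.info(
        "partition_targets: %d shared pairs, %d A-specific, %d B-specific",
        partition.n_shared, len(partition.specific_a), len(partition.specific_b),
    )
    return partition


def _require_one_to_one(pairs: Sequence[Tuple[str, str]]) -> None:
    count_a = Counter(a for a, _ in pairs)
    count_b = Counter(b for _, b in pairs)
    bad = [a for a, n in count_a.items() if n > 1] + [b for b, n in count_b.items() if n > 1]
    if bad:
        raise NsdgrnError(
            f"ortholog map is not one-to-one; offending ids: {sorted(set(bad))[:10]}"
        )


def build_comparative_network(
    grn_a: nx.Graph,
    grn_b: nx.Graph,
    partition: TargetPartition,
    regulator_a: str,
    regulator_b: str,
    merged_regulator_id: str = "NsdD",
) -> nx.Graph:
    """Merge two species networks into one comparative rewiring network.

    Each shared ortholog pair collapses into a single node carrying both
    ids (node attribute ``id_a`` / ``id_b``, ``side='shared'``); the two
    regulator nodes merge into one central node connected to its targets
    from both species. Remaining nodes carry ``side`` 'A_specific' or
    'B_specific' and edges carry provenance 'A', 'B' or 'both'. Species
    gene namespaces must be disjoint apart from ortholog pairings.
    """
    pair_a_to_merged = {a: f"{a}|{b}" for a, b in partition.shared_pairs}
    pair_b_to_merged = {b: f"{a}|{b}" for a, b in partition.shared_pairs}

    nodes_a = set(grn_a.nodes) - {regulator_a}
    nodes_b = set(grn_b.nodes) - {regulator_b}
    collisions = (nodes_a & nodes_b) - (set(pair_a_to_merged) & set(pair_b_to_merged))
    if collisions:
        raise NsdgrnError(
            "species gene namespaces collide without an ortholog pairing: "
            f"{sorted(collisions)[:10]}"
        )

    def map_a(n: str) -> str:
        if n == regulator_a:
            return merged_regulator_id
        return pair_a_to_merged.get(n, n)

    def map_b(n: str) -> str:
        if n == regulator_b:
            return merged_regulator_id
        return pair_b_to_merged.get(n, n)

    merged = nx.Graph()
    merged.add_node(merged_regulator_id, side="regulator", origin="regulator")
    for n, data in grn_a.nodes(data=True):
        if n == regulator_a:
            continue
        node = map_a(n)
        side = "shared" if n in pair_a_to_merged else "A_specific"
        merged.add_node(node, side=side, id_a=n, origin=data.get("origin", ""))
    for n, data in grn_b.nodes(data=True):
        if n == regulator_b:
            continue
        node = map_b(n)
        if node in merged:
            merged.nodes[node]["id_b"] = n
            if merged.nodes[node].get("side") != "shared":
                merged.nodes[node]["side"] = "B_specific"
        else:
            merged.add_node(node, side="B_specific", id_b=n, origin=data.get("origin", ""))

    for u, v, data in grn_a.edges(data=True):
        mu, mv = map_a(u), map_a(v)
        merged.add_edge(mu, mv, provenance="A", kind=data.get("kind", "ppi"))
    for u, v, data in grn_b.edges(data=True):
        mu, mv = map_b(u), map_b(v)
        if merged.has_edge(mu, mv):
            merged[mu][mv]["provenance"] = "both"
        else:
            merged.add_edge(mu, mv, provenance="B", kind=data.get("kind", "ppi"))
    logger.info(
        "build_comparative_network: %d nodes, %d edges (%d shared pairs merged)",
        merged.number_of_nodes(), merged.number_of_edges(), partition.n_shared,
    )
    return merged
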