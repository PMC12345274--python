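"""Regulator-centered network construction on a PPI backbone.

The network backbone keeps every confidence-filtered protein-protein
association whose BOTH endpoints are regulator-associated genes (bound
and/or differentially expressed), layered with explicit direct-binding
edges from the regulator to each ChIP-bound gene. Guilt-by-association
expansion then adds the first neighbors of backbone nodes (depth 1,
never neighbors-of-neighbors), and a small core subnetwork of roughly 30
genes is extracted around chosen seed regulators for interpretation.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import pandas as pd

from .models import NsdgrnError, TargetClassification

logger = logging.getLogger("nsdgrn.grn")

CATEGORIES = (
    "vegetative growth",
    "asexual development",
    "sexual development",
    "primary metabolism",
    "secondary metabolism",
    "transcription regulation",
    "unannotated",
)

ORIGIN_CHIP = "chip"
ORIGIN_RNA = "rna"
ORIGIN_BOTH = "both"
ORIGIN_NEIGHBOR = "neighbor"
ORIGIN_REGULATOR = "regulator"


def load_ppi(
    source: Union[str, Path, pd.DataFrame],
    min_confidence: float = 150.0,
) -> pd.DataFrame:
    """Load a STRING-style PPI edge table and apply the confidence floor.

    Input columns: node_a, node_b, confidence (header optional when read
    from file). Edges with confidence >= the threshold are kept
    (inclusive); unordered duplicate pairs are collapsed keeping the
    maximum confidence; self-loops are dropped.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = ["node_a", "node_b", "confidence"]
    else:
        path = Path(source)
        with open(path) as fh:
            first = fh.readline()
        fields = first.rstrip("\n").split("\t")
        has_header = len(fields) >= 3 and not _is_number(fields[2])
        df = pd.read_csv(
            path, sep="\t", header=0 if has_header else None,
            names=["node_a", "node_b", "confidence"],
            usecols=[0, 1, 2], dtype={0: str, 1: str},
        )
        bad = df.index[pd.to_numeric(df["confidence"], errors="coerce").isna()]
        if len(bad):
            lineno = int(bad[0]) + (2 if has_header else 1)
            raise NsdgrnError(f"{path.name}:{lineno}: malformed confidence value")
    df["confidence"] = df["confidence"].astype(float)
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    df = df[df["node_a"] != df["node_b"]]
    df = df[df["confidence"] >= min_confidence]
    # canonical unordered pair, then keep the max-confidence duplicate
    lo = df[["node_a", "node_b"]].min(axis=1)
    hi = df[["node_a", "node_b"]].max(axis=1)
    df = df.assign(node_a=lo, node_b=hi)
    df = (
        df.sort_values("confidence", kind="stable")
        .drop_duplicates(["node_a", "node_b"], keep="last")
        .sort_values(["node_a", "node_b"], kind="stable", ignore_index=True)
    )
    logger.info("load_ppi: %d edges at confidence >= %g", len(df), min_confidence)
    return df[["node_a", "node_b", "confidence"]]


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def build_backbone(
    edges: pd.DataFrame,
    classification: TargetClassification,
    regulator_id: str,
    keep_isolated: bool = True,
) -> nx.Graph:
    """Network backbone: PPI edges with both endpoints regulator-associated,
    plus a direct-binding star from the regulator to every bound gene.

    Node ``origin`` is 'both' for direct targets, 'chip' for bound-only,
    'rna' for DEG-only, and 'regulator' for the regulator node itself.
    Isolated associated genes are retained as nodes by default.
    """
    assoc = classification.associated
    g = nx.Graph()
    if keep_isolated:
        for gene in assoc:
            g.add_node(gene)
    for _, row in edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a in assoc and b in assoc:
            g.add_edge(a, b, kind="ppi", confidence=float(row["confidence"]))
    g.add_node(regulator_id)
    for gene in classification.putative_direct:
        if g.has_edge(regulator_id, gene):
            g[regulator_id][gene]["kind"] = "direct_binding"
        else:
            g.add_edge(regulator_id, gene, kind="direct_binding")
    _set_origins(g, classification, regulator_id)
    logger.info(
        "build_backbone: %d nodes, %d edges (%d direct-binding)",
        g.number_of_nodes(), g.number_of_edges(),
        sum(1 for *_, d in g.edges(data=True) if d["kind"] == "direct_binding"),
    )
    return g


def _set_origins(g: nx.Graph, classification: TargetClassification, regulator_id: str) -> None:
    for node in g.nodes:
        if node == regulator_id:
            origin = ORIGIN_REGULATOR
        elif node in classification.direct:
            origin = ORIGIN_BOTH
        elif node in classification.putative_direct:
            origin = ORIGIN_CHIP
        elif node in classification.degs:
            origin = ORIGIN_RNA
        else:
            origin = ORIGIN_NEIGHBOR
        g.nodes[node]["origin"] = origin
        g.nodes[node].setdefault("category", "unannotated")
        g.nodes[node].setdefault("is_seed", False)


def gba_expand(backbone: nx.Graph, full_edges: pd.DataFrame) -> nx.Graph:
    """Guilt-by-association expansion: add first neighbors of the backbone.

    ``full_edges`` must already be confidence-filtered. Every node
    adjacent to a backbone node is added (origin 'neighbor'), together
    with the edges connecting it to the backbone. Exactly depth 1:
    neighbors of neighbors are never added, and edges among two added
    neighbors are not included.
    """
    g = backbone.copy()
    backbone_nodes = set(backbone.nodes)
    for _, row in full_edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        a_in, b_in = a in backbone_nodes, b in backbone_nodes
        if not (a_in or b_in):
            continue
        for node in (a, b):
            if node not in g:
                g.add_node(node, origin=ORIGIN_NEIGHBOR, category="unannotated",
                           is_seed=False)
        if not g.has_edge(a, b):
            g.add_edge(a, b, kind="ppi", confidence=float(row["confidence"]))
    added = g.number_of_nodes() - backbone.number_of_nodes()
    logger.info("gba_expand: %d neighbor nodes added (depth 1)", added)
    return g


def extract_core(
    grn: nx.Graph,
    seed_regulators: Iterable[str],
    size_target: int,
    regulator_id: str,
) -> nx.Graph:
    """Extract a core subnetwork of about ``size_target`` genes.

    Always contains the regulator and every (present) seed; the remaining
    slots are filled with neighbors of the seeds ranked by degree in the
    full network (descending) with lexicographic gene-id tie-breaks, then
    the induced subgraph on the selection is returned. Deterministic.
    """
    seeds = sorted(set(seed_regulators))
    present = [s for s in seeds if s in grn]
    missing = sorted(set(seeds) - set(present))
    if missing:
        warnings.warn(f"extract_core: seeds not in network, dropped: {missing}")
    if size_target < len(present) + 1:
        raise NsdgrnError(
            f"extract_core: size_target {size_target} < |seeds| + 1 = {len(present) + 1}"
        )
    if regulator_id not in grn:
        raise NsdgrnError(f"extract_core: regulator {regulator_id!r} not in network")
    selected: List[str] = [regulator_id] + [s for s in present if s != regulator_id]
    chosen = set(selected)
    candidates = set()
    for seed in present:
        candidates.update(grn.neighbors(seed))
    candidates -= chosen
    ranked = sorted(candidates, key=lambda n: (-grn.degree(n), n))
    for node in ranked:
        if len(selected) >= size_target:
            break
        selected.append(node)
        chosen.add(node)
    core = grn.subgraph(selected).copy()
    for node in core.nodes:
        core.nodes[node]["is_seed"] = node in present or node == regulator_id
    logger.info(
        "extract_core: %d nodes selected (target %d, %d seeds)",
        core.number_of_nodes(), size_target, len(present),
    )
    return core


def annotate_categories(grn: nx.Graph, category_map: Mapping[str, str]) -> nx.Graph:
    """Attach functional-category labels to nodes.

    Labels must come from the fixed palette (vegetative growth, asexual
    development, sexual development, primary metabolism, secondary
    metabolism, transcription regulation, unannotated); an unknown label
    is a hard error. Unmapped genes are labelled 'unannotated'.
    """
    bad = {lbl for lbl in category_map.values() if lbl not in CATEGORIES}
    if bad:
        raise NsdgrnError(
            f"annotate_categories: unknown category label(s) {sorted(bad)}; "
            f"allowed: {', '.join(CATEGORIES)}"
        )
    g = grn.copy()
    for node in g.nodes:
        g.nodes[node]["category"] = category_map.get(node, "unannotated")
    return g


def core_table(core: nx.Graph) -> pd.DataFrame:
    """Tabular view of a core subnetwork: node, origin, category, is_seed, degree."""
    rows = [
        {
            "node": n,
            "origin": d.get("origin", ""),
            "category": d.get("category", "unannotated"),
            "is_seed": bool(d.get("is_seed", False)),
            "degree": core.degree(n),
        }
        for n, d in sorted(core.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["node", "origin", "category", "is_seed", "degree"])
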