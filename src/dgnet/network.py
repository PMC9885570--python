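"""Bipartite drug-gene networks, per-gene degree scores and the gene partition.

The landscape model has two binary layers over the same drug and gene
universes: a *target* layer (drug i physically binds the protein of gene j,
indicator t_ij) and a *sensitive* layer (treatment with drug i significantly
perturbs gene j's expression, indicator s_ij).  A gene's KDTN is its degree in
the target layer, Sigma_i t_ij; its KDSN is its degree in the sensitive layer,
Sigma_i s_ij.  Thresholding the two scores at >= 1 splits scored genes into
three disjoint sets: DTG (target only), DSG (sensitive only) and DTSG (both).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

TARGET = "target"
SENSITIVE = "sensitive"
LAYERS = (TARGET, SENSITIVE)


@dataclass(frozen=True)
class LayeredNetwork:
    """Bipartite drug-gene graph with typed edges.

    Edges are triples ``(drug, gene, layer)`` with ``layer`` in
    ``{"target", "sensitive"}``.  A pair that is both bound and sensitive
    contributes two distinct typed edges, keeping KDTN and KDSN independent
    sums.  ``drugs`` / ``genes`` may include isolated nodes (e.g. after a
    round trip through GraphML), but builders never create them.
    """

    edges: frozenset[tuple[str, str, str]]
    drugs: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        for d, g, layer in self.edges:
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r} on edge ({d}, {g})")
            if d not in self.drugs or g not in self.genes:
                raise ValueError(f"edge ({d}, {g}, {layer}) references unknown node")
        if self.drugs & self.genes:
            raise ValueError(
                f"node ids used as both drug and gene: {sorted(self.drugs & self.genes)[:5]}"
            )

    @property
    def layers(self) -> frozenset[str]:
        return frozenset(layer for _, _, layer in self.edges)

    def layer_view(self, layer: str) -> "LayeredNetwork":
        """Single-layer view: edges of ``layer``, dropping isolated nodes."""
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        edges = frozenset(e for e in self.edges if e[2] == layer)
        return LayeredNetwork(
            edges=edges,
            drugs=frozenset(d for d, _, _ in edges),
            genes=frozenset(g for _, g, _ in edges),
        )

    def edge_pairs(self, layer: str) -> frozenset[tuple[str, str]]:
        return frozenset((d, g) for d, g, lay in self.edges if lay == layer)

    def to_networkx(
        self, partition: "GeneSetPartition | None" = None
    ) -> nx.MultiGraph:
        """Export as a MultiGraph with ``kind``/``set`` node and ``layer`` edge attrs."""
        graph = nx.MultiGraph()
        labels = partition.labels() if partition is not None else {}
        for d in sorted(self.drugs):
            graph.add_node(d, kind="drug", set="none")
        for g in sorted(self.genes):
            graph.add_node(g, kind="gene", set=labels.get(g, "none"))
        for d, g, layer in sorted(self.edges):
            graph.add_edge(d, g, key=layer, layer=layer)
        return graph

    def n_nodes(self) -> int:
        return len(self.drugs) + len(self.genes)


@dataclass(frozen=True)
class GeneScores:
    """Per-gene layer degrees: KDTN (target layer) and KDSN (sensitive layer).

    Genes absent from a layer score 0 in it; every gene known to either layer
    has an entry in both mappings.
    """

    kdtn: Mapping[str, int]
    kdsn: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.kdtn) != set(self.kdsn):
            raise ValueError("kdtn and kdsn must cover the same gene set")
        for table in (self.kdtn, self.kdsn):
            for g, k in table.items():
                if k < 0 or int(k) != k:
                    raise ValueError(f"degree scores are non-negative integers: {g}={k}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.kdtn)

    def __len__(self) -> int:
        return len(self.kdtn)


@dataclass(frozen=True)
class GeneSetPartition:
    """Disjoint split of scored genes: DTG (KDTN>=1 only), DSG (KDSN>=1 only), DTSG (both)."""

    dtg: frozenset[str]
    dsg: frozenset[str]
    dtsg: frozenset[str]

    def __post_init__(self) -> None:
        if self.dtg & self.dsg or self.dtg & self.dtsg or self.dsg & self.dtsg:
            raise ValueError("partition sets must be pairwise disjoint")

    def labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, members in (("DTG", self.dtg), ("DSG", self.dsg), ("DTSG", self.dtsg)):
            out.update({g: name for g in members})
        return out

    def sizes(self) -> dict[str, int]:
        return {"DTG": len(self.dtg), "DSG": len(self.dsg), "DTSG": len(self.dtsg)}


def build_layer(pairs: Iterable[tuple[str, str]], layer: str) -> LayeredNetwork:
    """Build a single-layer bipartite network from (drug, gene) pairs.

    One node per distinct drug/gene, one typed edge per distinct pair.
    Degenerate inputs (empty pairs) produce degenerate networks.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    pairset = frozenset((d, g) for d, g in pairs)
    return LayeredNetwork(
        edges=frozenset((d, g, layer) for d, g in pairset),
        drugs=frozenset(d for d, _ in pairset),
        genes=frozenset(g for _, g in pairset),
    )


def merge_layers(dtn: LayeredNetwork, dsn: LayeredNetwork) -> LayeredNetwork:
    """Merge single-layer DTN and DSN into one multidimensional network.

    Node sets are unions; the edge set is the disjoint-by-layer union, so a
    (drug, gene) pair present in both layers contributes two typed edges.
    """
    if dtn.layers - {TARGET}:
        raise ValueError("first argument must be a pure target-layer network")
    if dsn.layers - {SENSITIVE}:
        raise ValueError("second argument must be a pure sensitive-layer network")
    return LayeredNetwork(
        edges=dtn.edges | dsn.edges,
        drugs=dtn.drugs | dsn.drugs,
        genes=dtn.genes | dsn.genes,
    )


def compute_gene_scores(net: LayeredNetwork) -> GeneScores:
    """Exact per-gene layer degrees over all genes in the network."""
    kdtn = Counter(g for _, g, layer in net.edges if layer == TARGET)
    kdsn = Counter(g for _, g, layer in net.edges if layer == SENSITIVE)
    genes = net.genes
    return GeneScores(
        kdtn={g: kdtn.get(g, 0) for g in genes},
        kdsn={g: kdsn.get(g, 0) for g in genes},
    )


def partition_genes(scores: GeneScores) -> GeneSetPartition:
    """Split scored genes into DTG / DSG / DTSG by thresholding both scores at >= 1.

    Genes with both scores 0 belong to no set (they are unscored background).
    """
    dtg, dsg, dtsg = set(), set(), set()
    for g in scores.genes:
        t, s = scores.kdtn[g], scores.kdsn[g]
        if t >= 1 and s >= 1:
            dtsg.add(g)
        elif t >= 1:
            dtg.add(g)
        elif s >= 1:
            dsg.add(g)
    part = GeneSetPartition(frozenset(dtg), frozenset(dsg), frozenset(dtsg))
    logger.info("partition sizes: %s", part.sizes())
    return part


def sample_drug_subnetwork(
    net: LayeredNetwork, drug_fraction: float, seed: int
) -> LayeredNetwork:
    """Seeded uniform sample of round(fraction x #drugs) drugs (min 1) plus
    all their gene neighbours in both layers (subgraph induced on the drug
    subset).  Rounding is half-up.
    """
    if not net.drugs:
        raise ValueError("network has no drugs to sample")
    if not 0 < drug_fraction <= 1:
        raise ValueError(f"drug_fraction must be in (0, 1], got {drug_fraction}")
    n = max(1, int(math.floor(drug_fraction * len(net.drugs) + 0.5)))
    rng = np.random.default_rng(seed)
    chosen = frozenset(rng.choice(sorted(net.drugs), size=n, replace=False).tolist())
    edges = frozenset(e for e in net.edges if e[0] in chosen)
    return LayeredNetwork(
        edges=edges,
        drugs=frozenset(d for d, _, _ in edges) or chosen,
        genes=frozenset(g for _, g, _ in edges),
    )
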