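"""m-core peeling decomposition of a single network layer.

The m-core of a layer is the maximal subgraph in which every *gene* keeps a
layer degree of at least m; it is obtained by iteratively peeling genes whose
current degree falls below m and then dropping drugs left without edges,
until a fixed point.  The constraint applies to gene nodes only, because the
scores being decomposed (KDTN, KDSN) are gene-side degrees; drug nodes
persist while they retain at least one edge.  All connected components of
the fixed point are kept (maximality then holds per component), with a
largest-component-only mode available.

Peeling is order-independent: the fixed point is the unique maximal gene set
satisfying the constraint, so any deletion order yields the same core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .network import LayeredNetwork, LAYERS


@dataclass(frozen=True)
class MCoreDecomposition:
    """Per-gene core numbers and per-m core summaries for one layer.

    ``cores[m]`` holds (gene members, drug members, #components) of the
    m-core; cores are nested: cores[m+1] genes are a subset of cores[m] genes.
    ``core_number[g]`` is the largest m whose core contains g.
    """

    layer: str
    core_number: Mapping[str, int]
    cores: Mapping[int, tuple[frozenset[str], frozenset[str], int]]
    m_max: int

    def __post_init__(self) -> None:
        ms = sorted(self.cores)
        for lo, hi in zip(ms, ms[1:]):
            if not self.cores[hi][0] <= self.cores[lo][0]:
                raise ValueError("core nesting violated")


def _single_layer(net: LayeredNetwork) -> str:
    layers = net.layers
    if len(layers) != 1:
        raise ValueError(f"expected a single-layer network, got layers {sorted(layers)}")
    return next(iter(layers))


def m_core(
    net: LayeredNetwork,
    m: int,
    strict: bool = False,
    largest_component_only: bool = False,
) -> LayeredNetwork:
    """The m-core of a single-layer network (possibly empty).

    Iteratively deletes genes with layer degree < m (<= m when ``strict``,
    i.e. the 'greater than m' reading), then drugs with no remaining edges,
    to a fixed point.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    layer = _single_layer(net) if net.edges else None
    threshold = m + 1 if strict else m

    gene_adj: dict[str, set[str]] = {g: set() for g in net.genes}
    drug_adj: dict[str, set[str]] = {d: set() for d in net.drugs}
    for d, g, _ in net.edges:
        gene_adj[g].add(d)
        drug_adj[d].add(g)

    changed = True
    while changed:
        changed = False
        for g in [g for g, ds in gene_adj.items() if len(ds) < threshold]:
            for d in gene_adj.pop(g):
                drug_adj[d].discard(g)
            changed = True
        for d in [d for d, gs in drug_adj.items() if not gs]:
            del drug_adj[d]

    edges = frozenset(
        (d, g, layer) for g, ds in gene_adj.items() for d in ds
    )
    core = LayeredNetwork(
        edges=edges,
        drugs=frozenset(drug_adj),
        genes=frozenset(gene_adj),
    )
    if largest_component_only and core.edges:
        graph = nx.Graph((d, g) for d, g, _ in core.edges)
        giant = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
        edges = frozenset(e for e in core.edges if e[0] in giant)
        core = LayeredNetwork(
            edges=edges,
            drugs=frozenset(d for d, _, _ in edges),
            genes=frozenset(g for _, g, _ in edges),
        )
    return core


def _n_components(core: LayeredNetwork) -> int:
    if not core.edges:
        return 0
    graph = nx.Graph((d, g) for d, g, _ in core.edges)
    return nx.number_connected_components(graph)


def peel_decomposition(
    net: LayeredNetwork, strict: bool = False, largest_component_only: bool = False
) -> MCoreDecomposition:
    """Full decomposition: m-cores for m = 1..m_max and per-gene core numbers."""
    if not net.edges:
        raise ValueError("cannot decompose an empty network")
    layer = _single_layer(net)

    cores: dict[int, tuple[frozenset[str], frozenset[str], int]] = {}
    core_number: dict[str, int] = {}
    m = 1
    while True:
        core = m_core(net, m, strict=strict, largest_component_only=largest_component_only)
        if not core.genes:
            break
        cores[m] = (core.genes, core.drugs, _n_components(core))
        for g in core.genes:
            core_number[g] = m
        m += 1
    if not cores:
        raise ValueError("no gene survives the m=1 core (network has no gene with degree >= 1)")
    for g in net.genes:
        core_number.setdefault(g, 0)
    return MCoreDecomposition(
        layer=layer, core_number=core_number, cores=cores, m_max=max(cores)
    )


def core_profile(dec: MCoreDecomposition) -> pd.DataFrame:
    """One row per m: (m, n_genes, n_drugs, n_components); gene counts non-increasing."""
    rows = [
        {"m": m, "n_genes": len(genes), "n_drugs": len(drugs), "n_components": ncomp}
        for m, (genes, drugs, ncomp) in sorted(dec.cores.items())
    ]
    return pd.DataFrame(rows, columns=["m", "n_genes", "n_drugs", "n_components"])


def cores_as_gene_sets(dec: MCoreDecomposition) -> dict[str, frozenset[str]]:
    """Core gene membership per m as a GMT-ready mapping (term 'm=K')."""
    return {f"m={m}": genes for m, (genes, _, _) in sorted(dec.cores.items())}
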