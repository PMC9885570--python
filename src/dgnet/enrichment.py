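"""Set-level statistics: hypergeometric over-representation analysis,
cross-set term-overlap accounting and TF binding-frequency summaries.

ORA tests each library term for over-representation in a query gene set
against a background universe with the one-sided upper-tail hypergeometric
probability, then controls the FDR across terms within the library by
Benjamini-Hochberg.  The TF summary counts, for every gene of a set, how many
TF target sets contain it; the per-gene mean is the set's TF binding
frequency (the dual-layer landscape contrasts sensitive genes, which are
densely regulated, with target genes, which are not).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics."""

    term: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    fdr: float


@dataclass(frozen=True)
class TFFrequencySummary:
    """TF binding-frequency profile of one gene set."""

    mean_tfs_per_gene: float
    tf_set: frozenset[str]
    per_tf_coverage: Mapping[str, int]  # TF term -> #genes of the set it covers
    per_gene_counts: Mapping[str, int]  # gene -> #TF sets containing it


def hypergeometric_ora(
    query: Iterable[str],
    universe: Iterable[str],
    library: GeneSetLibrary,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA of ``query`` against every library term.

    Terms are restricted to the universe before testing; only terms with at
    least one overlapping gene are reported.  BH-FDR is computed across all
    tested terms of the library; results are sorted by p (ties by term id).
    ``fdr_threshold`` only filters the returned list; pass 1.0 to keep all.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        offenders = sorted(query - universe)
        raise ValueError(f"query genes outside the universe: {offenders[:10]}")
    if not len(library):
        raise ValueError("empty gene-set library")

    big_n, n = len(universe), len(query)
    rows: list[tuple[str, int, int, float]] = []
    for term, (_, members) in library.sets.items():
        in_universe = members & universe
        k_term = len(in_universe)
        if k_term == 0:
            continue
        overlap = len(in_universe & query)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, k_term, n))
        rows.append((term, overlap, k_term, min(p, 1.0)))
    if not rows:
        return []
    fdr = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term=term,
            overlap=overlap,
            set_size=n,
            term_size=k_term,
            universe_size=big_n,
            p=p,
            fdr=float(q),
        )
        for (term, overlap, k_term, p), q in zip(rows, fdr)
        if overlap >= 1
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return [r for r in results if r.fdr <= fdr_threshold or fdr_threshold >= 1.0]


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term", "overlap", "set_size", "term_size", "universe_size", "p", "fdr"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)


def term_overlap(
    results_per_set: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-set accounting of significant terms.

    Returns a per-term table (term, one boolean column per set, n_sets) and
    summary counts: total distinct terms and terms hit by >= 2 sets.
    """
    if len(results_per_set) < 2:
        raise ValueError("need at least two result sets to compare")
    sets = {name: frozenset(terms) for name, terms in results_per_set.items()}
    all_terms = sorted(frozenset().union(*sets.values()))
    rows = []
    for term in all_terms:
        hit = {name: term in members for name, members in sets.items()}
        rows.append({"term": term, **hit, "n_sets": sum(hit.values())})
    table = pd.DataFrame(rows, columns=["term", *sets, "n_sets"])
    summary = {
        "n_terms_total": len(all_terms),
        "n_terms_shared": int((table["n_sets"] >= 2).sum()) if all_terms else 0,
    }
    return table, summary


def tf_binding_frequency(
    gene_set: Iterable[str], tf_library: GeneSetLibrary
) -> TFFrequencySummary:
    """Per-gene TF-set membership counts and their mean over the gene set.

    A gene absent from every TF target set contributes 0; the distinct TFs
    touching the set are returned for cross-set comparisons.
    """
    genes = frozenset(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    per_gene = {g: 0 for g in genes}
    per_tf: dict[str, int] = {}
    for tf, (_, members) in tf_library.sets.items():
        covered = members & genes
        if covered:
            per_tf[tf] = len(covered)
            for g in covered:
                per_gene[g] += 1
    return TFFrequencySummary(
        mean_tfs_per_gene=float(np.mean(list(per_gene.values()))),
        tf_set=frozenset(per_tf),
        per_tf_coverage=per_tf,
        per_gene_counts=per_gene,
    )
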