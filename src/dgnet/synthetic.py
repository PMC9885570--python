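"""Synthetic drug-gene landscapes with planted ground truth.

Emulates the statistical structure of a public drug-signature database's
target (D1-style) and expression-signature (D3-style) layers so every
pipeline stage is testable without downloads:

* heavy-tailed gene-side degree sequences in both layers (truncated discrete
  power laws realized exactly);
* a target gene set and a sensitive gene set whose intersection (the planted
  dual DTSG set) is a configurable fraction of the target set and small
  relative to the sensitive set;
* optional reciprocity: on shared genes the two planted degree sequences are
  coupled by rank reversal, so strong target hubs tend to be weak sensitive
  hubs (``anti_correlation`` in [-1, 0]);
* expression tables in which planted sensitive pairs pass the calling
  thresholds (clean mode: with certainty; noisy mode: with narrowed margins
  and fold-change-plausible null records);
* annotation/TF libraries with terms oversampling a named gene set by a
  planted effect factor.

Everything is deterministic in ``spec.seed``: the same spec yields
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .io import (
    DrugTargetTable,
    GeneSetLibrary,
    SignatureTable,
    make_signature_table,
    write_drug_target_table,
    write_signature_table,
    write_gmt,
)
from .signatures import SignatureCalls, SignatureCallingConfig


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic landscape.

    Defaults are a ~1/10-scale rendition of the real landscape's shape:
    40 drugs over 950 genes, 72 target genes of which 64% are also sensitive,
    923 sensitive genes, gene-side degree exponents ~2.2 (target) and ~1.9
    (sensitive, denser layer), and mild reciprocity (-0.5).
    """

    n_drugs: int = 40
    n_genes: int = 950
    n_target_genes: int | None = None  # default: 7.6% of n_genes
    n_sensitive_genes: int | None = None  # default: 97.2% of n_genes
    target_degree_alpha: float = 2.2
    sensitive_degree_alpha: float = 1.9
    overlap_fraction: float = 0.64
    anti_correlation: float = -0.5
    mode: str = "clean"
    n_null_per_drug: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_genes < 1:
            raise ValueError("need at least one drug and one gene")
        # landscape-shaped defaults: target/sensitive set sizes proportional
        # to the gene universe
        if self.n_target_genes is None:
            object.__setattr__(self, "n_target_genes", max(1, _round_half_up(0.076 * self.n_genes)))
        if self.n_sensitive_genes is None:
            object.__setattr__(self, "n_sensitive_genes", max(1, _round_half_up(0.972 * self.n_genes)))
        if not (0 < self.n_target_genes <= self.n_genes):
            raise ValueError("n_target_genes must be in [1, n_genes]")
        if not (0 < self.n_sensitive_genes <= self.n_genes):
            raise ValueError("n_sensitive_genes must be in [1, n_genes]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        n_shared = _round_half_up(self.overlap_fraction * self.n_target_genes)
        if n_shared > self.n_sensitive_genes:
            raise ValueError(
                "overlap_fraction demands more shared genes than the sensitive set holds"
            )
        if (self.n_target_genes - n_shared) + self.n_sensitive_genes > self.n_genes:
            raise ValueError("target and sensitive sets do not fit into n_genes")
        if not -1.0 <= self.anti_correlation <= 0.0:
            raise ValueError("anti_correlation must be in [-1, 0]")
        if self.mode not in ("clean", "noisy"):
            raise ValueError("mode must be 'clean' or 'noisy'")
        for alpha in (self.target_degree_alpha, self.sensitive_degree_alpha):
            if alpha <= 1.0:
                raise ValueError("degree exponents must exceed 1")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Exact discrete power-law sampling

def sample_zeta(
    alpha: float,
    size: int,
    rng: np.random.Generator,
    xmin: int = 1,
    kmax: int | None = None,
) -> np.ndarray:
    """Exact samples from the discrete power law p(k) proportional to k^-alpha, k >= xmin.

    Inverse-CDF sampling against the Hurwitz-zeta CCDF, with a table for the
    bulk and per-sample bisection for the far tail.  ``kmax`` truncates the
    support (resampling interpretation: the law conditioned on k <= kmax).
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1 for a normalizable law")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    if kmax is not None and kmax < xmin:
        raise ValueError("kmax must be >= xmin")

    table_top = 1 << 16
    ks = np.arange(xmin, xmin + table_top, dtype=float)
    norm = special.zeta(alpha, xmin)
    ccdf = special.zeta(alpha, ks) / norm  # descending, ccdf[0] = 1

    lo = 0.0 if kmax is None else float(special.zeta(alpha, kmax + 1) / norm)
    u = rng.uniform(low=lo, high=1.0, size=size)

    # largest k with CCDF(k) >= u  <=>  last table index where ccdf >= u
    idx = np.searchsorted(-ccdf, -u, side="right") - 1
    out = (xmin + idx).astype(np.int64)

    beyond = u < ccdf[-1]
    for i in np.flatnonzero(beyond):
        out[i] = _zeta_tail_quantile(float(u[i]), alpha, xmin, norm)
    if kmax is not None:
        out = np.minimum(out, kmax)  # only reachable via float ties at the bound
    return out


def _zeta_tail_quantile(u: float, alpha: float, xmin: int, norm: float) -> int:
    """Largest k with zeta(alpha, k)/norm >= u, via doubling + bisection."""
    lo = xmin
    hi = max(2 * xmin, 2)
    while special.zeta(alpha, hi) / norm >= u:
        lo, hi = hi, hi * 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if special.zeta(alpha, mid) / norm >= u:
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Landscape plan: gene roles and coupled planted degree sequences

@dataclass(frozen=True)
class LandscapePlan:
    """Deterministic planted truth shared by both generated layers."""

    drugs: tuple[str, ...]
    genes: tuple[str, ...]
    target_genes: tuple[str, ...]
    sensitive_genes: tuple[str, ...]
    shared_genes: tuple[str, ...]
    kdtn: Mapping[str, int]  # planted target-layer degree, target genes only
    kdsn: Mapping[str, int]  # planted sensitive-layer degree, sensitive genes only

    def partition_sizes(self) -> dict[str, int]:
        shared = set(self.shared_genes)
        return {
            "DTG": len(set(self.target_genes) - shared),
            "DSG": len(set(self.sensitive_genes) - shared),
            "DTSG": len(shared),
        }


def _truncated_zeta(
    alpha: float, size: int, kmax: int, rng: np.random.Generator
) -> np.ndarray:
    """Power-law degrees conditioned on <= kmax, by rejection resampling."""
    out = sample_zeta(alpha, size, rng)
    for _ in range(1000):
        bad = out > kmax
        if not bad.any():
            return out
        out[bad] = sample_zeta(alpha, int(bad.sum()), rng)
    raise ValueError(
        f"could not realize a degree sequence <= {kmax} after 1000 resampling rounds"
    )


def landscape_plan(spec: SyntheticSpec) -> LandscapePlan:
    """Assign gene roles and planted degree sequences, coupled on shared genes."""
    rng = np.random.default_rng([spec.seed, 0])
    width = max(4, len(str(spec.n_genes)))
    genes = tuple(f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1))
    drugs = tuple(f"D{i:04d}" for i in range(1, spec.n_drugs + 1))

    order = rng.permutation(spec.n_genes)
    n_shared = _round_half_up(spec.overlap_fraction * spec.n_target_genes)
    n_target_only = spec.n_target_genes - n_shared
    shared = tuple(genes[i] for i in order[:n_shared])
    target_only = tuple(genes[i] for i in order[n_shared : n_shared + n_target_only])
    sens_only = tuple(
        genes[i]
        for i in order[
            n_shared + n_target_only : n_target_only + spec.n_sensitive_genes
        ]
    )
    target_genes = shared + target_only
    sensitive_genes = shared + sens_only

    kdtn_seq = _truncated_zeta(
        spec.target_degree_alpha, len(target_genes), spec.n_drugs, rng
    )
    kdsn_seq = _truncated_zeta(
        spec.sensitive_degree_alpha, len(sensitive_genes), spec.n_drugs, rng
    )

    kdtn = dict(zip(target_genes, kdtn_seq.tolist()))

    # Reciprocity on shared genes: a |anti_correlation| fraction of them gets
    # its sensitive degree by rank reversal against its target degree; the
    # rest (and all sensitive-only genes) draw independently.
    kdsn: dict[str, int] = {}
    shared_kdsn = kdsn_seq[: len(shared)].tolist()
    if shared:
        n_coupled = _round_half_up(abs(spec.anti_correlation) * len(shared))
        coupled_idx = rng.choice(len(shared), size=n_coupled, replace=False)
        coupled = [shared[i] for i in sorted(coupled_idx)]
        free = [g for g in shared if g not in set(coupled)]
        # coupled: largest planted KDTN gets the smallest planted KDSN
        by_kdtn = sorted(coupled, key=lambda g: (-kdtn[g], g))
        degrees_sorted = sorted(shared_kdsn[: len(coupled)])
        for g, d in zip(by_kdtn, degrees_sorted):
            kdsn[g] = d
        rest = shared_kdsn[len(coupled) :]
        rng.shuffle(rest)
        for g, d in zip(free, rest):
            kdsn[g] = d
    kdsn.update(zip(sens_only, kdsn_seq[len(shared) :].tolist()))

    return LandscapePlan(
        drugs=drugs,
        genes=genes,
        target_genes=tuple(sorted(target_genes)),
        sensitive_genes=tuple(sorted(sensitive_genes)),
        shared_genes=tuple(sorted(shared)),
        kdtn=kdtn,
        kdsn=kdsn,
    )


def _realize_incidence(
    degrees: Mapping[str, int], drugs: Sequence[str], rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Realize gene-side degrees exactly: each gene picks that many distinct drugs."""
    drug_arr = np.asarray(drugs)
    pairs: set[tuple[str, str]] = set()
    for gene in sorted(degrees):
        chosen = rng.choice(drug_arr, size=degrees[gene], replace=False)
        pairs.update((str(d), gene) for d in chosen)
    return pairs


def generate_target_table(
    spec: SyntheticSpec, plan: LandscapePlan | None = None
) -> tuple[DrugTargetTable, dict[str, int]]:
    """Drug-target incidence realizing the planted KDTN sequence exactly.

    Every drug is guaranteed at least one target (a drug without targets
    would not enter the landscape); repair edges added for empty drugs are
    reflected in the returned planted degrees, which therefore always equal
    the degrees recomputable from the emitted table.
    """
    plan = plan or landscape_plan(spec)
    rng = np.random.default_rng([spec.seed, 1])
    pairs = _realize_incidence(plan.kdtn, plan.drugs, rng)
    kdtn = dict(plan.kdtn)
    covered = {d for d, _ in pairs}
    for drug in plan.drugs:
        if drug not in covered:
            gene = str(rng.choice(np.asarray(plan.target_genes)))
            pairs.add((drug, gene))
            kdtn[gene] += 1
    return DrugTargetTable(frozenset(pairs)), kdtn


_CLEAN = {
    "up_fc": (2.2, 8.0), "down_fc": (0.1, 0.45), "hit_p": (0.0, 0.04),
    "null_fc": (0.6, 1.8), "null_p": (0.0, 1.0),
}
_NOISY = {
    "up_fc": (2.05, 8.0), "down_fc": (0.1, 0.48), "hit_p": (0.0, 0.049),
    "null_fc": (0.3, 3.0), "null_p": (0.0, 1.0),
}


def generate_signature_tables(
    spec: SyntheticSpec, plan: LandscapePlan | None = None
) -> tuple[SignatureTable, SignatureCalls]:
    """Expression records realizing the planted KDSN sequence.

    Planted sensitive pairs draw fold changes outside the (0.5, 2) window and
    adjusted p below 0.05; null pairs draw fold changes inside the window
    (clean mode) or straddling it (noisy mode) with uniform p.  In clean mode
    calling with the default thresholds recovers the planted pairs exactly.
    """
    plan = plan or landscape_plan(spec)
    rng = np.random.default_rng([spec.seed, 2])
    params = _CLEAN if spec.mode == "clean" else _NOISY

    planted = sorted(_realize_incidence(plan.kdsn, plan.drugs, rng))
    rows: list[tuple[str, str, float, float, float]] = []
    for drug, gene in planted:
        if rng.uniform() < 0.5:
            fc = float(rng.uniform(*params["up_fc"]))
        else:
            fc = float(rng.uniform(*params["down_fc"]))
        p_adj = float(rng.uniform(*params["hit_p"]))
        rows.append((drug, gene, fc, p_adj, p_adj))

    planted_by_drug: dict[str, set[str]] = {}
    for drug, gene in planted:
        planted_by_drug.setdefault(drug, set()).add(gene)
    gene_arr = np.asarray(plan.genes)
    for drug in plan.drugs:
        taken = planted_by_drug.get(drug, set())
        candidates = gene_arr[~np.isin(gene_arr, sorted(taken))]
        n_null = min(spec.n_null_per_drug, candidates.size)
        for gene in rng.choice(candidates, size=n_null, replace=False):
            fc = float(rng.uniform(*params["null_fc"]))
            p = float(rng.uniform(*params["null_p"]))
            rows.append((drug, str(gene), fc, p, p))

    table = make_signature_table(rows)
    calls = SignatureCalls(
        pairs=frozenset(planted),
        config=SignatureCallingConfig(adjust_method="none"),
        n_tested=len(rows),
    )
    return table, calls


def generate_annotation_library(
    planted_terms: Sequence[tuple[int, str, float]],
    spec: SyntheticSpec,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    n_background_terms: int = 20,
    background_term_size: int = 30,
    name: str = "synthetic-annotation",
    plan: LandscapePlan | None = None,
) -> GeneSetLibrary:
    """Annotation/TF library with planted enrichment.

    ``planted_terms`` holds (term_size, enriched_in, effect): members of the
    named gene set are oversampled by the effect factor (effect 1.0 is the
    null: uniform sampling).  ``gene_sets`` defaults to the plan's partition
    sets {"DTG", "DSG", "DTSG"}.  Background terms sample uniformly.
    """
    plan = plan or landscape_plan(spec)
    rng = np.random.default_rng([spec.seed, 3])
    if gene_sets is None:
        shared = set(plan.shared_genes)
        gene_sets = {
            "DTG": set(plan.target_genes) - shared,
            "DSG": set(plan.sensitive_genes) - shared,
            "DTSG": shared,
        }
    universe = np.asarray(plan.genes)

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, (term_size, enriched_in, effect) in enumerate(planted_terms, start=1):
        if not 0 < term_size <= len(universe):
            raise ValueError(f"term size {term_size} infeasible for {len(universe)} genes")
        if effect < 1.0:
            raise ValueError("effect must be >= 1 (oversampling factor)")
        if enriched_in not in gene_sets:
            raise ValueError(f"unknown gene set {enriched_in!r}")
        favored = frozenset(gene_sets[enriched_in])
        weights = np.where(np.isin(universe, sorted(favored)), effect, 1.0)
        weights /= weights.sum()
        members = rng.choice(universe, size=term_size, replace=False, p=weights)
        sets[f"PLANTED_{i}_{enriched_in}"] = (
            f"planted effect={effect}",
            frozenset(str(g) for g in members),
        )
    for i in range(1, n_background_terms + 1):
        size = min(background_term_size, len(universe))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"BG_{i:03d}"] = ("background", frozenset(str(g) for g in members))
    return GeneSetLibrary(name=name, sets=sets)


def write_synthetic_inputs(spec: SyntheticSpec, outdir: str | Path) -> dict[str, str]:
    """Emit a complete synthetic input bundle plus a truth manifest.

    Files: targets.tsv (two-column dialect), signatures.tsv, tf_library.gmt,
    annotation.gmt and manifest.json recording the spec and planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = landscape_plan(spec)
    targets, kdtn = generate_target_table(spec, plan)
    signatures, calls = generate_signature_tables(spec, plan)
    annotation = generate_annotation_library(
        [(30, "DTG", 6.0), (40, "DSG", 6.0), (30, "DTSG", 6.0)], spec, plan=plan,
        name="annotation",
    )
    tf_library = generate_annotation_library(
        [(25, "DSG", 8.0)] * 4 + [(25, "DTG", 2.0)], spec, plan=plan,
        n_background_terms=40, background_term_size=25, name="tf",
    )

    paths = {
        "targets": str(outdir / "targets.tsv"),
        "signatures": str(outdir / "signatures.tsv"),
        "annotation": str(outdir / "annotation.gmt"),
        "tf_library": str(outdir / "tf_library.gmt"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_drug_target_table(targets, paths["targets"])
    write_signature_table(signatures, paths["signatures"])
    write_gmt(annotation, paths["annotation"])
    write_gmt(tf_library, paths["tf_library"])

    manifest = {
        "spec": asdict(spec),
        "partition_sizes": plan.partition_sizes(),
        "planted_kdtn": {g: int(k) for g, k in sorted(kdtn.items())},
        "planted_kdsn": {g: int(k) for g, k in sorted(plan.kdsn.items())},
        "planted_calls": sorted(map(list, calls.pairs)),
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
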