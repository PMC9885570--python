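"""Signature calling: thresholding differential expression into binary s_ij.

A (drug, gene) pair is called drug-sensitive (s_ij = 1) when its adjusted
p-value is below the threshold AND its linear-scale fold change lies outside
the (fc_lower, fc_upper) window, i.e. adjusted p < 0.05 and FC > 2 or
FC < 0.5 with the defaults.  All inequalities are strict; boundary values are
not called.  Pairs absent from a drug's table are simply uncalled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import SignatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureCallingConfig:
    """Thresholds and adjustment policy for signature calling.

    fold changes are linear-scale; ``fc_lower``/``fc_upper`` default to the
    reciprocal pair (0.5, 2.0) so up- and downregulation are symmetric.
    ``adjust_method="none"`` requires precomputed adjusted p-values;
    ``"benjamini-hochberg"`` computes them from raw p, per drug by default
    (each drug's profile is its own testing family) or globally.
    """

    adjusted_p_threshold: float = 0.05
    fc_upper: float = 2.0
    fc_lower: float = 0.5
    adjust_method: str = "benjamini-hochberg"
    adjust_scope: str = "per-drug"

    def __post_init__(self) -> None:
        if not 0 < self.adjusted_p_threshold <= 1:
            raise ValueError("adjusted_p_threshold must be in (0, 1]")
        if not self.fc_lower < 1 < self.fc_upper:
            raise ValueError("need fc_lower < 1 < fc_upper (linear-scale window)")
        if self.adjust_method not in ("benjamini-hochberg", "none"):
            raise ValueError(f"unknown adjust_method {self.adjust_method!r}")
        if self.adjust_scope not in ("per-drug", "global"):
            raise ValueError(f"unknown adjust_scope {self.adjust_scope!r}")
        if abs(self.fc_lower * self.fc_upper - 1.0) > 1e-9:
            warnings.warn(
                "fc_lower and fc_upper are not reciprocal; up/down thresholds asymmetric",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SignatureCalls:
    """The called pairs (s_ij = 1) plus provenance."""

    pairs: frozenset[tuple[str, str]]
    config: SignatureCallingConfig
    n_tested: int


def adjust_pvalues(p: Sequence[float], method: str = "benjamini-hochberg") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    Output q_i = min_{j: p_(j) >= p_i sorted position} p_(j) * n / j, capped
    at 1; monotone in the input.
    """
    if method != "benjamini-hochberg":
        raise ValueError(f"unknown adjustment method {method!r}")
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_signatures(table: SignatureTable, config: SignatureCallingConfig) -> SignatureCalls:
    """Apply the thresholds to every record; deterministic and order-independent.

    With ``adjust_method="none"`` every record must already carry an adjusted
    p-value; otherwise raw p-values are BH-adjusted within the configured
    scope before thresholding.
    """
    df = table.records
    if len(df) == 0:
        return SignatureCalls(frozenset(), config, 0)

    if config.adjust_method == "none":
        missing = df["p_adj"].isna()
        if missing.any():
            bad = df.loc[missing].iloc[0]
            raise ValueError(
                f"adjust_method='none' but record ({bad['drug']}, {bad['gene']}) "
                "has no adjusted p-value"
            )
        p_adj = df["p_adj"].to_numpy()
    else:
        missing = df["p"].isna()
        if missing.any():
            bad = df.loc[missing].iloc[0]
            raise ValueError(
                f"BH adjustment requested but record ({bad['drug']}, {bad['gene']}) "
                "has no raw p-value"
            )
        p_adj = np.empty(len(df), dtype=float)
        if config.adjust_scope == "global":
            p_adj[:] = adjust_pvalues(df["p"].to_numpy())
        else:
            for _, idx in df.groupby("drug", sort=False).indices.items():
                p_adj[idx] = adjust_pvalues(df["p"].to_numpy()[idx])

    fc = df["fc"].to_numpy()
    called = (p_adj < config.adjusted_p_threshold) & (
        (fc > config.fc_upper) | (fc < config.fc_lower)
    )
    pairs = frozenset(
        (d, g) for d, g in df.loc[called, ["drug", "gene"]].itertuples(index=False)
    )
    logger.info("called %d of %d records", len(pairs), len(df))
    return SignatureCalls(pairs=pairs, config=config, n_tested=len(df))
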