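"""Flux enrichment analysis: hypergeometric over-representation of a hit
set (typically the essential reactions) within model subsystems.

For a subsystem of size n inside a universe of N reactions of which K are
hits, observing k hits in the subsystem has upper-tail probability
P(X >= k) under the hypergeometric null (drawing n reactions without
replacement).  Raw p-values are Benjamini-Hochberg adjusted across
subsystems by default; significance is declared at ``alpha`` (0.01 by
default) on the adjusted values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["flux_enrichment", "bh_adjust"]


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flux_enrichment(
    universe: dict[str, str],
    hits: set[str],
    alpha: float = 0.01,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``hits`` within subsystems.

    Parameters
    ----------
    universe
        Map reaction id -> subsystem label; defines both the population and
        the subsystem partition.  The caller chooses the universe (the
        pipeline default is all non-blocked reactions).
    hits
        Reaction ids to test for over-representation (must be a subset of
        the universe).
    adjust
        "bh" (default) or "none".

    Returns a table with one row per subsystem — hit count, subsystem size,
    raw and adjusted p, significance flag — sorted by adjusted p.
    """
    if not universe:
        raise ValueError("universe is empty")
    unknown = hits - set(universe)
    if unknown:
        raise ValueError(f"hit reaction(s) not in universe: {sorted(unknown)[:5]}")
    if adjust not in {"bh", "none"}:
        raise ValueError(f"unknown adjustment method {adjust!r}")

    N = len(universe)
    K = len(hits)
    rows = []
    subsystems = sorted({s for s in universe.values()})
    for sub in subsystems:
        members = [r for r, s in universe.items() if s == sub]
        n = len(members)
        k = sum(1 for r in members if r in hits)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sub, k, n, min(p_raw, 1.0)))

    table = pd.DataFrame(
        rows, columns=["subsystem", "n_hits", "subsystem_size", "p_raw"]
    )
    if adjust == "bh":
        table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["p_adjusted"] = table["p_raw"]
    table["significant"] = table["p_adjusted"] < alpha
    table = table.sort_values(
        ["p_adjusted", "p_raw", "subsystem"], kind="stable"
    ).reset_index(drop=True)
    return table
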