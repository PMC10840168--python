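"""Focal-gene neighborhood extraction and between-group edge comparison.

Partial-correlation graphs are undirected, so the neighborhood is a
breadth-first expansion over significant edges. Edge strengths are paired
between a reference network (where significance is assessed) and an
alternate network; pairs whose absolute strength difference exceeds a fixed
threshold (0.2 by default) are flagged as differential.
"""

from __future__ import annotations

import pandas as pd

from .errors import GlknetError
from .ggm import GGMNetwork


def extract_neighborhood(network: GGMNetwork, focal: str,
                         alpha: float = 0.01, steps: int = 5) -> set:
    """Genes reachable from ``focal`` within ``steps`` BFS expansions over
    edges with p < alpha. Includes the focal gene; order-independent."""
    if focal not in network.genes:
        raise GlknetError(f"focal gene {focal!r} not in network panel")
    if steps < 0:
        raise GlknetError("steps must be >= 0")
    index = {g: i for i, g in enumerate(network.genes)}
    selected = {focal}
    frontier = {focal}
    for _ in range(steps):
        nxt = set()
        for g in frontier:
            gi = index[g]
            for h, hi in index.items():
                if h not in selected and network.p_values[gi, hi] < alpha:
                    nxt.add(h)
        if not nxt:
            break
        selected |= nxt
        frontier = nxt
    return selected


def compare_edge_strengths(reference: GGMNetwork, alternate: GGMNetwork, genes,
                           alpha: float = 0.01,
                           delta_threshold: float = 0.2) -> pd.DataFrame:
    """Pair edge strengths between two networks over a gene subset.

    Every unordered pair within ``genes`` whose edge is significant
    (p < alpha) in the *reference* network is paired with its strength in the
    alternate network; delta = strength_ref - strength_alt; pairs with
    |delta| strictly above ``delta_threshold`` are flagged. Sorted by |delta|
    descending, ties by gene pair.

    Strengths are the networks' deattenuated partial correlations
    (pcor / (1 - lambda)): each network's own shrinkage factor is divided
    out so that strengths estimated at different sample sizes (hence
    different shrinkage intensities) are on a common scale.
    """
    genes = sorted(genes)
    for g in genes:
        if g not in reference.genes:
            raise GlknetError(f"gene {g!r} missing from reference network")
        if g not in alternate.genes:
            raise GlknetError(f"gene {g!r} missing from alternate network")
    rows = []
    for a_i, gi in enumerate(genes):
        for gj in genes[a_i + 1:]:
            if reference.p_of(gi, gj) < alpha:
                s_ref = reference.strength_of(gi, gj)
                s_alt = alternate.strength_of(gi, gj)
                delta = s_ref - s_alt
                rows.append((gi, gj, s_ref, s_alt, delta, abs(delta) > delta_threshold))
    out = pd.DataFrame(rows, columns=["gene_i", "gene_j", "strength_ref",
                                      "strength_alt", "delta", "flagged"])
    if len(out):
        out["abs_delta"] = out["delta"].abs()
        out = (
            out.sort_values(["abs_delta", "gene_i", "gene_j"],
                            ascending=[False, True, True])
            .drop(columns="abs_delta")
            .reset_index(drop=True)
        )
    return out
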