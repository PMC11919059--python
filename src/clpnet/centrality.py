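"""Expected-influence and bridge centrality for directed symptom networks.

All indices are computed on the coefficient (log-OR) scale, where an absent
edge contributes exactly 0; autoregressive paths are excluded throughout.

- out-EI(i): sum of i's outgoing cross-lagged coefficients.
- in-EI(j): sum of j's incoming cross-lagged coefficients.
- bridge-EI(i): the cross-community part — by default both the outgoing and
  incoming coefficients that connect i to nodes of the other diagnostic
  community; a switch restricts it to outgoing paths only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimate import SymptomNetwork


def expected_influence(network: SymptomNetwork) -> pd.DataFrame:
    """Per-node in-EI, out-EI and bridge-EI with per-index ranks (1 = highest)."""
    coef = network.coef
    out_ei = coef.sum(axis=1)
    in_ei = coef.sum(axis=0)
    bridge = bridge_expected_influence(network)
    table = pd.DataFrame({
        "node": network.nodes,
        "community": [network.community[n] for n in network.nodes],
        "in_ei": in_ei,
        "out_ei": out_ei,
        "bridge_ei": bridge,
    })
    for col in ("in_ei", "out_ei", "bridge_ei"):
        table[f"{col}_rank"] = table[col].rank(ascending=False, method="min").astype(int)
    return table


def bridge_expected_influence(network: SymptomNetwork,
                              direction: str = "both") -> np.ndarray:
    """Cross-community expected influence per node.

    ``direction='both'`` (default) sums outgoing and incoming cross-community
    coefficients; ``'out'`` counts outgoing only.
    """
    if direction not in ("both", "out"):
        raise ValueError("direction must be 'both' or 'out'")
    communities = [network.community.get(n) for n in network.nodes]
    if any(c is None for c in communities):
        raise ValueError("every node needs a community label")
    comm = np.asarray(communities)
    other = comm[:, None] != comm[None, :]          # [i, j] True if cross-community
    coef = network.coef
    out_part = (coef * other).sum(axis=1)
    if direction == "out":
        return out_part
    in_part = (coef * other).sum(axis=0)
    return out_part + in_part
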