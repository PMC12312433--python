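"""Expected-influence centrality for directed cross-lagged networks.

out-EI(i) sums the edges node i sends (how strongly it predicts the rest of
the network at follow-up); in-EI(j) sums the edges node j receives (how
predictable it is from the baseline network). Autoregressive self-loops are
excluded by default — they measure stability of a construct, not influence on
other constructs — but an ``include_self`` toggle covers the other
convention. Because both indices range over the same edge set, their totals
agree: sum(out-EI) == sum(in-EI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import CLPNetwork
from .panel import InputError


def out_expected_influence(net: CLPNetwork, include_self: bool = False) -> np.ndarray:
    """Per-node sum of outgoing edge weights (row sums of B, sans diagonal)."""
    out = net.B.sum(axis=1)
    if not include_self:
        out = out - np.diag(net.B)
    return out


def in_expected_influence(net: CLPNetwork, include_self: bool = False) -> np.ndarray:
    """Per-node sum of incoming edge weights (column sums of B, sans diagonal)."""
    inc = net.B.sum(axis=0)
    if not include_self:
        inc = inc - np.diag(net.B)
    return inc


@dataclass
class CentralityTable:
    """Per-node out-/in-expected influence with optional z-scores and ranks.

    Ranks are descending (rank 1 = largest value, ties averaged), matching
    how rank-order stability is assessed.
    """

    nodes: list[str]
    out_ei: np.ndarray
    in_ei: np.ndarray
    include_self: bool = False
    out_ei_z: Optional[np.ndarray] = None
    in_ei_z: Optional[np.ndarray] = None

    @property
    def out_rank(self) -> np.ndarray:
        return stats.rankdata(-self.out_ei)

    @property
    def in_rank(self) -> np.ndarray:
        return stats.rankdata(-self.in_ei)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "node": self.nodes,
                "out_ei": self.out_ei,
                "in_ei": self.in_ei,
                "out_rank": self.out_rank,
                "in_rank": self.in_rank,
            }
        )
        if self.out_ei_z is not None:
            df["out_ei_z"] = self.out_ei_z
            df["in_ei_z"] = self.in_ei_z
        return df


def centrality_table(net: CLPNetwork, include_self: bool = False) -> CentralityTable:
    return CentralityTable(
        nodes=list(net.node_names),
        out_ei=out_expected_influence(net, include_self),
        in_ei=in_expected_influence(net, include_self),
        include_self=include_self,
    )


def _zscore(values: np.ndarray, label: str) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise InputError(f"cannot standardize {label}: zero variance across nodes")
    return (values - values.mean()) / sd


def standardize_centrality(table: CentralityTable) -> CentralityTable:
    """Z-score each index across nodes (n-1 denominator)."""
    if len(table.nodes) < 2:
        raise InputError("standardization needs at least two nodes")
    return CentralityTable(
        nodes=list(table.nodes),
        out_ei=table.out_ei.copy(),
        in_ei=table.in_ei.copy(),
        include_self=table.include_self,
        out_ei_z=_zscore(table.out_ei, "out-EI"),
        in_ei_z=_zscore(table.in_ei, "in-EI"),
    )
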