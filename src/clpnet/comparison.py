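"""Agreement statistics between two group-specific networks.

Three complementary views: Pearson correlation of the vectorized edge
weights, the proportion of edges whose sign class differs ("direction
discordance"), and Pearson correlations of the centrality vectors. The
default edge set is the p*(p-1) directed cross-lagged entries including
exact zeros — under lasso selection an edge present in one group and absent
in the other is a substantive directional disagreement — with a
nonzero-union variant available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .centrality import CentralityTable
from .estimation import CLPNetwork
from .panel import InputError

EDGE_SETS = ("cross_lagged", "nonzero_union")


@dataclass
class ComparisonResult:
    edge_correlation: float
    edge_correlation_p: float
    discordance_proportion: float
    discordant_edges: int
    compared_edges: int
    edge_set: str
    out_ei_correlation: float | None = None
    out_ei_correlation_p: float | None = None
    in_ei_correlation: float | None = None
    in_ei_correlation_p: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _check_nodes(a: CLPNetwork, b: CLPNetwork) -> None:
    if list(a.node_names) != list(b.node_names):
        raise InputError(
            f"node sets differ: {a.node_names} vs {b.node_names}"
        )


def _edge_vectors(netA: CLPNetwork, netB: CLPNetwork, edge_set: str):
    _check_nodes(netA, netB)
    if edge_set not in EDGE_SETS:
        raise InputError(f"edge_set must be one of {EDGE_SETS}")
    p = netA.p
    off = ~np.eye(p, dtype=bool)
    a = netA.B[off]
    b = netB.B[off]
    if edge_set == "nonzero_union":
        keep = (a != 0) | (b != 0)
        a, b = a[keep], b[keep]
    return a, b


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.size < 3:
        raise InputError(f"need at least 3 paired values for a correlation, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("cannot correlate a constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def edge_list_correlation(
    netA: CLPNetwork, netB: CLPNetwork, edge_set: str = "cross_lagged"
) -> tuple[float, float]:
    """Pearson r (with two-tailed t-approximation p) between edge vectors."""
    a, b = _edge_vectors(netA, netB, edge_set)
    return _pearson(a, b)


def sign_discordance(
    netA: CLPNetwork, netB: CLPNetwork, edge_set: str = "cross_lagged"
) -> tuple[float, tuple[int, int]]:
    """Proportion of edges whose sign class differs between the networks.

    Exact zero is its own sign class, so presence-vs-absence counts as
    discordant. Returns (proportion, (discordant, compared)).
    """
    a, b = _edge_vectors(netA, netB, edge_set)
    if a.size == 0:
        raise InputError("empty edge set; nothing to compare")
    disc = int((np.sign(a) != np.sign(b)).sum())
    return disc / a.size, (disc, int(a.size))


def centrality_correlation(
    tabA: CentralityTable, tabB: CentralityTable, index: str = "out"
) -> tuple[float, float]:
    """Pearson correlation of per-node out- or in-EI between two networks.

    With p = 6 nodes these p values are low-powered by construction; report
    them as descriptive, as in the source analyses.
    """
    if list(tabA.nodes) != list(tabB.nodes):
        raise InputError(f"node sets differ: {tabA.nodes} vs {tabB.nodes}")
    if index not in ("out", "in"):
        raise InputError("index must be 'out' or 'in'")
    a = tabA.out_ei if index == "out" else tabA.in_ei
    b = tabB.out_ei if index == "out" else tabB.in_ei
    return _pearson(a, b)


def compare_networks(
    netA: CLPNetwork,
    netB: CLPNetwork,
    tabA: CentralityTable | None = None,
    tabB: CentralityTable | None = None,
    edge_set: str = "cross_lagged",
) -> ComparisonResult:
    """All agreement statistics between two networks in one report."""
    r, p = edge_list_correlation(netA, netB, edge_set)
    prop, (disc, total) = sign_discordance(netA, netB, edge_set)
    result = ComparisonResult(
        edge_correlation=r,
        edge_correlation_p=p,
        discordance_proportion=prop,
        discordant_edges=disc,
        compared_edges=total,
        edge_set=edge_set,
    )
    if tabA is not None and tabB is not None:
        result.out_ei_correlation, result.out_ei_correlation_p = centrality_correlation(
            tabA, tabB, "out"
        )
        result.in_ei_correlation, result.in_ei_correlation_p = centrality_correlation(
            tabA, tabB, "in"
        )
    return result
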