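"""Hub identification by the betweenness 2-SD rule.

A region is a hub when its betweenness centrality lies at least two standard
deviations above the mean nodal betweenness of the same network.  The z-score
uses the population standard deviation over the R nodal values (the network's
nodes are the full population, not a sample), and the boundary is inclusive
(z >= 2).  Hub detection is descriptive and is run at the minimum density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import betweenness, degrees
from .network import BinaryNetwork

__all__ = ["HubSet", "identify_hubs"]


@dataclass(frozen=True)
class HubSet:
    """Hub regions of one group network at one density."""

    group: str
    density: float
    hubs: tuple[tuple[str, float, float], ...]  # (region, betweenness, z)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hubs, columns=["region", "betweenness", "z"])

    def regions(self) -> list[str]:
        return [h[0] for h in self.hubs]


def identify_hubs(net: BinaryNetwork, *, z_threshold: float = 2.0) -> HubSet:
    """Regions whose betweenness is >= ``z_threshold`` SDs above the mean.

    Hub membership is invariant to any positive rescaling of betweenness.
    A network with zero betweenness variance (e.g. a complete graph) has no
    hubs; that case warns and returns an empty set rather than erroring.
    """
    if net.n_nodes < 3:
        raise ValueError("hub analysis needs >= 3 nodes")
    b = betweenness(net)
    sd = float(b.std())  # population SD: the nodes are the whole population
    if sd == 0:
        warnings.warn(
            "betweenness has zero variance (all nodes equivalent); no hubs",
            stacklevel=2,
        )
        return HubSet(group=net.group, density=net.density, hubs=())
    z = (b - b.mean()) / sd
    # inclusive boundary with a roundoff guard: z of exactly 2 must qualify
    idx = np.flatnonzero(z >= z_threshold - 1e-9)
    # descending z; ties by higher degree then label, mirroring attack ranking
    k = degrees(net)
    labels = np.asarray(net.labels)
    order = idx[np.lexsort((labels[idx], -k[idx].astype(float), -z[idx]))]
    hubs = tuple((str(labels[i]), float(b[i]), float(z[i])) for i in order)
    return HubSet(group=net.group, density=net.density, hubs=hubs)
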