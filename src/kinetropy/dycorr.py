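"""Dynamic correlation (DyCorr) maps: synchrony of exchange dynamics in
k_on - k_off rate space.

Each exchange-detected methyl becomes a point (k_on, k_off) =
(p_E k_ex, p_G k_ex), where p_E is the excited-state (minor) population and
p_G = 1 - p_E.  For a pair of points the relative distance is

    kappa_ij = |r_i - r_j| / |(r_i + r_j)/2|

i.e. the Euclidean separation normalized by the distance from the origin to
the pair midpoint.  Over the closed non-negative quadrant kappa has supremum
2, attained by points on the two axes equidistant from the origin (separation
d*sqrt(2), midpoint at distance d/sqrt(2)).  Relative proximity maps kappa to
[0, 1]:

    nonlinear: eta_ij = (kappa_m - kappa_ij) / (kappa_m (kappa_ij + 1))
    linear:    eta_ij = 1 - kappa_ij / 2

with kappa_m the maximum kappa observed in the dataset.  eta = 1 marks
synchronous (co-moving) residues, eta = 0 the most asynchronous pair.  The
normalization makes kappa, and hence the map, invariant to a global rescaling
of all rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cpmg import ExchangeFit
from .data_io import MethylId
from .errors import ValidationError

__all__ = ["RatePoint", "DyCorrMap", "rate_decomposition", "relative_distance",
           "proximity", "build_map", "synchrony_clusters"]

KAPPA_SUP = 2.0  # analytic supremum of kappa over the non-negative quadrant


@dataclass(frozen=True)
class RatePoint:
    """One methyl's position in k_on - k_off space."""

    methyl: MethylId | None
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValidationError("rates must be non-negative")

    @property
    def k_ex(self) -> float:
        return self.k_on + self.k_off

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.k_on, self.k_off])


@dataclass
class DyCorrMap:
    methyls: list[MethylId]
    kappa: np.ndarray            # relative distance, symmetric, zero diagonal
    eta: np.ndarray              # relative proximity, symmetric, unit diagonal
    kappa_m: float
    mode: str                    # "nonlinear" | "linear"
    excluded: list[MethylId] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{m.residue_type}{m.residue_number}-{m.methyl_label}"
                  for m in self.methyls]
        return pd.DataFrame(self.eta, index=labels, columns=labels)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.methyls)):
            for j in range(i + 1, len(self.methyls)):
                rows.append({"methyl_i": str(self.methyls[i]),
                             "methyl_j": str(self.methyls[j]),
                             "kappa": self.kappa[i, j],
                             "eta": self.eta[i, j]})
        return pd.DataFrame(rows)


def rate_decomposition(fit: ExchangeFit,
                       methyl: MethylId | None = None) -> RatePoint:
    """k_on = p_E k_ex, k_off = p_G k_ex with p_E = p_B (minor state)."""
    if not fit.exchange_detected:
        raise ValidationError("rate decomposition requires detected exchange")
    return RatePoint(methyl=methyl, k_on=fit.p_b * fit.k_ex,
                     k_off=(1.0 - fit.p_b) * fit.k_ex)


def relative_distance(a, b) -> float:
    """kappa: pair separation over origin-to-midpoint distance.

    Accepts RatePoints or 2-vectors in the non-negative quadrant.  Undefined
    (NaN) when both points sit at the origin."""
    pa = a.xy if isinstance(a, RatePoint) else np.asarray(a, dtype=float)
    pb = b.xy if isinstance(b, RatePoint) else np.asarray(b, dtype=float)
    if np.any(pa < 0) or np.any(pb < 0):
        raise ValidationError("rate points must lie in the non-negative quadrant")
    mid = 0.5 * (pa + pb)
    denom = float(np.hypot(*mid))
    if denom == 0.0:
        return float("nan")
    return float(np.hypot(*(pa - pb)) / denom)


def proximity(kappa: float, kappa_m: float, mode: str = "nonlinear") -> float:
    """Relative proximity eta in [0, 1] from a relative distance."""
    if not (0.0 <= kappa_m <= KAPPA_SUP + 1e-12):
        raise ValidationError(f"kappa_m must lie in [0, 2], got {kappa_m}")
    if kappa < 0 or kappa > kappa_m + 1e-12:
        raise ValidationError(f"kappa {kappa} outside [0, kappa_m={kappa_m}]")
    if mode == "nonlinear":
        if kappa_m == 0.0:
            return 1.0
        return (kappa_m - kappa) / (kappa_m * (kappa + 1.0))
    if mode == "linear":
        return 1.0 - 0.5 * kappa
    raise ValueError(f"unknown proximity mode {mode!r}")


def build_map(fits: dict[MethylId, ExchangeFit] | list[RatePoint],
              mode: str = "nonlinear") -> DyCorrMap:
    """Pairwise relative proximities over all exchange-detected methyls.

    kappa_m is the maximum observed relative distance in the dataset (not the
    theoretical supremum 2).  Methyls without detected exchange are excluded
    and listed on the returned map.
    """
    excluded: list[MethylId] = []
    points: list[RatePoint] = []
    if isinstance(fits, dict):
        for mid, fit in fits.items():
            if fit.exchange_detected:
                points.append(rate_decomposition(fit, mid))
            else:
                excluded.append(mid)
    else:
        points = list(fits)
    if len(points) < 2:
        raise ValidationError("DyCorr map needs >= 2 exchange-detected methyls")

    n = len(points)
    kappa = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            kappa[i, j] = kappa[j, i] = relative_distance(points[i], points[j])
    finite = kappa[np.isfinite(kappa)]
    kappa_m = float(finite.max()) if len(finite) else 0.0
    eta = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(kappa[i, j]):
                eta[i, j] = eta[j, i] = proximity(min(kappa[i, j], kappa_m),
                                                  kappa_m, mode)
            else:
                eta[i, j] = eta[j, i] = np.nan
    methyls = [p.methyl if p.methyl is not None
               else MethylId(i + 1, "I", "d1") for i, p in enumerate(points)]
    return DyCorrMap(methyls=methyls, kappa=kappa, eta=eta, kappa_m=kappa_m,
                     mode=mode, excluded=excluded)


def synchrony_clusters(dymap: DyCorrMap, cutoff: float = 0.9
                       ) -> list[set[MethylId]]:
    """Connected components of the graph with edges eta_ij > cutoff,
    largest first.  Singletons are returned too."""
    g = nx.Graph()
    g.add_nodes_from(range(len(dymap.methyls)))
    n = len(dymap.methyls)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dymap.eta[i, j]) and dymap.eta[i, j] > cutoff:
                g.add_edge(i, j)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    return [{dymap.methyls[i] for i in comp} for comp in comps]
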