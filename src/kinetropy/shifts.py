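"""Chemical-shift statistics across ligation states: perturbations (CSP),
CONCISE equilibrium positions and populations, and CHESCA covariance with the
maximum-vector-distance filter.

CSP combines proton and heteronuclear shift changes as
sqrt(ddH^2 + c * ddX^2) with c = 0.25 for 13C and 0.154 for 15N.

CONCISE treats each methyl's (dH, dC) trajectory across states as a 2-D point
cloud; a per-methyl PCA gives a dominant direction (PC1) and the spread
around it (PC2).  Methyls whose shifts respond linearly to a two-state
open <-> closed equilibrium have SD(PC1)/SD(PC2) above a threshold (default
3.0); weak responders (CSP < 0.05 ppm) are discarded.  PC1 scores normalized
between an open and a closed basis state yield one equilibrium position per
state (mean over kept methyls) which, read as a closed-state population p,
converts to a binding free-energy change through the two-state log-odds
ddG = -R T [ln(p/(1-p)) - ln(p_ref/(1-p_ref))].

CHESCA correlates full state-response vectors between residues: after the
max-vector-distance filter, each methyl's concatenated (dH, scaled dC)
profile is Pearson-correlated with every other; highly correlated pairs
(r > 0.9) trace the allosteric network and average-linkage clustering of
1 - r groups residues that respond together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .constants import R_KCAL
from .data_io import MethylId, StateShiftTable
from .errors import ValidationError

__all__ = ["CSP_SCALE", "csp", "max_vector_distance", "ChescaResult",
           "chesca", "ConciseResult", "concise", "populations_to_ddg"]

#: Eq.-4-style scaling of the heteronuclear dimension
CSP_SCALE = {"13C": 0.25, "15N": 0.154}

#: factor applied to dC before building response vectors / PCA clouds
CARBON_SCALE = 0.25


def csp(ddh_ppm, ddx_ppm, nucleus: str = "13C"):
    """Combined chemical-shift perturbation, ppm."""
    try:
        c = CSP_SCALE[nucleus]
    except KeyError:
        raise ValidationError(f"unknown nucleus {nucleus!r}; expected 13C or 15N")
    return np.sqrt(np.asarray(ddh_ppm, dtype=float) ** 2
                   + c * np.asarray(ddx_ppm, dtype=float) ** 2)


def max_vector_distance(profile: np.ndarray) -> float:
    """Largest pairwise combined shift distance across states for one methyl.

    ``profile`` is (n_states, 2) of (dH, dC); the distance between states i, j
    is sqrt((0.25 ddC)^2 + ddH^2)."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape[0] < 2:
        raise ValidationError("need >= 2 states")
    dh = profile[:, 0][:, None] - profile[:, 0][None, :]
    dc = profile[:, 1][:, None] - profile[:, 1][None, :]
    d = np.sqrt((CARBON_SCALE * dc) ** 2 + dh ** 2)
    return float(d.max())


# ---------------------------------------------------------------------------
# CHESCA
# ---------------------------------------------------------------------------

@dataclass
class ChescaResult:
    methyls: list[MethylId]
    pearson: np.ndarray
    linkage: np.ndarray                  # scipy hierarchical linkage records
    edges: list[tuple[MethylId, MethylId, float]]
    distance_cutoff: float
    edge_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{m.residue_type}{m.residue_number}-{m.methyl_label}"
                  for m in self.methyls]
        return pd.DataFrame(self.pearson, index=labels, columns=labels)


def chesca(table: StateShiftTable, distance_cutoff: float = 0.1,
           edge_cutoff: float = 0.9) -> ChescaResult:
    """Chemical-shift covariance analysis over the table's state series."""
    states = table.states
    if len(states) < 2:
        raise ValidationError("CHESCA needs >= 2 states")
    kept: list[MethylId] = []
    vectors: list[np.ndarray] = []
    for mid in table.methyls():
        prof = table.profile(mid)
        if prof is None:
            continue
        if max_vector_distance(prof) < distance_cutoff:
            continue
        # center each shift dimension on its own mean: the response is the
        # change across states, not the absolute position of the resonance
        dh = prof[:, 0] - prof[:, 0].mean()
        dc = CARBON_SCALE * (prof[:, 1] - prof[:, 1].mean())
        vec = np.concatenate([dh, dc])
        if np.allclose(vec, 0.0):
            continue
        kept.append(mid)
        vectors.append(vec)
    if len(kept) < 2:
        raise ValidationError(
            f"fewer than 2 methyls retained at distance cutoff {distance_cutoff}")
    mat = np.corrcoef(np.asarray(vectors))
    np.fill_diagonal(mat, 1.0)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    link = linkage(squareform(dist, checks=False), method="average")
    edges = [(kept[i], kept[j], float(mat[i, j]))
             for i in range(len(kept)) for j in range(i + 1, len(kept))
             if mat[i, j] > edge_cutoff]
    return ChescaResult(methyls=kept, pearson=mat, linkage=link, edges=edges,
                        distance_cutoff=distance_cutoff, edge_cutoff=edge_cutoff)


# ---------------------------------------------------------------------------
# CONCISE
# ---------------------------------------------------------------------------

@dataclass
class ConciseResult:
    states: list[str]
    basis_states: tuple[str, str]             # (open, closed)
    kept: list[MethylId]
    scores: pd.DataFrame                      # kept methyls x states, in [0,1]-ish
    positions: dict[str, float]               # mean normalized PC1 per state
    position_sd: dict[str, float]
    attrition: dict[str, int] = field(default_factory=dict)


def _methyl_pca(prof: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 scores of one methyl's (dH, scaled dC) cloud and the
    SD(PC1)/SD(PC2) linearity ratio (inf for a perfectly linear cloud)."""
    pts = np.column_stack([prof[:, 0], CARBON_SCALE * prof[:, 1]])
    pts = pts - pts.mean(axis=0)
    # SVD-based PCA; states are observations, the 2 shift axes variables
    u, s, vt = np.linalg.svd(pts, full_matrices=False)
    scores = pts @ vt[0]
    sd1 = s[0]
    sd2 = s[1] if len(s) > 1 else 0.0
    ratio = float("inf") if sd2 == 0 else float(sd1 / sd2)
    return scores, ratio


def concise(table: StateShiftTable, basis_states: tuple[str, str],
            sd_ratio_threshold: float = 3.0,
            csp_cutoff: float = 0.05) -> ConciseResult:
    """Per-methyl PCA linearity filtering and equilibrium positions.

    ``basis_states`` names the open and closed reference states; every kept
    methyl's PC1 scores are affinely normalized so the open basis maps to 0
    and the closed basis to 1, making positions comparable across methyls.
    """
    open_state, closed_state = basis_states
    for b in basis_states:
        if b not in table.states:
            raise ValidationError(f"basis state {b!r} not in table")
    i_open = table.states.index(open_state)
    i_closed = table.states.index(closed_state)

    n_profile = n_csp = n_ratio = n_degenerate = 0
    kept: list[MethylId] = []
    score_rows: list[np.ndarray] = []
    for mid in table.methyls():
        prof = table.profile(mid)
        if prof is None:
            n_profile += 1
            continue
        pair_csp = csp(prof[:, 0][:, None] - prof[:, 0][None, :],
                       prof[:, 1][:, None] - prof[:, 1][None, :], "13C")
        if float(pair_csp.max()) < csp_cutoff:
            n_csp += 1
            continue
        scores, ratio = _methyl_pca(prof)
        if ratio < sd_ratio_threshold:
            n_ratio += 1
            continue
        span = scores[i_closed] - scores[i_open]
        if span == 0:
            n_degenerate += 1
            continue
        kept.append(mid)
        score_rows.append((scores - scores[i_open]) / span)
    if not kept:
        raise ValidationError(
            "no methyl survives the CONCISE filters "
            f"(missing-profile: {n_profile}, CSP<{csp_cutoff}: {n_csp}, "
            f"SD-ratio<{sd_ratio_threshold}: {n_ratio}, "
            f"degenerate basis: {n_degenerate})")
    score_df = pd.DataFrame(score_rows, columns=table.states,
                            index=[str(m) for m in kept])
    positions = {s: float(score_df[s].mean()) for s in table.states}
    sds = {s: float(score_df[s].std(ddof=1)) if len(kept) > 1 else 0.0
           for s in table.states}
    return ConciseResult(states=list(table.states), basis_states=basis_states,
                         kept=kept, scores=score_df, positions=positions,
                         position_sd=sds,
                         attrition={"missing_profile": n_profile,
                                    "csp": n_csp, "sd_ratio": n_ratio,
                                    "degenerate": n_degenerate})


def populations_to_ddg(result: ConciseResult, reference_state: str,
                       T: float = 300.0, ci: float = 0.90,
                       n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Binding free-energy changes from CONCISE equilibrium positions.

    The equilibrium position is read as the closed-state population p and
    ddG(state) = -R T [ln(p/(1-p)) - ln(p_ref/(1-p_ref))].  Confidence
    intervals come from bootstrap resampling of the kept methyls' normalized
    PC1 scores.  Positions at or beyond {0, 1} give an unbounded log-odds and
    are reported as censored (NaN ddG).
    """
    if reference_state not in result.states:
        raise ValidationError(f"reference state {reference_state!r} unknown")

    def logodds(p):
        return np.log(p / (1.0 - p))

    p_ref = result.positions[reference_state]
    rng = np.random.default_rng(seed)
    scores = result.scores.to_numpy()
    n_methyl = scores.shape[0]
    boot_pos = np.empty((n_boot, len(result.states)))
    for b in range(n_boot):
        idx = rng.integers(0, n_methyl, n_methyl)
        boot_pos[b] = scores[idx].mean(axis=0)

    alpha = (1.0 - ci) / 2.0
    rows = []
    for k, state in enumerate(result.states):
        p = result.positions[state]
        censored = not (0.0 < p < 1.0) or not (0.0 < p_ref < 1.0)
        if censored:
            ddg = lo = hi = float("nan")
        else:
            ddg = -R_KCAL * T * (logodds(p) - logodds(p_ref))
            bp = np.clip(boot_pos[:, k], 1e-9, 1 - 1e-9)
            bref = np.clip(boot_pos[:, result.states.index(reference_state)],
                           1e-9, 1 - 1e-9)
            bddg = -R_KCAL * T * (logodds(bp) - logodds(bref))
            lo, hi = np.quantile(bddg, [alpha, 1.0 - alpha])
        rows.append({"state": state, "position": p,
                     "ddG_kcal_mol": ddg, "ddG_ci_low": float(lo),
                     "ddG_ci_high": float(hi), "censored": censored})
    return pd.DataFrame(rows)
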