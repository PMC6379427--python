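"""Physical constants and run-level configuration.

All thermodynamic quantities are handled in kcal mol^-1 with the gas constant
in kcal mol^-1 K^-1, matching how binding thermodynamics are conventionally
tabulated for ITC work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

#: Boltzmann constant, J K^-1 (Stokes-Einstein)
K_BOLTZMANN = 1.380649e-23

#: Default sample temperature, K
T_DEFAULT = 300.0


@dataclass(frozen=True)
class MethylConstants:
    """Physical constants entering the eta -> O^2 conversion for a
    CH3 group (intra-methyl 1H-1H dipolar cross-correlation).

    The defaults are the standard methyl geometry used in the
    cross-correlated-relaxation literature: the H-H vector perpendicular
    to the threefold symmetry axis, so P2(cos 90 deg)^2 = 1/4.
    """

    theta_hh_deg: float = 90.0          # angle between H-H vector and methyl axis
    r_hh_m: float = 1.813e-10           # intra-methyl proton-proton distance
    gamma_h: float = 2.6752e8           # 1H gyromagnetic ratio, rad s^-1 T^-1
    hbar: float = 1.0546e-34            # J s
    mu0_over_4pi: float = 1.0e-7        # T^2 J^-1 m^3

    #: gamma_C / gamma_H, used to convert ppm chemical-shift differences
    #: measured on 13C into rad s^-1 at a given 1H spectrometer frequency.
    gamma_ratio_c_h: float = 0.25144


DEFAULT_METHYL_CONSTANTS = MethylConstants()


@dataclass
class Thresholds:
    """Named analysis cutoffs used by the shift-statistics stages."""

    concise_sd_ratio: float = 3.0       # SD(PC1)/SD(PC2) linearity filter
    concise_csp_cutoff: float = 0.05    # ppm, minimum perturbation to keep
    pearson_cutoff: float = 0.9         # order-parameter / CHESCA edge cutoff
    chesca_distance_cutoffs: tuple[float, ...] = (0.1, 0.05)  # ppm


@dataclass
class RunConfig:
    """Run configuration shared across pipeline stages."""

    temperature: float = T_DEFAULT
    gas_constant: float = R_KCAL
    random_seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        th = self.thresholds
        scalars = [th.concise_sd_ratio, th.concise_csp_cutoff, th.pearson_cutoff,
                   *th.chesca_distance_cutoffs]
        if any(t <= 0 for t in scalars):
            raise ValueError("all thresholds must be > 0")
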