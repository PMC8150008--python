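"""The similarity measure omega.

omega = B_bar * L / (1 + exp[s * (tau2 + delta_tau2 - m)]) combines the
propensity-score sample overlap B_bar with a decreasing logistic
function of the total outcome/study-characteristic heterogeneity.  The
defaults (L = 1, midpoint m = 0.24, slope s = 10) place the logistic
midpoint at the upper end of the heterogeneity range typical of
psychological research, so omega discriminates sharply across realistic
tau2 values.  omega is non-compensatory: it never exceeds either factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generalizability import GeneralizabilityResult

__all__ = ["OmegaConfig", "SimilarityWeights", "omega", "similarity_weights"]


@dataclass(frozen=True)
class OmegaConfig:
    L: float = 1.0
    midpoint: float = 0.24
    slope: float = 10.0

    def __post_init__(self) -> None:
        if self.midpoint <= 0 or self.slope <= 0 or self.L <= 0:
            raise ValueError("L, midpoint and slope must all be positive")


@dataclass
class SimilarityWeights:
    """Per-predictor weights and the (tau2, delta_tau2, B_bar) they used."""

    omega_p: np.ndarray
    components: list


def omega(
    tau2: float,
    delta_tau2: float,
    B_bar: float,
    config: OmegaConfig = OmegaConfig(),
) -> float:
    """Similarity weight for one predictor's informative prior."""
    if tau2 < 0 or delta_tau2 < 0:
        raise ValueError("heterogeneity components must be non-negative")
    if not 0.0 <= B_bar <= 1.0:
        raise ValueError(f"B_bar must lie in [0, 1], got {B_bar}")
    h = tau2 + delta_tau2
    logistic = config.L / (1.0 + np.exp(config.slope * (h - config.midpoint)))
    return float(B_bar * logistic)


def similarity_weights(
    meta_summaries,
    gen: GeneralizabilityResult,
    config: OmegaConfig = OmegaConfig(),
) -> SimilarityWeights:
    """One omega per predictor from its heterogeneity and the shared B_bar."""
    if len(meta_summaries) == 0:
        raise ValueError("need one heterogeneity summary per predictor")
    comps, values = [], []
    for s in meta_summaries:
        if s is None or not np.isfinite(s.tau2) or not np.isfinite(s.delta_tau2):
            raise ValueError(
                f"incomplete heterogeneity summary for predictor {getattr(s, 'predictor_index', '?')}"
            )
        comps.append((s.tau2, s.delta_tau2, gen.B_bar))
        values.append(omega(s.tau2, s.delta_tau2, gen.B_bar, config))
    return SimilarityWeights(omega_p=np.array(values), components=comps)
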