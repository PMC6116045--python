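"""Auto-covariance features over predicted secondary-structure profiles.

For each state j in (helix, strand, coil) and lag lam = 1..l_min - 1:

    AC(lam, j) = 1/(L - lam) * sum_i (s_ij - mean_j) * (s_(i+lam)j - mean_j)

where s_ij is the probability that residue i is in state j. With the
default minimum sequence length l_min = 50 this yields 49 * 3 = 147
auto-covariance terms; the three state means and three population
standard deviations bring the total to 153. Layout is lag-major within
state, states in (H, E, C) order, then means, then stds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SS_STATES, FeatureBlock, SsProfile


@dataclass(frozen=True)
class AcConfig:
    """Minimum sequence length; lags run 1..l_min - 1."""

    l_min: int = 50

    def __post_init__(self) -> None:
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")

    @property
    def max_lag(self) -> int:
        return self.l_min - 1

    @property
    def feature_length(self) -> int:
        return 3 * self.max_lag + 6


def ac_struct(profile: SsProfile, cfg: AcConfig = AcConfig()) -> FeatureBlock:
    """Auto-covariance descriptor of a 3-state probability profile."""
    probs = profile.probs
    length = probs.shape[0]
    if length < cfg.l_min:
        raise ValueError(
            f"profile {profile.record_id!r}: length {length} is below the "
            f"minimum l_min={cfg.l_min}"
        )
    means = probs.mean(axis=0)
    stds = probs.std(axis=0)  # population convention, matching the AC divisor
    centered = probs - means
    values: list[float] = []
    labels: list[str] = []
    for j, state in enumerate(SS_STATES):
        col = centered[:, j]
        for lag in range(1, cfg.l_min):
            values.append(float(col[: length - lag] @ col[lag:] / (length - lag)))
            labels.append(f"{state}.lag{lag}")
    values.extend(means)
    labels.extend(f"mean.{state}" for state in SS_STATES)
    values.extend(stds)
    labels.extend(f"std.{state}" for state in SS_STATES)
    return FeatureBlock("ac_struct", np.array(values), tuple(labels))
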