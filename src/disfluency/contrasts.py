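"""Effects-coded contrasts for the blur and frequency factors.

The blur factor (clear / low / high) is analysed with two orthogonal-in-intent
contrasts:

* ``BLUR_HIGH_VS_OTHERS`` — high-blur (+0.5) against clear and low-blur (each
  -0.5).  The weights are kept exactly as conventionally printed even though
  they do not sum to zero; used as regression codes the coefficient still
  equals ``theta_high - mean(theta_clear, theta_low)`` because the spacing
  between the coded groups is 1.
* ``BLUR_LOW_VS_CLEAR`` — low-blur (+0.5) against clear (-0.5), high-blur 0.

Experiment-2 adds ``FREQ_HIGH_VS_LOW`` (high +0.5, low -0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ContrastSpec",
    "BLUR_HIGH_VS_OTHERS",
    "BLUR_LOW_VS_CLEAR",
    "FREQ_HIGH_VS_LOW",
    "centered",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One contrast on one factor: a name and a level -> weight map."""

    name: str
    factor: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def codes(self, levels: pd.Series | np.ndarray) -> np.ndarray:
        """Map a vector of factor levels to contrast codes (regression column)."""
        levels = pd.Series(levels)
        unknown = set(levels.unique()) - set(self.weights)
        if unknown:
            raise KeyError(
                f"contrast {self.name!r} has no weight for level(s) {sorted(unknown)}"
            )
        return levels.map(self.weights).to_numpy(dtype=float)

    def effect(self, level_values: Mapping[str, float]) -> float:
        """Contrast effect on a table of per-level values.

        Computed as the mean over positive-weight levels minus the mean over
        negative-weight levels, which equals the regression coefficient under
        the +-0.5 coding convention (the coded groups are one unit apart).
        """
        pos = [lvl for lvl, w in self.weights.items() if w > 0]
        neg = [lvl for lvl, w in self.weights.items() if w < 0]
        if not pos or not neg:
            raise ValueError(f"contrast {self.name!r} needs both signs of weights")
        missing = [lvl for lvl in pos + neg if lvl not in level_values]
        if missing:
            raise KeyError(f"missing level values for {missing}")
        return float(
            np.mean([level_values[lvl] for lvl in pos])
            - np.mean([level_values[lvl] for lvl in neg])
        )

    @property
    def levels(self) -> list[str]:
        return list(self.weights)


BLUR_HIGH_VS_OTHERS = ContrastSpec(
    name="high_vs_others",
    factor="blur",
    weights={"high": 0.5, "clear": -0.5, "low": -0.5},
)

BLUR_LOW_VS_CLEAR = ContrastSpec(
    name="low_vs_clear",
    factor="blur",
    weights={"low": 0.5, "clear": -0.5, "high": 0.0},
)

FREQ_HIGH_VS_LOW = ContrastSpec(
    name="high_vs_low_freq",
    factor="frequency",
    weights={"high": 0.5, "low": -0.5},
)


def centered(spec: ContrastSpec) -> ContrastSpec:
    """Zero-sum variant of a contrast (e.g. +0.5 / -0.25 / -0.25). Non-default."""
    w = dict(spec.weights)
    total = sum(w.values())
    neg = [lvl for lvl, wt in w.items() if wt < 0]
    if abs(total) > 1e-12 and neg:
        shift = total / len(neg)
        for lvl in neg:
            w[lvl] = w[lvl] - shift
    return ContrastSpec(name=spec.name + "_centered", factor=spec.factor, weights=w)
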