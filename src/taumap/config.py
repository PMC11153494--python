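"""Pipeline configuration.

Holds the constants of the group analysis: frequency-map thresholds, the
heat-equation diffusion parameter, cluster-forming p, permutation and
bootstrap counts, the minimum valid-vertex fraction, and the reference ROI
used for burden normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass
class PipelineConfig:
    """Constants used across the burden/thickness group analysis.

    Attributes
    ----------
    frequency_thresholds:
        Burden thresholds for the frequency maps, strictly decreasing.
        Defaults correspond to severe (>1.0), moderate (>0.5), mild (>0.25)
        and rare (>0.1) pathological burden.
    diffusion_T:
        Total diffusion time of the heat-equation smoothing applied to
        per-vertex thickness before the pointwise GLM.
    cluster_p:
        Cluster-forming threshold (uncorrected, per-vertex one-sided p).
    n_permutations:
        Number of Freedman-Lane permutations for cluster-level FWE.
    min_valid_fraction:
        Minimum fraction of specimens with a valid thickness observation a
        vertex needs to enter the analysis.
    n_bootstrap:
        Bootstrap replicates for ROI correlation confidence intervals.
    ci_level:
        Confidence level of the bootstrap interval.
    reference_roi:
        Name of the ROI burden is normalized to (transentorhinal cortex).
    seed:
        Master seed; all randomness derives from it.
    """

    frequency_thresholds: Sequence[float] = field(
        default_factory=lambda: (1.0, 0.5, 0.25, 0.1)
    )
    diffusion_T: float = 4.0
    cluster_p: float = 0.01
    n_permutations: int = 1000
    min_valid_fraction: float = 0.25
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    reference_roi: str = "BA35"
    seed: int = 0

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.frequency_thresholds)
        if any(b >= a for a, b in zip(thr, thr[1:])):
            raise ValueError("frequency_thresholds must be strictly decreasing")
        if not 0.0 < self.cluster_p < 1.0:
            raise ValueError("cluster_p must lie in (0, 1)")
        if not 0.0 < self.min_valid_fraction < 1.0:
            raise ValueError("min_valid_fraction must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        self.frequency_thresholds = thr

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequency_thresholds"] = list(self.frequency_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def default_config() -> PipelineConfig:
    """Return the default analysis configuration.

    The defaults are the published analysis constants: frequency thresholds
    [1.0, 0.5, 0.25, 0.1], diffusion T = 4, cluster-forming uncorrected
    p < 0.01, 1000 permutations, a 25% valid-vertex rule, 1000 bootstrap
    iterations with 95% intervals, and BA35 as the normalization reference.
    """
    return PipelineConfig()
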