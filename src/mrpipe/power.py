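"""Power approximation for two-sample MR with a binary outcome.

The test statistic for the causal log-odds ratio in a case-control outcome
sample is approximately normal with non-centrality driven by the attenuated
effect on the observed (0/1) scale, the outcome sample size, the case
fraction, and the fraction of exposure variance the instruments explain
(R^2).  Power for a two-sided level-alpha test is then a single normal tail
evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the binary-outcome MR power approximation.

    ``odds_ratio`` is the detectable OR per unit of exposure; ``r2`` is the
    variance of the exposure explained by the instruments in the exposure
    sample.
    """

    n_cases: int
    n_controls: int
    r2: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("case and control counts must be positive")
        if not (0 < self.r2 < 1):
            raise ValidationError(f"r2 {self.r2} outside (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if self.odds_ratio <= 0:
            raise ValidationError("odds_ratio must be positive")


def mr_power_binary(spec: PowerSpec, method: str = "attenuated") -> float:
    """Approximate power of the two-sample MR test for a binary outcome.

    With N = cases + controls and case fraction K, the attenuated per-unit
    effect on the 0/1 outcome scale is

        b = K * (OR / (1 + K*(OR - 1)) - 1),

    and power = Phi(|b| * sqrt(N * R^2) / sqrt(K*(1-K)) - z_{1-alpha/2}).

    ``method="log_or"`` gives the simpler variant based directly on |ln OR|:
    Phi(|ln OR| * sqrt(N * K*(1-K) * R^2) - z).
    """
    n = spec.n_cases + spec.n_controls
    k = spec.n_cases / n
    if k <= 0.0 or k >= 1.0:
        raise ValidationError("degenerate case fraction")
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    if method == "attenuated":
        b = k * (spec.odds_ratio / (1.0 + k * (spec.odds_ratio - 1.0)) - 1.0)
        ncp = abs(b) * math.sqrt(n * spec.r2) / math.sqrt(k * (1.0 - k))
    elif method == "log_or":
        ncp = abs(math.log(spec.odds_ratio)) * math.sqrt(n * k * (1.0 - k) * spec.r2)
    else:
        raise ValidationError(f"unknown power method {method!r}")
    return float(stats.norm.cdf(ncp - z))
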