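"""Poisson quantification of DNA methylation from droplet digital PCR.

A ddPCR reaction partitions the template across ~20,000 droplets; each
droplet is read as positive or negative in a methylated-probe channel
and an unmethylated-probe channel. Template copies distribute across
droplets approximately Poisson, so the mean copies per droplet for a
channel c with k_c positive droplets out of N is

    lambda_c = -ln(1 - k_c / N)

and the percent methylation is 100 * lambda_meth / (lambda_meth +
lambda_unmeth). Channel counts are treated independently (a
double-positive droplet counts in both), matching the per-channel
Poisson formula. A 95% confidence interval comes from propagating the
binomial standard error of k_c/N through the log transform and the
ratio (delta method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DdpcrWell", "MethylationEstimate", "estimate_methylation", "simulate_well"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DdpcrWell:
    """Droplet counts for one reaction: total droplets and positives per
    probe channel."""

    n_droplets: int
    pos_meth: int
    pos_unmeth: int

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        for label, k in (("pos_meth", self.pos_meth), ("pos_unmeth", self.pos_unmeth)):
            if not 0 <= k <= self.n_droplets:
                raise ValueError(f"{label}={k} outside [0, {self.n_droplets}]")


@dataclass(frozen=True)
class MethylationEstimate:
    lambda_meth: float
    lambda_unmeth: float
    percent_meth: float  # NaN when both channels are empty
    ci_low: float
    ci_high: float
    saturated: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent_meth)


def _channel_lambda(k: int, n: int) -> tuple[float, float, bool]:
    """(lambda, var(lambda), saturated) for one channel.

    At full saturation (k == N) the MLE diverges; the estimate is capped
    at -ln(1/(2N)) and flagged rather than failing.
    """
    if k == n:
        return -math.log(1.0 / (2 * n)), math.inf, True
    p = k / n
    lam = -math.log1p(-p)
    var_p = p * (1.0 - p) / n
    var_lam = var_p / (1.0 - p) ** 2  # d(lambda)/dp = 1/(1-p)
    return lam, var_lam, False


def estimate_methylation(well: DdpcrWell) -> MethylationEstimate:
    """Percent methylation with a delta-method 95% CI.

    Both channels empty gives an undefined (NaN) percent; a saturated
    channel is capped and flagged, and its CI widens to [0, 100].
    """
    lam_m, var_m, sat_m = _channel_lambda(well.pos_meth, well.n_droplets)
    lam_u, var_u, sat_u = _channel_lambda(well.pos_unmeth, well.n_droplets)
    saturated = sat_m or sat_u
    total = lam_m + lam_u
    if total == 0.0:
        return MethylationEstimate(lam_m, lam_u, math.nan, math.nan, math.nan, False)
    frac = lam_m / total
    percent = 100.0 * frac
    if math.isinf(var_m) or math.isinf(var_u):
        lo, hi = 0.0, 100.0
    else:
        # grad of lam_m/(lam_m+lam_u): (lam_u, -lam_m)/total^2
        var_frac = (lam_u**2 * var_m + lam_m**2 * var_u) / total**4
        half = 100.0 * _Z95 * math.sqrt(var_frac)
        lo = max(0.0, percent - half)
        hi = min(100.0, percent + half)
    return MethylationEstimate(lam_m, lam_u, percent, lo, hi, saturated)


def simulate_well(
    true_percent: float,
    total_copies: float,
    n_droplets: int,
    seed: int | np.random.Generator,
) -> DdpcrWell:
    """Simulate droplet counts for a known methylation fraction.

    Copies of each species land in droplets independently with per-droplet
    Poisson mean total_copies * fraction / N; a channel is positive when
    at least one copy of its species is present, so counts are binomial
    with success probability 1 - exp(-lambda).
    """
    if not (0.0 <= true_percent <= 100.0):
        raise ValueError("true_percent must be in [0, 100]")
    if total_copies < 0 or not math.isfinite(total_copies):
        raise ValueError("total_copies must be finite and non-negative")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_m = total_copies * (true_percent / 100.0) / n_droplets
    lam_u = total_copies * (1.0 - true_percent / 100.0) / n_droplets
    pos_m = int(rng.binomial(n_droplets, -math.expm1(-lam_m)))
    pos_u = int(rng.binomial(n_droplets, -math.expm1(-lam_u)))
    return DdpcrWell(n_droplets, pos_m, pos_u)
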