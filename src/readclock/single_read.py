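"""Epigenetic age prediction for individual bisulfite reads.

Each sequencing read of an amplicon carries a binary sequel of
methylated (1) and unmethylated (0) calls over the amplicon's CpGs.
Under the stochastic-aging view, CpG i of a molecule from an animal of
age a is methylated independently with probability

    p_i(a) = clip(intercept_i + slope_i * a, eps, 1 - eps)

where (slope_i, intercept_i) is the DNAm-vs-age trajectory of CpG i fit
on a training cohort and eps keeps the Bernoulli likelihood finite. A
read with pattern x is assigned the age on an integer grid of 0..200
weeks that maximises the log-likelihood

    L(a) = sum_i [ x_i ln p_i(a) + (1 - x_i) ln(1 - p_i(a)) ]

with missing calls dropped from the sum and ties resolved to the lowest
age. Per-sample summaries are the read-count-weighted mean age and the
normalised distribution of read ages over the grid (the heatmap rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .amplicon import ReadPatternTable
from .clocks import MethylationMatrix, trajectories_for

__all__ = [
    "AGE_GRID",
    "SingleReadModel",
    "ReadAgeDistribution",
    "SamplePrediction",
    "build_single_read_model",
    "predict_read_age",
    "predict_pattern_ages",
    "predict_sample",
    "combine_amplicons",
]

AGE_GRID = np.arange(0, 201)  # weeks, inclusive, step 1


@dataclass
class SingleReadModel:
    """Per-CpG age trajectories mapping binary patterns to grid ages."""

    amplicon: str
    cpg_ids: list[str]
    slopes: np.ndarray  # beta-fraction per week, one per CpG
    intercepts: np.ndarray  # beta-fraction at age 0
    epsilon: float = 0.01
    max_missing_frac: float = 0.5  # reads with more missing calls are excluded
    _loglik: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")
        if len(self.cpg_ids) < 2:
            raise ValueError("a single-read model needs >=2 usable CpGs; a shorter pattern carries no age signal")
        if not (len(self.cpg_ids) == self.slopes.size == self.intercepts.size):
            raise ValueError("cpg_ids, slopes and intercepts must align")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def prob_matrix(self) -> np.ndarray:
        """(201, n_cpgs) methylation probabilities over the age grid."""
        p = self.intercepts[None, :] + self.slopes[None, :] * AGE_GRID[:, None]
        return np.clip(p, self.epsilon, 1.0 - self.epsilon)

    def _log_terms(self) -> tuple[np.ndarray, np.ndarray]:
        if self._loglik is None:
            p = self.prob_matrix()
            self._loglik = (np.log(p), np.log1p(-p))
        return self._loglik


def build_single_read_model(
    matrix: MethylationMatrix,
    amplicon: str,
    epsilon: float = 0.01,
) -> SingleReadModel:
    """Fit trajectories for every CpG of an amplicon on a training set.

    All CpGs of the amplicon enter the model, not only the top ones;
    CpGs whose trajectory is undefined (constant DNAm) are excluded with
    a warning — their pattern slots are simply uninformative.
    """
    cols = matrix.amplicons().get(amplicon)
    if not cols:
        raise KeyError(f"amplicon {amplicon!r} not in matrix")
    trajs = trajectories_for(matrix, cols)
    usable = {c: t for c, t in trajs.items() if t.defined}
    skipped = [c for c in cols if c not in usable]
    if skipped:
        warnings.warn(f"{amplicon}: excluding CpGs with undefined trajectories: {skipped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError(f"{amplicon}: fewer than 2 CpGs with a defined age trajectory")
    return SingleReadModel(
        amplicon=amplicon,
        cpg_ids=list(usable),
        slopes=np.array([t.slope for t in usable.values()]),
        intercepts=np.array([t.intercept for t in usable.values()]),
        epsilon=epsilon,
    )


def _pattern_to_array(pattern) -> np.ndarray:
    if isinstance(pattern, str):
        return np.array([np.nan if ch == "?" else float(ch) for ch in pattern])
    arr = np.asarray(pattern, dtype=float)
    arr = np.where(arr < 0, np.nan, arr)  # -1 encodes missing
    return arr


def predict_read_age(pattern, model: SingleReadModel) -> int:
    """Most likely grid age (weeks) for one binary pattern.

    ``pattern`` is a string over {0,1,?} or a vector with -1/NaN for
    missing. Missing positions drop out of the likelihood; an
    all-missing pattern has no signal and is an error.
    """
    x = _pattern_to_array(pattern)
    if x.size != model.n_cpgs:
        raise ValueError(f"pattern length {x.size} != model CpG count {model.n_cpgs}")
    if np.all(np.isnan(x)):
        raise ValueError("pattern has no observed CpG calls")
    return int(predict_pattern_ages(x[None, :], model)[0])


def predict_pattern_ages(patterns: np.ndarray, model: SingleReadModel) -> np.ndarray:
    """Grid-age argmax for a (P, n_cpgs) batch of patterns (NaN = missing).

    np.argmax returns the first maximiser, which on an ascending grid is
    the lowest age — the documented tie-break.
    """
    x = np.asarray(patterns, dtype=float)
    obs = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    logp, log1mp = model._log_terms()
    # L[p, a] = sum_i obs * (x*logp + (1-x)*log1mp)
    ll = (x0 * obs) @ logp.T + ((1.0 - x0) * obs) @ log1mp.T
    return AGE_GRID[np.argmax(ll, axis=1)]


@dataclass(frozen=True)
class ReadAgeDistribution:
    """Relative frequency of read-level age calls over the 0..200 grid,
    normalised by the sample's read count (heatmap row)."""

    sample_id: str
    amplicon: str
    frequencies: np.ndarray  # length 201, sums to 1
    total_reads: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.size != AGE_GRID.size:
            raise ValueError("distribution must cover the full age grid")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")


@dataclass(frozen=True)
class SamplePrediction:
    sample_id: str
    amplicon: str
    mean_age: float  # NaN when no usable reads
    distribution: ReadAgeDistribution | None
    n_reads: int
    n_excluded: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.mean_age)


def predict_sample(table: ReadPatternTable, model: SingleReadModel) -> SamplePrediction:
    """Read-count-weighted mean single-read age and its grid distribution.

    Patterns missing at more than ``model.max_missing_frac`` of CpGs are
    excluded (they would otherwise pile up at the grid boundaries); an
    empty table yields an undefined (NaN) prediction, flagged rather
    than raised.
    """
    if table.amplicon != model.amplicon:
        raise ValueError(f"table amplicon {table.amplicon!r} != model amplicon {model.amplicon!r}")
    if not table.counts:
        return SamplePrediction(table.sample_id, table.amplicon, np.nan, None, 0, 0)
    arr, w = table.pattern_array()
    missing_frac = np.isnan(arr).mean(axis=1)
    keep = missing_frac <= model.max_missing_frac
    n_excluded = int(w[~keep].sum())
    if not np.any(keep):
        return SamplePrediction(table.sample_id, table.amplicon, np.nan, None, 0, n_excluded)
    ages = predict_pattern_ages(arr[keep], model)
    wk = w[keep]
    total = wk.sum()
    mean_age = float((wk * ages).sum() / total)
    freqs = np.bincount(ages, weights=wk, minlength=AGE_GRID.size) / total
    dist = ReadAgeDistribution(table.sample_id, table.amplicon, freqs, int(total))
    return SamplePrediction(table.sample_id, table.amplicon, mean_age, dist, int(total), n_excluded)


def combine_amplicons(
    means: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Final sample age: weighted mean over available amplicon means.

    Undefined (NaN) amplicons drop out with a warning; default weights
    are equal.
    """
    usable = {a: m for a, m in means.items() if m is not None and not np.isnan(m)}
    dropped = set(means) - set(usable)
    if dropped:
        warnings.warn(f"amplicons without predictions dropped: {sorted(dropped)}", stacklevel=2)
    if not usable:
        raise ValueError("no amplicon means available")
    if weights is None:
        return float(np.mean(list(usable.values())))
    w = np.array([float(weights.get(a, 0.0)) for a in usable])
    if w.sum() <= 0:
        raise ValueError("weights over available amplicons sum to zero")
    m = np.array(list(usable.values()))
    return float((w * m).sum() / w.sum())
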