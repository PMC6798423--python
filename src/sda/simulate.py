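"""Synthetic two-group MS abundance data with known differential status.

Each feature is semicontinuous: an observation is zero with a per-feature
probability p drawn from Uniform(0, 0.8), and otherwise the exponential of
a draw from a log-abundance source distribution.  Null features use the
same distribution in both groups; differential features add a log
fold-change (default log 2, group 2 elevated) to the non-zero part of
group 2.  An optional detection-limit step censors each feature at the
10th percentile of its combined non-zero values, converting low non-zero
values to zeros — so differential features end up with unequal zero counts
between groups, the lower-abundance group losing more values to the limit.

Two parametric log-abundance sources are provided so simulations run
self-contained: a normal (log-normal abundance) and a right-skewed shifted
gamma.  ``empirical_sampler`` resamples the non-zero log values of a
user-supplied reference matrix instead, feature by feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "lognormal_source", "skewed_source",
           "empirical_sampler", "simulate_dataset"]

#: log-abundance location/scale of the parametric sources (arbitrary units,
#: roughly matching ion intensities of ~150 on the raw scale)
_LOC = 5.0
_SCALE = 1.0

Source = Callable[[np.random.Generator, int], np.ndarray]


def lognormal_source(rng: np.random.Generator, size: int) -> np.ndarray:
    """Normal log-abundance: the normal-errors reference case."""
    return rng.normal(_LOC, _SCALE, size)


def skewed_source(rng: np.random.Generator, size: int) -> np.ndarray:
    """Right-skewed log-abundance: shifted gamma(shape 2, scale 1)
    (skewness ~1.4), emulating the heavy right tails seen in MS features."""
    return _LOC - 2.0 + rng.gamma(2.0, 1.0, size)


def empirical_sampler(reference: pd.DataFrame, min_nonzero: int = 20) -> Source:
    """With-replacement sampler over the non-zero log values of a reference
    matrix (features x samples).

    Each call selects one eligible feature (>= ``min_nonzero`` non-zero
    values) uniformly at random and resamples its non-zero log values, so
    every simulated feature inherits the empirical shape of one real one.
    """
    values = np.asarray(reference, dtype=float)
    eligible = [np.log(row[row > 0]) for row in values if np.sum(row > 0) >= min_nonzero]
    if not eligible:
        raise ValueError(f"no feature with >= {min_nonzero} non-zero values in the reference")

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        pool = eligible[rng.integers(len(eligible))]
        return rng.choice(pool, size=size, replace=True)

    return sample


_SOURCES = {"lognormal": lognormal_source, "skewed": skewed_source}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the benchmark design: two groups of n subjects, 4000
    features, 10% differential with a 2-fold effect, zero proportions
    uniform on (0, 0.8); ``detection_limit`` enables the censoring scenario
    with the limit at the 10th percentile of combined non-zero values.
    """

    n_per_group: int = 50
    n_features: int = 4000
    de_fraction: float = 0.1
    effect: float = float(np.log(2.0))
    zero_prop_range: tuple = (0.0, 0.8)
    source: Union[str, Source] = "skewed"
    detection_limit: bool = False
    detection_quantile: float = 0.10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0 < self.detection_quantile < 1:
            raise ValueError("detection_quantile must lie in (0, 1)")
        lo, hi = self.zero_prop_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("zero_prop_range must be a sub-interval of [0, 1]")

    def resolve_source(self) -> Source:
        if callable(self.source):
            return self.source
        try:
            return _SOURCES[self.source]
        except KeyError:
            raise ValueError(f"unknown source {self.source!r}; "
                             f"choose from {sorted(_SOURCES)} or pass a callable") from None


@dataclass
class SimTruth:
    """Per-feature generating truth for evaluating methods."""

    feature_ids: list
    is_de: np.ndarray
    p_zero: np.ndarray
    effect_applied: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "is_de": self.is_de.astype(int),
            "p_zero": self.p_zero,
            "effect": self.effect_applied,
        })


def simulate_dataset(config: SimConfig):
    """Generate one dataset: (abundance, covariates, truth).

    Returns a features x samples abundance DataFrame, a per-sample
    covariate DataFrame with a binary ``group`` column (group 1 coded 1 and
    elevated for differential features), and a :class:`SimTruth`.
    Bit-identical output for identical seed and config.
    """
    rng = np.random.default_rng(config.seed)
    source = config.resolve_source()
    n = config.n_per_group
    m = config.n_features
    n_de = int(round(config.de_fraction * m))
    de_idx = rng.choice(m, size=n_de, replace=False)
    is_de = np.zeros(m, dtype=bool)
    is_de[de_idx] = True

    lo, hi = config.zero_prop_range
    p_zero = rng.uniform(lo, hi, m)
    effect_applied = np.where(is_de, config.effect, 0.0)

    data = np.zeros((m, 2 * n))
    for g in range(m):
        zero_mask = rng.random(2 * n) < p_zero[g]
        k = int(np.sum(~zero_mask))
        logs = source(rng, k)
        vals = np.zeros(2 * n)
        nz_pos = np.flatnonzero(~zero_mask)
        # second half of the columns is group 1 (the elevated group)
        shift = np.where(nz_pos >= n, effect_applied[g], 0.0)
        vals[nz_pos] = np.exp(logs + shift)
        if config.detection_limit:
            nz = vals[vals > 0]
            if nz.size:
                limit = np.quantile(nz, config.detection_quantile)
                vals[vals < limit] = 0.0
        data[g] = vals

    feature_ids = [f"F{g + 1:05d}" for g in range(m)]
    sample_ids = [f"S{i + 1:04d}" for i in range(2 * n)]
    abundance = pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"),
                             columns=sample_ids)
    covariates = pd.DataFrame({
        "sample_id": sample_ids,
        "group": [0] * n + [1] * n,
    })
    truth = SimTruth(feature_ids=feature_ids, is_de=is_de, p_zero=p_zero,
                     effect_applied=effect_applied)
    return abundance, covariates, truth
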