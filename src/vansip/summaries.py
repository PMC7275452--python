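"""Group summaries used in reports: mean ± SE, one-way ANOVA, two-tailed t."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientReplicationError


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error; SE is NaN for a single observation."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientReplicationError("no observations")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return mean, se


def one_way_anova(*groups: Sequence[float]) -> float:
    """One-way ANOVA p-value across two or more groups.

    Identical groups (zero between- and within-variance pathologies) return
    p = 1.0 rather than NaN.
    """
    if len(groups) < 2:
        raise InsufficientReplicationError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InsufficientReplicationError("each group needs >= 2 observations")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*arrays)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def two_tailed_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed independent-samples t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("each group needs >= 2 observations")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    res = stats.ttest_ind(a, b)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p
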