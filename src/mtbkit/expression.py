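"""Correlation primitives for the expression workflows.

Implements the Pearson correlation between expression profiles, the
conditional correlation of a miRNA R and a target T1 given a second target
T2 (cell lines are split into two groups at the mean of T2's expression and
the within-group correlations are averaged), and the buffering statistic

    d(R, T1, T2) = f(R, T1 | T2) - f(R, T1).

A negative d means that knowing T2's expression improves the explanation of
the R-T1 relationship, i.e. T1 and T2 are not independently regulated by R —
the signature expected of competing endogenous RNAs that buffer each other.
Undefined correlations (zero-variance profiles, degenerate splits) are
returned as NaN and propagate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pearson", "conditional_correlation", "d_statistic"]

#: smallest number of samples for a defined within-group correlation;
#: 2-point correlations are degenerately +/-1 and contribute nothing.
MIN_GROUP_SIZE = 3


def _as_profiles(*vectors) -> list[np.ndarray]:
    arrays = [np.asarray(v, dtype=float) for v in vectors]
    n = arrays[0].size
    for a in arrays:
        if a.ndim != 1 or a.size != n:
            raise ValueError("profiles must be 1-D vectors of equal length")
        if not np.isfinite(a).all():
            raise ValueError("profiles must be finite")
    if n < MIN_GROUP_SIZE:
        raise ValueError(f"profiles need >= {MIN_GROUP_SIZE} samples")
    return arrays


def pearson(x, y) -> float:
    """Pearson correlation coefficient; NaN if either profile is constant."""
    x, y = _as_profiles(x, y)
    dx, dy = x - x.mean(), y - y.mean()
    ssx, ssy = float(dx @ dx), float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        return float("nan")
    return float(np.clip((dx @ dy) / np.sqrt(ssx * ssy), -1.0, 1.0))


def conditional_correlation(r, t1, t2) -> float:
    """Expected correlation f(R, T1 | T2) over the two mean-split T2 groups.

    Samples with T2 strictly above its mean form one group, the rest the
    other; the within-group Pearson correlations of R and T1 are averaged
    with weights proportional to group size.  Groups smaller than three
    samples or with an undefined correlation are excluded from the weighting;
    NaN when no group qualifies.
    """
    r, t1, t2 = _as_profiles(r, t1, t2)
    if t2.max() == t2.min():
        return float("nan")  # constant T2: the mean split is impossible
    above = t2 > t2.mean()
    weights, values = [], []
    for mask in (above, ~above):
        if mask.sum() < MIN_GROUP_SIZE:
            continue
        val = pearson(r[mask], t1[mask])
        if np.isnan(val):
            continue
        weights.append(int(mask.sum()))
        values.append(val)
    if not values:
        return float("nan")
    return float(np.average(values, weights=weights))


def d_statistic(r, t1, t2) -> float:
    """Buffering statistic d(R,T1,T2) = f(R,T1|T2) - f(R,T1); NaN propagates."""
    cond = conditional_correlation(r, t1, t2)
    plain = pearson(np.asarray(r, dtype=float), np.asarray(t1, dtype=float))
    return float(cond - plain)
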