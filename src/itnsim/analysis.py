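"""Downstream strategy comparison of the sweep outputs.

The comparison works on the encoded measure: the generation count for a
measured run, or the nominal class code (1000 toward / 1500 away / 2000
extinction) otherwise, so that every run contributes a rank-consistent
number.  Strategies are compared with a soft 10% cut-off on the relative
difference |a - b| / max(a, b); strategies within 10% of each other are
treated as equal.  Larger encoded values mean resistance (or control
failure) is delayed longer, i.e. better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strategies import COMPARED_STRATEGIES

__all__ = [
    "STRATEGY_LETTERS", "relative_difference", "classify_strategies",
    "classify_strategies_table", "classify_single_strategy",
    "probability_of_resistance", "binned_trend",
    "first_break_locus_fraction", "data_type_fraction",
]

#: Single-letter labels of the compared strategies, rendered in the
#: canonical order C (mosaics), X (mixtures), R (rotations), S (sequences).
STRATEGY_LETTERS = {"mosaics": "C", "mixtures": "X", "rotations": "R", "sequences": "S"}
_LETTER_ORDER = "CXRS"


def relative_difference(a, b):
    """|a - b| / max(a, b), elementwise; 0 where both are 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(m > 0, np.abs(a - b) / np.where(m > 0, m, 1.0), 0.0)
    return out


def _winning_set(values: np.ndarray, tol: float) -> np.ndarray | None:
    """Indices of the winning strategy set, or None when no clean set exists.

    The best (largest encoded value) strategy and everything within the
    tolerance of it form the candidate set; it wins only if every member
    differs by more than the tolerance from every non-member.
    """
    best = values.max()
    members = relative_difference(values, best) < tol
    if members.all():
        return np.arange(values.size)
    inside = values[members]
    outside = values[~members]
    ok = (relative_difference(inside[:, None], outside[None, :]) > tol).all()
    return np.flatnonzero(members) if ok else None


def classify_strategies(values, strategies=COMPARED_STRATEGIES, tol: float = 0.10) -> str:
    """Label which strategy (or combination) wins by the >10% rule.

    ``values`` are the encoded measures of the compared strategies, in
    the order of ``strategies`` (the maximum benchmark is excluded from
    comparison).  Returns '=' when all strategies are within tolerance
    of each other or no clean winning set exists; otherwise the winners'
    letters in canonical C, X, R, S order (e.g. 'X', 'CX', 'CXR').
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(strategies):
        raise ValueError("one value per compared strategy required")
    if np.any(values <= 0):
        raise ValueError("encoded measures must be positive")
    win = _winning_set(values, tol)
    if win is None or win.size == len(strategies):
        return "="
    letters = {STRATEGY_LETTERS[strategies[i]] for i in win}
    return "".join(c for c in _LETTER_ORDER if c in letters)


def classify_strategies_table(
    encoded: pd.DataFrame, strategies=COMPARED_STRATEGIES, tol: float = 0.10
) -> pd.Series:
    """Vectorised :func:`classify_strategies` over rows of a wide table.

    ``encoded`` has one column per compared strategy and one row per
    parameter set.
    """
    V = encoded.loc[:, list(strategies)].to_numpy(dtype=float)
    if np.any(V <= 0):
        raise ValueError("encoded measures must be positive")
    n, S = V.shape
    best = V.max(axis=1, keepdims=True)
    members = relative_difference(V, best) < tol  # (n, S)
    # pairwise relative differences (n, S, S)
    pair = relative_difference(V[:, :, None], V[:, None, :])
    # member-vs-non-member separation: every (member, non-member) pair > tol
    sep = pair > tol
    bad = np.any(members[:, :, None] & ~members[:, None, :] & ~sep, axis=(1, 2))
    all_in = members.all(axis=1)
    letters = [STRATEGY_LETTERS[s] for s in strategies]
    # precompute the label of every possible membership bitmask
    lut = np.empty(2 ** S, dtype=object)
    for mask in range(2 ** S):
        chosen = {letters[j] for j in range(S) if mask >> j & 1}
        lut[mask] = "".join(c for c in _LETTER_ORDER if c in chosen)
    codes = members @ (1 << np.arange(S))
    labels = lut[codes]
    labels[all_in | bad] = "="
    return pd.Series(labels, index=encoded.index, name="label")


def classify_single_strategy(
    values, focal: str, strategies=COMPARED_STRATEGIES, tol: float = 0.10
) -> str:
    """Classify one strategy against the rest by the same soft cut-off.

    Returns one of ``'most'`` (better than every other by > tol),
    ``'equal-most-all'`` (all strategies within tol), ``'equal-most-with-some'``
    (within tol of the best, which beats the worst by > tol) or
    ``'not-most'`` (some other strategy beats the focal by > tol).
    """
    values = np.asarray(values, dtype=float)
    if focal not in strategies:
        raise ValueError(f"focal strategy {focal!r} not among {strategies}")
    i = list(strategies).index(focal)
    others = np.delete(values, i)
    v = values[i]
    best = values.max()
    if relative_difference(v, best) > tol and best > v:
        return "not-most"
    if relative_difference(values[:, None], values[None, :]).max() < tol:
        return "equal-most-all"
    if np.all((relative_difference(v, others) > tol) & (v > others)):
        return "most"
    return "equal-most-with-some"


def probability_of_resistance(dtype_first) -> float:
    """Fraction of first-to-break outcomes moving in the resistance direction.

    Counts 'measured' and 'toward' outcomes over the subset.
    """
    dtype_first = np.asarray(dtype_first)
    if dtype_first.size == 0:
        raise ValueError("probability of resistance undefined on an empty subset")
    return float(np.isin(dtype_first, ("measured", "toward")).mean())


def first_break_locus_fraction(results, locus: str = "A", subset=None) -> float:
    """Fraction of runs whose first-broken locus is ``locus``, averaged
    over the given cells.

    ``results`` is an iterable of :class:`~itnsim.simulate.BatchResult`
    (e.g. one per strategy); per cell the fraction is taken over runs
    with a determinable first-to-break locus (some allele crossed, no
    tie), optionally restricted to a boolean ``subset`` over parameter
    sets, then averaged across cells.  With a mitochondrial locus A this
    is the probability that the mitochondrially-inherited resistance
    breaks first.
    """
    fractions = []
    for res in results:
        det = res.which_first != ""
        if subset is not None:
            det = det & subset
        if not det.any():
            continue
        fractions.append(float((res.which_first[det] == locus).mean()))
    if not fractions:
        raise ValueError("no runs with a determinable first-to-break locus")
    return float(np.mean(fractions))


def data_type_fraction(results, measure: str, types, subset=None) -> float:
    """Fraction of runs whose outcome class for ``measure`` is in ``types``,
    averaged over the given cells.

    Used for the data-type summaries of the sweep, e.g. the
    toward-or-away fraction at low female exposure or the extinction
    fraction at high birth rates.
    """
    types = tuple(np.atleast_1d(types))
    fractions = []
    for res in results:
        dt = getattr(res, f"dtype_{measure}")
        if subset is not None:
            dt = dt[subset]
        fractions.append(float(np.isin(dt, types).mean()))
    return float(np.mean(fractions))


def binned_trend(
    x, y, n_bins: int = 101, window: int = 5, z: float = 1.96
) -> pd.DataFrame:
    """Binned mean of y over x with a backward moving average and CI band.

    x is rounded to ``n_bins`` equally spaced grid points over its range;
    per bin the mean and standard error of y are computed, then the mean
    and the +-z*SE confidence bounds are smoothed with a backward-tail
    moving average of length ``window`` (early bins average over their
    available predecessors).  Empty bins and single-point bins (no SE)
    yield missing values that propagate through the smoothing positions
    they anchor, but are skipped inside other windows rather than
    interpolated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite observations")
    lo, hi = x.min(), x.max()
    centers = np.linspace(lo, hi, n_bins)
    if hi > lo:
        idx = np.rint((x - lo) / (hi - lo) * (n_bins - 1)).astype(int)
    else:
        idx = np.zeros(x.size, dtype=int)
    count = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=y, minlength=n_bins)
    ss = np.bincount(idx, weights=y * y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s / np.maximum(count, 1), np.nan)
        var = np.where(count > 1, (ss - count * mean ** 2) / np.maximum(count - 1, 1), np.nan)
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(count, 1))
    se = np.where(count > 1, se, np.nan)

    def smooth(v: np.ndarray) -> np.ndarray:
        out = np.full(n_bins, np.nan)
        for i in range(n_bins):
            if not np.isfinite(v[i]):
                continue
            w = v[max(0, i - window + 1): i + 1]
            out[i] = np.nanmean(w)
        return out

    sm = smooth(mean)
    return pd.DataFrame({
        "x": centers, "n": count, "mean": mean, "se": se,
        "smoothed_mean": sm,
        "ci_low": smooth(mean - z * se),
        "ci_high": smooth(mean + z * se),
    })
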