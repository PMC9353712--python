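"""Rank-based rhythm detection (JTK_CYCLE).

A series is compared against a grid of cosine reference waveforms (period x
phase lag) through the Jonckheere-Terpstra / Kendall-tau S statistic

    S = sum_{i<j} sign(x_j - x_i) * sign(r_j - r_i)

where ``r`` is the reference evaluated at the actual sample times.  Because S
depends on the data only through ranks, its null distribution conditional on
the tie patterns of both vectors is exactly computable by permutation
counting; we do that with Gaussian-binomial generating functions when the
data carry no ties and a capacity dynamic program otherwise.  The
per-reference one-sided upper-tail p-value is minimised over references.

Family-wise adjustment of that minimum comes in two flavours:

``adjust="permutation"`` (default)
    The exact permutation distribution of the min-p statistic itself,
    enumerated over all arrangements of the observed ranks (Monte Carlo
    above 9 samples).  This accounts for the strong dependence between
    overlapping cosine templates and is exactly calibrated.
``adjust="bonferroni"``
    The textbook correction ``min(1, raw_p * n_refs)``; conservative for
    dense reference grids because neighbouring templates are nearly
    identical.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ReferenceWaveform",
    "NullDistribution",
    "RhythmResult",
    "default_period_grid",
    "reference_waveforms",
    "jtk_statistic",
    "exact_null_distribution",
    "jtk_test",
    "jtk_scan",
    "call_rhythmic",
    "brute_force_null",
]

_ROUND = 9  # decimals used to detect ties in reference values
_EXACT_PERM_LIMIT = 9  # enumerate n! arrangements up to this many samples
_DEFAULT_MC_PERMS = 20000


# ---------------------------------------------------------------------------
# reference waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceWaveform:
    """One cosine template: ``cos(2*pi*(t - lag)/period)`` at the sample times."""

    period: float
    lag: float
    values: np.ndarray
    ranks: np.ndarray
    tie_pattern: tuple  # group sizes of equal values, ascending value order

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _tie_pattern(values: np.ndarray) -> tuple:
    """Group sizes of equal entries, in ascending order of the value."""
    _, counts = np.unique(values, return_counts=True)
    return tuple(int(c) for c in counts)


def _sampling_interval(times: np.ndarray) -> float:
    uniq = np.unique(times)
    if uniq.shape[0] < 2:
        return float("nan")
    return float(np.median(np.diff(uniq)))


def default_period_grid(times, period_min: float = 20.0, period_max: float = 28.0):
    """Periods testable on a sampling grid, within ``[period_min, period_max]``.

    A rank test on few samples cannot distinguish a period that is not a
    multiple of the sampling interval from its nearest on-grid neighbour, so
    the default grid keeps integer-hour periods that are multiples of the
    interval (21/24/27 h for 3-h sampling).  Falls back to every integer
    hour when the interval is irregular or sub-hourly.
    """
    times = np.asarray(times, dtype=float)
    interval = _sampling_interval(times)
    lo = int(math.ceil(period_min))
    hi = int(math.floor(period_max))
    candidates = [float(p) for p in range(lo, hi + 1)]
    if not (np.isfinite(interval) and interval > 0):
        return tuple(candidates)
    on_grid = [p for p in candidates if abs(p / interval - round(p / interval)) < 1e-9]
    return tuple(on_grid) if on_grid else tuple(candidates)


def reference_waveforms(design, period_grid=None, lag_step: float | None = None):
    """Build the deduplicated reference set for a sampling design.

    References are generated for every (period, lag) pair on the grid,
    ordered by descending period then ascending lag, and deduplicated on
    their rank pattern: two templates that order the samples identically
    yield identical S statistics.  The retained representative of each
    pattern is the first in that order, so p-value ties downstream resolve
    to the longest period and smallest lag.  The default lag step is half
    the sampling interval (finer phase shifts cannot reorder the samples).
    """
    times = np.asarray(
        design.sample_times if hasattr(design, "sample_times") else design, dtype=float
    )
    if times.shape[0] < 2:
        raise ValueError("need at least two samples to build reference waveforms")
    if period_grid is None:
        period_grid = default_period_grid(times)
    periods = sorted({float(p) for p in period_grid}, reverse=True)
    if not periods:
        raise ValueError("empty period grid")
    for p in periods:
        if not (20.0 <= p <= 28.0):
            raise ValueError(f"period {p} outside the supported 20-28 h range")
    if lag_step is None:
        interval = _sampling_interval(times)
        lag_step = interval / 2.0 if np.isfinite(interval) else 1.0
    if lag_step <= 0:
        raise ValueError("lag_step must be positive")
    refs = []
    seen = set()
    for period in periods:
        for lag in np.arange(0.0, 24.0, lag_step):
            vals = np.round(np.cos(2 * np.pi * (times - lag) / period), _ROUND)
            ranks = rankdata(vals)
            key = tuple(ranks)
            if key in seen:
                continue
            seen.add(key)
            refs.append(
                ReferenceWaveform(
                    period=period,
                    lag=float(lag),
                    values=vals,
                    ranks=ranks,
                    tie_pattern=_tie_pattern(vals),
                )
            )
    return refs


# ---------------------------------------------------------------------------
# the S statistic
# ---------------------------------------------------------------------------


def _pair_signs(values: np.ndarray) -> np.ndarray:
    """sign(v_j - v_i) over all pairs i<j (last axis), as int8."""
    v = np.asarray(values)
    i, j = np.triu_indices(v.shape[-1], k=1)
    return np.sign(v[..., j] - v[..., i]).astype(np.int8)


def jtk_statistic(series, ref) -> int:
    """Kendall-tau-style concordance count between a series and a reference.

    Pairs tied in either vector contribute zero.
    """
    y = np.asarray(series, dtype=float)
    rv = ref.values if isinstance(ref, ReferenceWaveform) else np.asarray(ref, dtype=float)
    if y.shape[0] != rv.shape[0]:
        raise ValueError(f"series length {y.shape[0]} != reference length {rv.shape[0]}")
    return int(np.sum(_pair_signs(y).astype(np.int32) * _pair_signs(rv).astype(np.int32)))


# ---------------------------------------------------------------------------
# exact null distribution of S
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Distribution of S under random pairing of two fixed tie patterns.

    The exact form stores the full support and probabilities; the
    large-sample normal form stores only the standard deviation
    (``approx=True``) and uses a continuity-corrected tail.
    """

    support: np.ndarray
    probs: np.ndarray
    approx: bool = False
    sd: float = 0.0
    _tail: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not self.approx:
            order = np.argsort(self.support)
            self.support = np.asarray(self.support)[order]
            self.probs = np.asarray(self.probs)[order]
            # suffix sums for upper-tail lookups
            self._tail = np.concatenate([np.cumsum(self.probs[::-1])[::-1], [0.0]])

    def sf(self, s):
        """P(S >= s), one-sided upper tail."""
        if self.approx:
            z = (np.asarray(s, dtype=float) - 0.5) / self.sd
            out = norm.sf(z)
            return float(out) if np.isscalar(s) else out
        idx = np.searchsorted(self.support, s, side="left")
        out = self._tail[idx]
        return float(out) if np.isscalar(s) else out


def _poly_mul_one_minus_qk(coeffs: list, k: int) -> list:
    out = coeffs + [0] * k
    for j in range(len(coeffs)):
        out[j + k] -= coeffs[j]
    return out


def _poly_div_one_minus_qk(coeffs: list, k: int) -> list:
    # exact synthetic division by (1 - q^k)
    out = list(coeffs)
    for j in range(k, len(out)):
        out[j] += out[j - k]
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


@lru_cache(maxsize=4096)
def _untied_counts(groups: tuple) -> tuple:
    """Arrangement counts of the Jonckheere-Terpstra J for untied data.

    The generating function is the Gaussian q-multinomial
    ``[n; g1,...,gk]_q``, built as a product of Gaussian binomials; the
    coefficient of ``q^J`` counts assignments whose Mann-Whitney total is J.
    Exact integer arithmetic throughout.
    """
    poly = [1]
    m = 0
    for g in groups:
        for i in range(1, g + 1):
            poly = _poly_mul_one_minus_qk(poly, m + i)
        for i in range(1, g + 1):
            poly = _poly_div_one_minus_qk(poly, i)
        m += g
    return tuple(poly)


def _compositions(total: int, caps: tuple):
    """All ways to split ``total`` into len(caps) parts with part i <= caps[i]."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for first in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


def _general_counts(groups: tuple, counts: tuple) -> dict:
    """Exact S counts when both vectors carry ties (capacity DP).

    Data values are placed into reference groups one distinct value at a
    time (ascending); the state is the remaining capacity of each group.
    Each composition is weighted by the number of position choices, so the
    total weight equals the number of distinct data arrangements.
    """
    states: dict = {tuple(groups): {0: 1}}
    k = len(groups)
    for c in counts:
        new: dict = defaultdict(lambda: defaultdict(int))
        for rem, smap in states.items():
            placed = tuple(g - r for g, r in zip(groups, rem))
            prefix = [0] * k  # placed in groups strictly below h
            run = 0
            for h in range(k):
                prefix[h] = run
                run += placed[h]
            total_placed = run
            for comp in _compositions(c, rem):
                ways = 1
                for r, a in zip(rem, comp):
                    ways *= math.comb(r, a)
                ds = 0
                for h in range(k):
                    if comp[h]:
                        ds += comp[h] * (2 * prefix[h] + placed[h] - total_placed)
                nrem = tuple(r - a for r, a in zip(rem, comp))
                tgt = new[nrem]
                for s, cnt in smap.items():
                    tgt[s + ds] += cnt * ways
        states = new
    return states[tuple(0 for _ in groups)]


def _normal_null(groups: tuple, counts: tuple, n: int) -> NullDistribution:
    # Kendall S variance with ties in both vectors
    def t1(v):
        return sum(x * (x - 1) for x in v)

    def t2(v):
        return sum(x * (x - 1) * (x - 2) for x in v)

    def t3(v):
        return sum(x * (x - 1) * (2 * x + 5) for x in v)

    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - t3(groups) - t3(counts)) / 18.0
    if n > 2:
        var += t2(groups) * t2(counts) / (9.0 * n * (n - 1) * (n - 2))
    var += t1(groups) * t1(counts) / (2.0 * n * (n - 1))
    return NullDistribution(
        support=np.empty(0), probs=np.empty(0), approx=True, sd=math.sqrt(max(var, 1e-300))
    )


_NULL_CACHE: dict = {}
_DP_STATE_LIMIT = 500_000


def exact_null_distribution(
    ref_tie_pattern, data_tie_pattern, n: int | None = None, exact_limit: int = 25
) -> NullDistribution:
    """Exact permutation null of S conditional on both tie patterns.

    Above ``exact_limit`` samples (or an intractably large tie-pattern DP)
    a continuity-corrected normal approximation is returned with
    ``approx=True``.
    """
    g = tuple(int(x) for x in ref_tie_pattern)
    c = tuple(int(x) for x in data_tie_pattern)
    if sum(g) != sum(c):
        raise ValueError("tie patterns describe different sample counts")
    if n is None:
        n = sum(g)
    elif n != sum(g):
        raise ValueError("n inconsistent with tie patterns")
    key = (g, c)
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit
    if n > exact_limit:
        dist = _normal_null(g, c, n)
    elif all(x == 1 for x in c):
        dist = _from_untied(g, n)
    elif all(x == 1 for x in g):
        dist = _from_untied(c, n)  # S is symmetric in the two vectors
    else:
        # choose the role assignment with the smaller DP state space
        bound_g = math.prod(x + 1 for x in g)
        bound_c = math.prod(x + 1 for x in c)
        gg, cc = (g, c) if bound_g <= bound_c else (c, g)
        if math.prod(x + 1 for x in gg) > _DP_STATE_LIMIT:
            dist = _normal_null(g, c, n)
        else:
            smap = _general_counts(gg, cc)
            total = sum(smap.values())
            support = np.array(sorted(smap), dtype=int)
            probs = np.array([smap[s] / total for s in support], dtype=float)
            dist = NullDistribution(support=support, probs=probs)
    _NULL_CACHE[key] = dist
    return dist


def _from_untied(groups: tuple, n: int) -> NullDistribution:
    counts = _untied_counts(tuple(groups))
    maxj = (n * n - sum(x * x for x in groups)) // 2
    total = sum(counts)
    support = np.array([2 * j - maxj for j in range(len(counts))], dtype=int)
    probs = np.array([cnt / total for cnt in counts], dtype=float)
    keep = probs > 0
    return NullDistribution(support=support[keep], probs=probs[keep])


def brute_force_null(ref_values, data_values) -> NullDistribution:
    """Exhaustive-permutation oracle for the null of S (testing aid).

    Enumerates every arrangement of ``data_values`` against the fixed
    reference; feasible only for small n.
    """
    rv = np.asarray(ref_values, dtype=float)
    ref_sign = _pair_signs(rv).astype(np.int32)
    counter: dict = defaultdict(int)
    for perm in permutations(tuple(np.asarray(data_values, dtype=float))):
        s = int(np.sum(_pair_signs(np.array(perm)).astype(np.int32) * ref_sign))
        counter[s] += 1
    total = sum(counter.values())
    support = np.array(sorted(counter), dtype=int)
    probs = np.array([counter[s] / total for s in support], dtype=float)
    return NullDistribution(support=support, probs=probs)


# ---------------------------------------------------------------------------
# family-wise adjustment over the reference set
# ---------------------------------------------------------------------------

_MINP_CACHE: dict = {}


def _perm_value_matrix(multiset: np.ndarray, mc_perms: int, seed: int) -> np.ndarray:
    """Arrangements of a value multiset: exhaustive for n <= 9, else MC."""
    n = multiset.shape[0]
    if n <= _EXACT_PERM_LIMIT:
        return np.array(list(permutations(multiset.tolist())), dtype=float)
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(multiset, (mc_perms, 1)), axis=1)


def _minp_null_sorted(
    ref_vals: tuple,
    data_tie_pattern: tuple,
    exact_limit: int,
    mc_perms: int,
    seed: int,
) -> tuple:
    """Sorted permutation null of min-p over the reference set.

    Returns ``(sorted minp array, exact flag)``.  ``ref_vals`` is a tuple of
    reference value tuples already restricted to the observed samples.
    """
    key = (ref_vals, data_tie_pattern)
    hit = _MINP_CACHE.get(key)
    if hit is not None:
        return hit
    n = sum(data_tie_pattern)
    multiset = np.repeat(np.arange(len(data_tie_pattern), dtype=float), data_tie_pattern)
    exact = n <= _EXACT_PERM_LIMIT
    perms = _perm_value_matrix(multiset, mc_perms, seed)
    dsign = _pair_signs(perms).astype(np.int32)
    pmat = np.empty((perms.shape[0], len(ref_vals)))
    for k, rv in enumerate(ref_vals):
        rv_arr = np.asarray(rv, dtype=float)
        rt = _tie_pattern(rv_arr)
        if len(rt) == 1:
            pmat[:, k] = 1.0
            continue
        s = dsign @ _pair_signs(rv_arr).astype(np.int32)
        pmat[:, k] = exact_null_distribution(rt, data_tie_pattern, exact_limit=exact_limit).sf(s)
    result = (np.sort(pmat.min(axis=1)), exact)
    _MINP_CACHE[key] = result
    return result


def _permutation_adjust(raw_p, null_sorted: np.ndarray):
    """P(min-p <= observed) under the permutation null (>= raw_p always)."""
    idx = np.searchsorted(null_sorted, np.asarray(raw_p), side="right")
    out = idx / null_sorted.shape[0]
    return float(out) if np.isscalar(raw_p) else out


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------


@dataclass
class RhythmResult:
    feature: str
    best_period: float
    best_lag: float
    amplitude: float
    raw_p: float
    adj_p: float
    rhythmic: bool
    approx: bool = False


def _cosinor_amplitude(y, times, period, lag) -> float:
    """Least-squares half-amplitude of a cosine at fixed (period, lag)."""
    x = np.cos(2 * np.pi * (times - lag) / period)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[1])


def _adjust_raw(raw_p, n_refs, ref_vals, data_ties, adjust, exact_limit, mc_perms, perm_seed):
    if adjust == "bonferroni":
        return min(1.0, raw_p * n_refs), False
    null_sorted, exact = _minp_null_sorted(ref_vals, data_ties, exact_limit, mc_perms, perm_seed)
    return _permutation_adjust(raw_p, null_sorted), not exact


def jtk_test(
    series,
    refs,
    times=None,
    threshold: float = 0.05,
    exact_limit: int = 25,
    adjust: str = "permutation",
    mc_perms: int = _DEFAULT_MC_PERMS,
    perm_seed: int = 0,
    feature: str = "feature",
) -> RhythmResult:
    """JTK test of one series against a reference set.

    Missing values are dropped (pairs involving them leave both the
    statistic and the null's pair count); constant or <4-point series are
    reported non-rhythmic with p = 1.
    """
    if adjust not in ("permutation", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    y = np.asarray(series, dtype=float)
    if times is None:
        raise ValueError("sample times are required")
    times = np.asarray(times, dtype=float)
    mask = np.isfinite(y)
    null_result = RhythmResult(feature, float("nan"), float("nan"), 0.0, 1.0, 1.0, False)
    if mask.sum() < 4:
        return null_result
    ysub = y[mask]
    if np.all(ysub == ysub[0]):
        return null_result
    data_ties = _tie_pattern(np.round(ysub, _ROUND))
    dsign = _pair_signs(ysub).astype(np.int32)
    best = None
    approx_any = False
    kept_vals = []
    for ref in refs:
        rsub = np.asarray(ref.values)[mask]
        kept_vals.append(tuple(rsub.tolist()))
        rt = _tie_pattern(rsub)
        if len(rt) == 1:  # reference constant on the observed subset
            continue
        s = int(np.sum(_pair_signs(rsub).astype(np.int32) * dsign))
        dist = exact_null_distribution(rt, data_ties, exact_limit=exact_limit)
        p = float(dist.sf(s))
        approx_any = approx_any or dist.approx
        if best is None or p < best[0]:
            best = (p, ref)
    if best is None:
        return null_result
    raw_p, ref = best
    adj_p, mc_used = _adjust_raw(
        raw_p, len(refs), tuple(kept_vals), data_ties, adjust, exact_limit, mc_perms, perm_seed
    )
    amp = _cosinor_amplitude(ysub, times[mask], ref.period, ref.lag)
    return RhythmResult(
        feature=feature,
        best_period=ref.period,
        best_lag=ref.lag,
        amplitude=amp,
        raw_p=raw_p,
        adj_p=adj_p,
        rhythmic=bool(adj_p < threshold),
        approx=approx_any or mc_used,
    )


def call_rhythmic(adj_p, threshold: float):
    """Strictly-less rhythm call: ``adj_p < threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    arr = np.asarray(adj_p, dtype=float)
    flags = arr < threshold
    return bool(flags) if np.isscalar(adj_p) else flags


def jtk_scan(
    matrix,
    period_grid=None,
    lag_step: float | None = None,
    threshold: float = 0.05,
    exact_limit: int = 25,
    refs=None,
    adjust: str = "permutation",
    adjust_across_features: bool = False,
    mc_perms: int = _DEFAULT_MC_PERMS,
    perm_seed: int = 0,
) -> pd.DataFrame:
    """Run the JTK test over every row of a :class:`TimeCourseMatrix`.

    Complete, tie-free rows share one vectorised pass (a single matmul for
    all S statistics plus cached null lookups); rows with missing values or
    tied ranks fall back to the per-series routine.  Returns a DataFrame
    indexed by feature with columns period, lag, amplitude, raw_p, adj_p,
    rhythmic, approx.

    ``adjust_across_features`` additionally Bonferroni-corrects for the
    number of features scanned (off by default: the JTK convention corrects
    per feature across its reference family only).
    """
    if adjust not in ("permutation", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    times = matrix.zt
    if refs is None:
        refs = reference_waveforms(times, period_grid=period_grid, lag_step=lag_step)
    values = matrix.values
    n_feat, n = values.shape
    feat_factor = n_feat if adjust_across_features else 1
    out = {}

    finite = np.isfinite(values)
    complete = finite.all(axis=1)
    rounded = np.round(values, _ROUND)
    sorted_rows = np.sort(rounded, axis=1)
    has_tie = (np.diff(sorted_rows, axis=1) == 0).any(axis=1) if n > 1 else np.zeros(n_feat, bool)
    simple = complete & ~has_tie

    if simple.any() and n >= 4:
        sub = values[simple]
        dsign = _pair_signs(sub).astype(np.int32)  # (F, P)
        rsign = np.stack([_pair_signs(r.values) for r in refs]).astype(np.int32)  # (R, P)
        S = dsign @ rsign.T  # (F, R)
        data_ties = (1,) * n
        pmat = np.empty(S.shape, dtype=float)
        approx_null = False
        for k, ref in enumerate(refs):
            dist = exact_null_distribution(ref.tie_pattern, data_ties, exact_limit=exact_limit)
            pmat[:, k] = dist.sf(S[:, k])
            approx_null = approx_null or dist.approx
        best_idx = np.argmin(pmat, axis=1)  # first minimum: longest period, smallest lag
        raw = pmat[np.arange(pmat.shape[0]), best_idx]
        if adjust == "bonferroni":
            adj = np.minimum(1.0, raw * len(refs) * feat_factor)
            mc_used = False
        else:
            ref_vals = tuple(tuple(r.values.tolist()) for r in refs)
            null_sorted, exact = _minp_null_sorted(
                ref_vals, data_ties, exact_limit, mc_perms, perm_seed
            )
            adj = np.minimum(1.0, _permutation_adjust(raw, null_sorted) * feat_factor)
            mc_used = not exact
        ids = np.asarray(matrix.feature_ids, dtype=object)[simple]
        for i, fid in enumerate(ids):
            ref = refs[best_idx[i]]
            amp = _cosinor_amplitude(sub[i], times, ref.period, ref.lag)
            out[fid] = (
                ref.period, ref.lag, amp, raw[i], adj[i],
                adj[i] < threshold, approx_null or mc_used,
            )

    for i, fid in enumerate(matrix.feature_ids):
        if simple[i] and n >= 4:
            continue
        r = jtk_test(
            values[i], refs, times=times, threshold=threshold, exact_limit=exact_limit,
            adjust=adjust, mc_perms=mc_perms, perm_seed=perm_seed, feature=str(fid),
        )
        adj = min(1.0, r.adj_p * feat_factor)
        out[fid] = (r.best_period, r.best_lag, r.amplitude, r.raw_p, adj,
                    adj < threshold, r.approx)

    df = pd.DataFrame.from_dict(
        out, orient="index",
        columns=["period", "lag", "amplitude", "raw_p", "adj_p", "rhythmic", "approx"],
    ).reindex(matrix.feature_ids)
    df.index.name = "feature"
    return df
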