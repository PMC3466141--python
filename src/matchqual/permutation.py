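"""Permutation machinery for partially paired two-sample comparisons.

Two samples (call them A and B) are *partially paired* when some observations
in the two groups share an index subject — here, a peer distance and a listed
distance belonging to the same survivor — while others do not. Standard rank
tests assume independent observations; the correlation induced by shared
survivors invalidates their null distributions.

The null distribution used here re-randomizes group labels in ways consistent
with exchangeability given the index subject:

* observations sharing an index subject form a *cluster*; within each cluster,
  labels are permuted uniformly over the assignments that preserve the
  cluster's observed per-group counts (for the common one-A/one-B pair this is
  an independent fair label swap);
* observations whose index subject appears in only one group are pooled, and
  labels are reassigned uniformly at random preserving the total unpaired
  per-group counts.

Two statistics are supported: the Wilcoxon rank sum of group A (midranks for
ties) and a Pearson chi-square deviation statistic on the group-by-category
table. Exact enumeration is used when the number of distinct arrangements is
small; otherwise Monte Carlo sampling with a seeded generator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import CapacityError, InsufficientDataError

#: Default cap on exact enumeration size (arrangements).
EXACT_CAP = 10**6

_METHOD_ALIASES = {
    "auto": "auto",
    "exact": "exact_enumeration",
    "exact_enumeration": "exact_enumeration",
    "mc": "monte_carlo",
    "monte_carlo": "monte_carlo",
}


def normalize_method(method: str) -> str:
    try:
        return _METHOD_ALIASES[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected auto|exact|monte_carlo") from None


def _as_values(v) -> list:
    """A scalar (including str) becomes a singleton list; sequences pass through."""
    if isinstance(v, (list, tuple, np.ndarray)):
        return list(v)
    return [v]


@dataclass
class PairedStructure:
    """Pooled observations annotated with the dependence structure.

    ``clusters`` holds ``(indices, n_a)`` for every index subject present in
    both groups: the pooled positions of its observations and how many carry
    the A label. ``unpaired_index`` pools the remaining observations, of which
    ``n_a_unpaired`` carry the A label.
    """

    values: np.ndarray  # object array of pooled observations
    clusters: list[tuple[np.ndarray, int]]
    unpaired_index: np.ndarray
    n_a_unpaired: int
    n_b_unpaired: int
    observed_mask: np.ndarray  # True where the observation carries the A label

    @property
    def n_paired(self) -> int:
        return len(self.clusters)

    @property
    def n_a_total(self) -> int:
        return int(self.observed_mask.sum())

    @property
    def n_total(self) -> int:
        return len(self.values)


def build_structure(a_map: dict, b_map: dict) -> PairedStructure:
    """Assemble a :class:`PairedStructure` from per-index-subject value maps.

    Map values may be scalars or sequences (an index subject contributing
    several observations to one group, e.g. two peers per survivor).
    """
    keys = sorted(set(a_map) | set(b_map), key=str)
    values: list = []
    mask: list[bool] = []
    clusters: list[tuple[np.ndarray, int]] = []
    unpaired: list[int] = []
    n_a_unp = 0
    n_b_unp = 0
    for k in keys:
        a_vals = _as_values(a_map[k]) if k in a_map else []
        b_vals = _as_values(b_map[k]) if k in b_map else []
        a_vals = [v for v in a_vals if v is not None]
        b_vals = [v for v in b_vals if v is not None]
        if not a_vals and not b_vals:
            continue
        start = len(values)
        values.extend(a_vals)
        mask.extend([True] * len(a_vals))
        values.extend(b_vals)
        mask.extend([False] * len(b_vals))
        idx = np.arange(start, len(values))
        if a_vals and b_vals:
            clusters.append((idx, len(a_vals)))
        else:
            unpaired.extend(idx.tolist())
            n_a_unp += len(a_vals)
            n_b_unp += len(b_vals)
    arr = np.empty(len(values), dtype=object)
    arr[:] = values
    return PairedStructure(
        values=arr,
        clusters=clusters,
        unpaired_index=np.asarray(unpaired, dtype=np.intp),
        n_a_unpaired=n_a_unp,
        n_b_unpaired=n_b_unp,
        observed_mask=np.asarray(mask, dtype=bool),
    )


def n_arrangements(structure: PairedStructure) -> int:
    """Number of distinct label arrangements in the permutation null."""
    total = 1
    for idx, n_a in structure.clusters:
        total *= math.comb(len(idx), n_a)
    m = len(structure.unpaired_index)
    total *= math.comb(m, structure.n_a_unpaired)
    return total


@dataclass
class NullDistribution:
    """The observed statistic and its permutation-null replicates."""

    observed: float
    stats: np.ndarray
    method: str  # exact_enumeration | monte_carlo
    n_draws: int  # arrangements enumerated, or Monte Carlo samples
    expected: float | None  # E[statistic] under the null (None if unused)

    def _tol(self) -> float:
        scale = max(1.0, abs(self.observed), float(np.max(np.abs(self.stats), initial=0.0)))
        return 1e-9 * scale

    def p_lower(self) -> float:
        """P(null <= observed); the observed arrangement counts in Monte Carlo."""
        hits = int(np.sum(self.stats <= self.observed + self._tol()))
        if self.method == "exact_enumeration":
            return hits / len(self.stats)
        return (1 + hits) / (len(self.stats) + 1)

    def p_upper(self) -> float:
        hits = int(np.sum(self.stats >= self.observed - self._tol()))
        if self.method == "exact_enumeration":
            return hits / len(self.stats)
        return (1 + hits) / (len(self.stats) + 1)

    def p_center(self) -> float:
        """P(|null - E| >= |observed - E|): the two-sided tail around the null mean."""
        e = self.expected if self.expected is not None else float(self.stats.mean())
        obs_dev = abs(self.observed - e)
        hits = int(np.sum(np.abs(self.stats - e) >= obs_dev - self._tol()))
        if self.method == "exact_enumeration":
            return hits / len(self.stats)
        return (1 + hits) / (len(self.stats) + 1)

    def p_tie(self) -> float:
        """P(null == observed), used by the label-swap antisymmetry identity."""
        tol = self._tol()
        hits = int(np.sum(np.abs(self.stats - self.observed) <= tol))
        if self.method == "exact_enumeration":
            return hits / len(self.stats)
        return hits / len(self.stats)


def resolve_method(structure: PairedStructure, method: str, exact_cap: int = EXACT_CAP) -> str:
    """Pick exact enumeration vs Monte Carlo; enforce the enumeration cap."""
    method = normalize_method(method)
    n_arr = n_arrangements(structure)
    if method == "auto":
        return "exact_enumeration" if n_arr <= exact_cap else "monte_carlo"
    if method == "exact_enumeration" and n_arr > exact_cap:
        raise CapacityError(
            f"exact enumeration needs {n_arr} arrangements (cap {exact_cap}); "
            "use method='monte_carlo'"
        )
    return method


def _check_nonempty(structure: PairedStructure) -> None:
    n_a = structure.n_a_total
    if n_a == 0 or n_a == structure.n_total:
        raise InsufficientDataError(
            "both groups need at least one usable observation "
            f"(group sizes {n_a} and {structure.n_total - n_a})"
        )


# ---------------------------------------------------------------------------
# Rank-sum statistic


def midranks(values) -> np.ndarray:
    """Average ranks (midranks) of a pooled sample, ties averaged."""
    return rankdata(np.asarray(values, dtype=float), method="average")


def _cluster_options_sums(ranks: np.ndarray, clusters) -> list[np.ndarray]:
    """For each cluster, the possible sums of A-labelled ranks."""
    out = []
    for idx, n_a in clusters:
        r = ranks[idx]
        opts = np.array(
            [float(np.sum(c)) for c in itertools.combinations(r, n_a)], dtype=float
        )
        out.append(opts)
    return out


def ranksum_null(
    structure: PairedStructure,
    method: str = "auto",
    n_permutations: int = 9999,
    seed: int = 0,
    exact_cap: int = EXACT_CAP,
) -> NullDistribution:
    """Null distribution of the group-A rank sum under the structured permutation."""
    _check_nonempty(structure)
    mode = resolve_method(structure, method, exact_cap)
    ranks = midranks(structure.values)
    observed = float(ranks[structure.observed_mask].sum())
    cluster_opts = _cluster_options_sums(ranks, structure.clusters)
    unp_ranks = ranks[structure.unpaired_index]
    m = len(unp_ranks)
    n_au = structure.n_a_unpaired

    expected = sum(
        (n_a / len(idx)) * float(ranks[idx].sum()) for idx, n_a in structure.clusters
    )
    if m:
        expected += (n_au / m) * float(unp_ranks.sum())

    if mode == "exact_enumeration":
        paired = np.zeros(1)
        for opts in cluster_opts:
            paired = (paired[:, None] + opts[None, :]).ravel()
        if m == 0 or n_au == 0:
            unp = np.zeros(1)
        elif n_au == m:
            unp = np.array([float(unp_ranks.sum())])
        else:
            count = math.comb(m, n_au)
            unp = np.fromiter(
                (float(np.sum(c)) for c in itertools.combinations(unp_ranks, n_au)),
                dtype=float,
                count=count,
            )
        stats = (paired[:, None] + unp[None, :]).ravel()
        return NullDistribution(observed, stats, mode, len(stats), expected)

    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    stats = np.zeros(n_permutations)
    # group clusters by option count so each group needs one vectorized draw
    by_nopt: dict[int, list[np.ndarray]] = {}
    for opts in cluster_opts:
        by_nopt.setdefault(len(opts), []).append(opts)
    for n_opt, group in sorted(by_nopt.items()):
        arr = np.stack(group)  # (g, n_opt)
        if n_opt == 1:
            stats += arr[:, 0].sum()
            continue
        idx = rng.integers(0, n_opt, size=(n_permutations, len(group)))
        stats += arr[np.arange(len(group))[None, :], idx].sum(axis=1)
    if m and 0 < n_au < m:
        tiled = np.tile(unp_ranks, (n_permutations, 1))
        rng.permuted(tiled, axis=1, out=tiled)
        stats += tiled[:, :n_au].sum(axis=1)
    elif m and n_au == m:
        stats += float(unp_ranks.sum())
    return NullDistribution(observed, stats, mode, n_permutations, expected)


# ---------------------------------------------------------------------------
# Chi-square deviation statistic (categorical marginals)


def _encode(values: np.ndarray) -> tuple[np.ndarray, int]:
    levels, codes = np.unique(np.asarray([str(v) for v in values]), return_inverse=True)
    return codes.astype(np.intp), len(levels)


def chisq_null(
    structure: PairedStructure,
    method: str = "auto",
    n_permutations: int = 9999,
    seed: int = 0,
    exact_cap: int = EXACT_CAP,
) -> NullDistribution:
    """Null distribution of the Pearson chi-square statistic on the 2xK table.

    Group sizes and pooled category totals are invariant under label
    permutation, so the statistic is a function of group A's category counts
    alone; large values indicate compositional difference (upper tail).
    """
    _check_nonempty(structure)
    mode = resolve_method(structure, method, exact_cap)
    codes, k = _encode(structure.values)
    if k < 2:
        raise InsufficientDataError("need at least 2 pooled categories")
    n = structure.n_total
    n_a = structure.n_a_total
    n_b = n - n_a
    totals = np.bincount(codes, minlength=k).astype(float)
    e_a = n_a * totals / n
    e_b = n_b * totals / n

    def chi2(counts_a: np.ndarray) -> np.ndarray:
        counts_b = totals - counts_a
        return ((counts_a - e_a) ** 2 / e_a + (counts_b - e_b) ** 2 / e_b).sum(axis=-1)

    obs_counts = np.bincount(codes[structure.observed_mask], minlength=k).astype(float)
    observed = float(chi2(obs_counts))

    cluster_opts = []
    for idx, n_ac in structure.clusters:
        c = codes[idx]
        opts = np.stack(
            [np.bincount(np.fromiter(sel, dtype=np.intp, count=n_ac), minlength=k)
             if n_ac else np.zeros(k, dtype=np.int64)
             for sel in itertools.combinations(c, n_ac)]
        )
        cluster_opts.append(opts.astype(np.int64))
    unp_codes = codes[structure.unpaired_index]
    m = len(unp_codes)
    n_au = structure.n_a_unpaired

    if mode == "exact_enumeration":
        paired = np.zeros((1, k), dtype=np.int64)
        for opts in cluster_opts:
            paired = (paired[:, None, :] + opts[None, :, :]).reshape(-1, k)
        if m == 0 or n_au == 0:
            unp = np.zeros((1, k), dtype=np.int64)
        elif n_au == m:
            unp = np.bincount(unp_codes, minlength=k).astype(np.int64)[None, :]
        else:
            count = math.comb(m, n_au)
            unp = np.stack(
                [np.bincount(np.fromiter(sel, dtype=np.intp, count=n_au), minlength=k)
                 for sel in itertools.combinations(unp_codes, n_au)]
            ).astype(np.int64)
        chunks = []
        step = max(1, (4 * 10**6) // max(len(unp), 1))
        for i in range(0, len(paired), step):
            tot = paired[i : i + step, None, :] + unp[None, :, :]
            chunks.append(chi2(tot.reshape(-1, k).astype(float)))
        stats = np.concatenate(chunks)
        return NullDistribution(observed, stats, mode, len(stats), float(stats.mean()))

    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_permutations, k))
    by_nopt: dict[int, list[np.ndarray]] = {}
    for opts in cluster_opts:
        by_nopt.setdefault(len(opts), []).append(opts)
    for n_opt, group in sorted(by_nopt.items()):
        arr = np.stack(group)  # (g, n_opt, k)
        if n_opt == 1:
            counts += arr[:, 0, :].sum(axis=0)
            continue
        idx = rng.integers(0, n_opt, size=(n_permutations, len(group)))
        counts += arr[np.arange(len(group))[None, :], idx].sum(axis=1)
    if m and 0 < n_au < m:
        tiled = np.tile(unp_codes, (n_permutations, 1))
        rng.permuted(tiled, axis=1, out=tiled)
        sel = tiled[:, :n_au]
        for cat in range(k):
            counts[:, cat] += (sel == cat).sum(axis=1)
    elif m and n_au == m:
        counts += np.bincount(unp_codes, minlength=k)
    stats = chi2(counts)
    return NullDistribution(observed, stats, mode, n_permutations, float(stats.mean()))
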