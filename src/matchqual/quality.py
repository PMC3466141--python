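"""Pair-level match quality: absolute pair distances and the one-sided test.

Match quality is operationalized as the absolute difference between a
comparison subject and their matched survivor on each matching variable. For
every variable, the peer-survivor distances and the listed-survivor distances
form a partially paired two-sample problem (a survivor may contribute a
distance to both groups, one, or neither), tested with the structured
permutation null in :mod:`matchqual.permutation`.

The one-sided alternative is fixed as "peer matching is better", i.e. peer
distances are stochastically smaller, so small one-sided p-values favour the
peer method and p-values near 1 favour the listed sample (read p < 0.05 as
peers better, p > 0.95 as listed better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, participant_value
from .errors import InsufficientDataError, SpecError
from .permutation import (
    EXACT_CAP,
    build_structure,
    midranks,
    normalize_method,
    ranksum_null,
)
from .varspec import VariableSpec, default_varspecs

PEER_RULES = ("first", "mean_distance", "all")


def pair_distance(index_value, comparison_value, spec: VariableSpec):
    """Absolute within-pair difference on one variable; ``None`` if either is missing.

    continuous -> |difference|; binary/nominal -> 0/1 disagreement;
    ordinal -> absolute rank difference on the declared level order.
    """
    if index_value is None or comparison_value is None:
        return None
    if isinstance(index_value, float) and np.isnan(index_value):
        return None
    if isinstance(comparison_value, float) and np.isnan(comparison_value):
        return None
    if spec.scale == "continuous":
        return abs(float(index_value) - float(comparison_value))
    if spec.scale in ("binary", "nominal"):
        return 0.0 if index_value == comparison_value else 1.0
    # ordinal
    levels = spec.ordinal_levels
    for v in (index_value, comparison_value):
        if v not in levels:
            raise SpecError(
                f"variable {spec.name!r}: value {v!r} not in declared levels {levels}"
            )
    return float(abs(levels.index(index_value) - levels.index(comparison_value)))


def rank_sum_statistic(group_a, group_b) -> float:
    """Sum of midranks of ``group_a`` within the pooled sample."""
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise InsufficientDataError("rank_sum_statistic requires two non-empty groups")
    ranks = midranks(a + b)
    return float(ranks[: len(a)].sum())


@dataclass
class PairDistanceSet:
    """Per-variable absolute pair distances, keyed by survivor, per group.

    Values are non-negative floats, or tuples of floats under the ``all``
    peer rule (a survivor's two peers kept as one correlated cluster).
    """

    variable: str
    peer_distances: dict
    listed_distances: dict

    def __post_init__(self) -> None:
        for name, dists in (("peer", self.peer_distances), ("listed", self.listed_distances)):
            for sid, d in dists.items():
                vals = d if isinstance(d, (list, tuple)) else (d,)
                for v in vals:
                    if v is not None and v < 0:
                        raise ValueError(
                            f"{name} distance for survivor {sid} is negative: {v}"
                        )


@dataclass
class PermutationResult:
    """Outcome of the partially paired rank-sum permutation test."""

    observed_statistic: float
    n_permutations: int
    p_one_sided: float
    p_two_sided: float
    method: str
    seed: int | None
    n_paired: int
    n_peer_only: int
    n_listed_only: int


def _select_peer_distances(cohort: CohortTable, spec: VariableSpec, rule: str) -> dict:
    out: dict = {}
    for mset in cohort.matched_sets:
        s_val = cohort.value(mset.survivor_id, spec.name)
        dists = []
        for pid in mset.peer_ids:
            d = pair_distance(s_val, cohort.value(pid, spec.name), spec)
            if d is not None:
                dists.append(d)
        if not dists:
            continue
        if rule == "first":
            # first enrolled peer defines the pair; a missing value there
            # excludes the survivor for this variable (complete case)
            d0 = pair_distance(
                s_val, cohort.value(mset.peer_ids[0], spec.name), spec
            )
            if d0 is not None:
                out[mset.survivor_id] = d0
        elif rule == "mean_distance":
            out[mset.survivor_id] = float(np.mean(dists))
        elif rule == "all":
            out[mset.survivor_id] = tuple(dists)
        else:
            raise ValueError(f"unknown peer rule {rule!r}; expected one of {PEER_RULES}")
    return out


def compute_pair_distances(
    cohort: CohortTable, spec: VariableSpec, peer_rule: str = "first"
) -> PairDistanceSet:
    """Absolute pair distances on one variable for both comparison groups."""
    if peer_rule not in PEER_RULES:
        raise ValueError(f"unknown peer rule {peer_rule!r}; expected one of {PEER_RULES}")
    peer = _select_peer_distances(cohort, spec, peer_rule)
    listed: dict = {}
    for mset in cohort.matched_sets:
        if mset.listed_id is None:
            continue
        d = pair_distance(
            cohort.value(mset.survivor_id, spec.name),
            cohort.value(mset.listed_id, spec.name),
            spec,
        )
        if d is not None:
            listed[mset.survivor_id] = d
    return PairDistanceSet(spec.name, peer, listed)


def permutation_test_partially_paired(
    distances: PairDistanceSet,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    exact_cap: int = EXACT_CAP,
) -> PermutationResult:
    """Test whether peer distances are stochastically smaller than listed distances.

    The observed statistic is the rank sum of the peer-distance group in the
    pooled sample. Small rank sums mean small peer distances, i.e. better peer
    matching; ``p_one_sided`` is the null probability of a rank sum as small
    as or smaller than observed. ``p_two_sided`` measures deviation from the
    null mean in either direction.
    """
    structure = build_structure(distances.peer_distances, distances.listed_distances)
    nd = ranksum_null(
        structure,
        method=method,
        n_permutations=n_permutations,
        seed=seed,
        exact_cap=exact_cap,
    )
    exact = nd.method == "exact_enumeration"
    return PermutationResult(
        observed_statistic=nd.observed,
        n_permutations=nd.n_draws,
        p_one_sided=nd.p_lower(),
        p_two_sided=nd.p_center(),
        method=nd.method,
        seed=None if exact else seed,
        n_paired=structure.n_paired,
        n_peer_only=structure.n_a_unpaired,
        n_listed_only=structure.n_b_unpaired,
    )


def match_quality_report(
    cohort: CohortTable,
    varspecs: list[VariableSpec] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    peer_rule: str = "first",
) -> pd.DataFrame:
    """One match-quality test per variable: the per-variable p-value table.

    Variables where one comparison group has no usable distances are flagged
    (``flag`` column) rather than silently dropped.
    """
    if varspecs is None:
        varspecs = default_varspecs()
    if not cohort.survivors:
        raise InsufficientDataError("cohort contains no survivors")
    normalize_method(method)
    rows = []
    for i, spec in enumerate(varspecs):
        dists = compute_pair_distances(cohort, spec, peer_rule)
        n_peer = sum(
            len(v) if isinstance(v, tuple) else 1 for v in dists.peer_distances.values()
        )
        n_listed = len(dists.listed_distances)
        row = {
            "variable": spec.name,
            "n_peer": n_peer,
            "n_listed": n_listed,
            "n_paired": np.nan,
            "statistic": np.nan,
            "p_one_sided": np.nan,
            "method": "",
            "seed": seed + i,
            "flag": "",
        }
        if not dists.peer_distances or not dists.listed_distances:
            row["flag"] = "insufficient_data"
        else:
            res = permutation_test_partially_paired(
                dists, n_permutations=n_permutations, seed=seed + i, method=method
            )
            row.update(
                n_paired=res.n_paired,
                statistic=res.observed_statistic,
                p_one_sided=res.p_one_sided,
                method=res.method,
            )
        rows.append(row)
    return pd.DataFrame(rows)
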