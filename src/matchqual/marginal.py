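"""Marginal (group-level) distribution comparisons, two-sided.

These tests ask whether the survivors' whole-group distribution of a variable
equals that of a comparison group, ignoring pair identity — the complement of
the pair-level match-quality test. The same structured permutation null is
used: values of a survivor and their matched comparison subject(s) form a
cluster whose labels are permuted; survivors without a usable comparison
value, and comparison values whose survivor value is missing, enter the
unpaired pool with count-preserving label reassignment.

A key caution: marginal equality does not imply individual-level match — the
pairs (1,10), (10,1), (1,10), (10,1) have identical marginal distributions
(both means 5.5) while every pair differs by 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import InsufficientDataError
from .permutation import (
    EXACT_CAP,
    build_structure,
    chisq_null,
    normalize_method,
    ranksum_null,
)
from .varspec import VariableSpec, default_varspecs

GROUP_PAIRS = ("survivor_vs_peer", "survivor_vs_listed")


@dataclass
class MarginalResult:
    """Two-sided marginal comparison of one variable for one group pair."""

    group_pair: str
    n_index: int
    n_comparison: int
    summary_index: dict
    summary_comparison: dict
    statistic: float
    p_two_sided: float
    method: str
    seed: int | None
    variable: str = ""
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)


def _flatten(values_map: dict) -> list:
    out = []
    for v in values_map.values():
        out.extend(v if isinstance(v, (list, tuple)) else [v])
    return [x for x in out if x is not None]


def _continuous_summary(values: list) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"n": len(arr), "mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")}


def _categorical_summary(values: list) -> dict:
    n = len(values)
    levels, counts = np.unique([str(v) for v in values], return_counts=True)
    return {"n": n, "proportions": {lv: c / n for lv, c in zip(levels, counts.tolist())}}


def marginal_test_continuous(
    index_values: dict,
    comparison_values: dict,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    group_pair: str = "survivor_vs_peer",
    exact_cap: int = EXACT_CAP,
) -> MarginalResult:
    """Rank-sum permutation test of marginal location, respecting pairing.

    Both maps are keyed by survivor id: ``index_values`` holds survivor
    values, ``comparison_values`` the matched comparison subjects' values
    (missing entries make that survivor's values unpaired).
    """
    idx = {k: v for k, v in index_values.items() if v is not None}
    cmp_ = {k: v for k, v in comparison_values.items() if v is not None}
    a_flat, b_flat = _flatten(idx), _flatten(cmp_)
    if len(a_flat) < 2 or len(b_flat) < 2:
        raise InsufficientDataError(
            f"marginal test needs >=2 complete cases per group "
            f"(got {len(a_flat)} and {len(b_flat)})"
        )
    structure = build_structure(idx, cmp_)
    nd = ranksum_null(
        structure, method=method, n_permutations=n_permutations, seed=seed, exact_cap=exact_cap
    )
    exact = nd.method == "exact_enumeration"
    return MarginalResult(
        group_pair=group_pair,
        n_index=len(a_flat),
        n_comparison=len(b_flat),
        summary_index=_continuous_summary(a_flat),
        summary_comparison=_continuous_summary(b_flat),
        statistic=nd.observed,
        p_two_sided=nd.p_center(),
        method=nd.method,
        seed=None if exact else seed,
    )


def marginal_test_categorical(
    index_values: dict,
    comparison_values: dict,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    group_pair: str = "survivor_vs_peer",
    exact_cap: int = EXACT_CAP,
) -> MarginalResult:
    """Permuted chi-square test of group-by-category composition.

    With a single pooled category the test is degenerate: the result carries
    p = 1 and a warning flag instead of an error.
    """
    idx = {k: v for k, v in index_values.items() if v is not None}
    cmp_ = {k: v for k, v in comparison_values.items() if v is not None}
    a_flat, b_flat = _flatten(idx), _flatten(cmp_)
    if not a_flat or not b_flat:
        raise InsufficientDataError("marginal test needs complete cases in both groups")
    pooled = {str(v) for v in a_flat} | {str(v) for v in b_flat}
    base = dict(
        group_pair=group_pair,
        n_index=len(a_flat),
        n_comparison=len(b_flat),
        summary_index=_categorical_summary(a_flat),
        summary_comparison=_categorical_summary(b_flat),
    )
    if len(pooled) < 2:
        return MarginalResult(
            statistic=0.0,
            p_two_sided=1.0,
            method="degenerate",
            seed=None,
            degenerate=True,
            warnings=["single pooled category; test degenerate"],
            **base,
        )
    structure = build_structure(idx, cmp_)
    nd = chisq_null(
        structure, method=method, n_permutations=n_permutations, seed=seed, exact_cap=exact_cap
    )
    exact = nd.method == "exact_enumeration"
    return MarginalResult(
        statistic=nd.observed,
        p_two_sided=nd.p_upper(),
        method=nd.method,
        seed=None if exact else seed,
        **base,
    )


def _collect_marginal_maps(
    cohort: CohortTable, variable: str, comparison_group: str, peer_rule: str
) -> tuple[dict, dict]:
    """Survivor-keyed value maps for the index group and one comparison group."""
    idx: dict = {}
    cmp_: dict = {}
    for mset in cohort.matched_sets:
        s_val = cohort.value(mset.survivor_id, variable)
        if s_val is not None:
            idx[mset.survivor_id] = s_val
        if comparison_group == "peer":
            ids = list(mset.peer_ids)
            if peer_rule == "first" and ids:
                ids = ids[:1]
            vals = [cohort.value(i, variable) for i in ids]
            vals = [v for v in vals if v is not None]
            if vals:
                cmp_[mset.survivor_id] = tuple(vals) if len(vals) > 1 else vals[0]
        else:
            if mset.listed_id is not None:
                v = cohort.value(mset.listed_id, variable)
                if v is not None:
                    cmp_[mset.survivor_id] = v
    return idx, cmp_


def marginal_report(
    cohort: CohortTable,
    varspecs: list[VariableSpec] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    peer_rule: str = "all",
) -> pd.DataFrame:
    """Marginal comparisons for every variable and both group pairs.

    The default ``peer_rule='all'`` counts every completed peer in the peer
    margin (the study reported all 44 peers against 100 survivors); under
    ``'first'`` only the first enrolled peer per survivor enters.
    """
    if varspecs is None:
        varspecs = default_varspecs()
    if not cohort.survivors:
        raise InsufficientDataError("cohort contains no survivors")
    normalize_method(method)
    rows = []
    for i, spec in enumerate(varspecs):
        for j, grp in enumerate(("peer", "listed")):
            pair = f"survivor_vs_{grp}"
            idx, cmp_ = _collect_marginal_maps(cohort, spec.name, grp, peer_rule)
            test_seed = seed + 2 * i + j
            row = {
                "variable": spec.name,
                "group_pair": pair,
                "n_index": len(_flatten(idx)),
                "n_comparison": len(_flatten(cmp_)),
                "summary_index": None,
                "summary_comparison": None,
                "statistic": np.nan,
                "p_two_sided": np.nan,
                "method": "",
                "seed": test_seed,
                "flag": "",
            }
            try:
                if spec.is_categorical:
                    res = marginal_test_categorical(
                        idx, cmp_, n_permutations=n_permutations, seed=test_seed,
                        method=method, group_pair=pair,
                    )
                else:
                    res = marginal_test_continuous(
                        idx, cmp_, n_permutations=n_permutations, seed=test_seed,
                        method=method, group_pair=pair,
                    )
            except InsufficientDataError:
                row["flag"] = "insufficient_data"
                rows.append(row)
                continue
            row.update(
                summary_index=res.summary_index,
                summary_comparison=res.summary_comparison,
                statistic=res.statistic,
                p_two_sided=res.p_two_sided,
                method=res.method,
                flag="degenerate" if res.degenerate else "",
            )
            rows.append(row)
    return pd.DataFrame(rows)
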