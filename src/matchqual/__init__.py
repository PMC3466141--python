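"""matchqual: comparison-group match quality, marginal tests, recruitment costs.

Tools for evaluating candidate comparison groups against an index group of
cancer survivors: per-pair absolute-distance match-quality tests and marginal
distribution tests under a partially paired permutation null, recruitment
funnel yield and cost-per-complete accounting, and synthetic cohort
generators for calibration studies.
"""

__version__ = "1.0.0"

from .accounting import (
    RecruitmentLedger,
    accounting_report,
    cost_per_complete,
    total_cost,
    yield_rate,
)
from .cohort import (
    CohortTable,
    MatchedSet,
    Participant,
    build_matched_sets,
    derive_smoking_duration,
    read_cohort,
    write_cohort,
)
from .marginal import (
    MarginalResult,
    marginal_report,
    marginal_test_categorical,
    marginal_test_continuous,
)
from .quality import (
    PairDistanceSet,
    PermutationResult,
    compute_pair_distances,
    match_quality_report,
    pair_distance,
    permutation_test_partially_paired,
    rank_sum_statistic,
)
from .simulate import (
    GeneratorConfig,
    SimulationSummary,
    generate_cohort,
    generate_null_cohort,
    generate_recruitment_ledger,
    generate_shifted_cohort,
    power_simulation,
    type_one_error_simulation,
)
from .varspec import VariableSpec, default_varspecs, load_varspecs

__all__ = [
    "__version__",
    "CohortTable",
    "GeneratorConfig",
    "MarginalResult",
    "MatchedSet",
    "PairDistanceSet",
    "Participant",
    "PermutationResult",
    "RecruitmentLedger",
    "SimulationSummary",
    "VariableSpec",
    "accounting_report",
    "build_matched_sets",
    "compute_pair_distances",
    "cost_per_complete",
    "default_varspecs",
    "derive_smoking_duration",
    "generate_cohort",
    "generate_null_cohort",
    "generate_recruitment_ledger",
    "generate_shifted_cohort",
    "load_varspecs",
    "marginal_report",
    "marginal_test_categorical",
    "marginal_test_continuous",
    "match_quality_report",
    "pair_distance",
    "permutation_test_partially_paired",
    "power_simulation",
    "rank_sum_statistic",
    "read_cohort",
    "total_cost",
    "type_one_error_simulation",
    "write_cohort",
    "yield_rate",
]


def run_study(*args, **kwargs):
    """Lazy wrapper for :func:`matchqual.report.run_study` (avoids import cycle)."""
    from .report import run_study as _run

    return _run(*args, **kwargs)
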