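"""End-to-end study report: marginal tests + match quality + cost accounting.

One call runs both analytic strategies on a cohort CSV and, if a recruitment
ledger is supplied, the cost accounting, returning a single serializable
:class:`StudyReport`. Reports are deterministic given the seed and carry the
seed and input digests for provenance; re-running with identical inputs
produces byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accounting import accounting_report, read_ledgers
from .cohort import read_cohort
from .errors import MatchQualError
from .marginal import marginal_report
from .quality import match_quality_report
from .varspec import default_varspecs, load_varspecs

log = logging.getLogger("matchqual")

SMALL_N = 10  # per-group count below which a warning is attached


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


@dataclass
class StudyReport:
    """Combined analysis artifact: metadata, three tables, warnings."""

    metadata: dict
    marginal: pd.DataFrame
    quality: pd.DataFrame
    accounting: pd.DataFrame | None
    warnings: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        def records(frame):
            if frame is None:
                return None
            out = frame.to_dict(orient="records")
            for row in out:
                for k, v in row.items():
                    if isinstance(v, float) and math.isnan(v):
                        row[k] = None
            return out

        return {
            "metadata": self.metadata,
            "marginal": records(self.marginal),
            "quality": records(self.quality),
            "accounting": records(self.accounting),
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        self.marginal.to_csv(out / "marginal.tsv", sep="\t", index=False)
        self.quality.to_csv(out / "quality.tsv", sep="\t", index=False)
        if self.accounting is not None:
            self.accounting.to_csv(out / "costs.tsv", sep="\t", index=False)


def run_study(
    cohort_path,
    varspec_path=None,
    ledger_path=None,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "auto",
    peer_rule: str = "first",
    rounding: str = "truncate",
    out_dir=None,
) -> StudyReport:
    """Run the full method-comparison analysis on one cohort.

    The ledger is optional: without it the accounting section is marked
    absent rather than failing. Validation errors propagate; statistical
    findings never affect the exit path.
    """
    varspecs = load_varspecs(varspec_path) if varspec_path else default_varspecs()
    cohort = read_cohort(cohort_path, varspecs)
    log.info("cohort: %d participants, %d matched sets", len(cohort), len(cohort.matched_sets))

    warnings: list[dict] = []
    for exc in cohort.exclusions:
        warnings.append({"code": "ROW_EXCLUDED", **exc})

    try:
        marginal = marginal_report(
            cohort, varspecs, n_permutations=n_permutations, seed=seed, method=method,
            peer_rule="all" if peer_rule == "all" else peer_rule,
        )
        quality = match_quality_report(
            cohort, varspecs, n_permutations=n_permutations, seed=seed, method=method,
            peer_rule=peer_rule,
        )
    except MatchQualError as exc:
        raise type(exc)(f"analysis failed on {cohort_path}: {exc}") from exc

    for frame, pcol in ((marginal, "p_two_sided"), (quality, "p_one_sided")):
        for _, row in frame.iterrows():
            if row.get("flag"):
                warnings.append(
                    {"code": "VARIABLE_FLAGGED", "variable": row["variable"], "flag": row["flag"]}
                )
    n_peer = len(cohort.group("peer"))
    n_listed = len(cohort.group("listed"))
    for name, n in (("peer", n_peer), ("listed", n_listed)):
        if n < SMALL_N:
            warnings.append({"code": "SMALL_N", "group": name, "n": n})

    accounting = None
    if ledger_path is not None:
        accounting = accounting_report(read_ledgers(ledger_path), rounding=rounding)
    else:
        warnings.append({"code": "NO_LEDGER", "message": "accounting section absent"})

    metadata = {
        "package": "matchqual",
        "version": __version__,
        "seed": seed,
        "n_permutations": n_permutations,
        "method": method,
        "peer_rule": peer_rule,
        "rounding": rounding,
        "cohort_digest": _digest(cohort_path),
        "varspec_digest": _digest(varspec_path) if varspec_path else "default",
        "ledger_digest": _digest(ledger_path) if ledger_path else None,
        "n_survivors": len(cohort.survivors),
        "n_peer": n_peer,
        "n_listed": n_listed,
    }
    report = StudyReport(metadata, marginal, quality, accounting, warnings)
    if out_dir is not None:
        report.write(out_dir)
    return report
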