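"""Synthetic survivor/peer/listed cohorts and recruitment funnels.

The generator emulates the study design the analysis assumes: an index group
of older oral/pharyngeal cancer survivors (mean age ~65, 72% men, heavy
lifetime tobacco exposure), a peer-nominated comparison arm (each survivor
nominates 0-2 peers, each nominee reached with ~48% success, so ~44 completed
peers per 100 survivors), and a listed-sample arm hard-matched on sex and age
within +/-5 years with all other variables drawn independently of the
survivor.

Three generators are provided:

* :func:`generate_cohort` — the study emulator, with arm-specific fidelity
  (younger peers, hard listed age window, peer sex only loosely matched);
* :func:`generate_null_cohort` — a validation harness in which both comparison
  groups' values are drawn from the *identical* conditional law given the
  survivor, the exchangeability null of the match-quality test;
* :func:`generate_shifted_cohort` — the null harness plus a location shift on
  the designated variable for the listed arm only, making listed pair
  distances stochastically larger (power analysis); shift 0 reduces exactly
  to the null generator.

Smoking and alcohol variables are zero-inflated non-negatives (a point mass
at zero plus a truncated normal), which is how means far below their standard
deviations arise in this population.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .accounting import RecruitmentLedger
from .cohort import CohortTable, Participant
from .errors import ConfigError
from .quality import compute_pair_distances, permutation_test_partially_paired
from .varspec import VariableSpec

_ALC_VARS = ("alc_freq_month", "alc_typical", "alc_six_freq")

#: Population marginals for survivor-like subjects: demographics centred on
#: older, mostly male, mostly white samples; smoking/alcohol zero-inflated.
DEFAULT_MARGINALS: dict = {
    "age": {"mean": 64.90, "sd": 10.09, "min": 30.0},
    "sex": {"male": 0.72},
    "race": {"white": 0.94, "black": 0.02, "other": 0.04},
    "education": {"less-than-HS": 0.07, "HS-grad": 0.213, "post-HS": 0.717},
    "employment": {"employed": 0.33, "retired": 0.64, "other": 0.03},
    "smoking": {
        "ever_prob": 0.60,
        "current_prob": 0.15,  # marginal prevalence of current smoking
        "current_days_mean": 28.0,
        "current_days_sd": 5.0,
        "age_first_mean": 17.0,
        "age_first_sd": 3.0,
    },
    "alc_freq_month": {"zero_prob": 0.25, "mean": 2.0, "sd": 1.5},
    "alc_typical": {"zero_prob": 0.25, "mean": 0.9, "sd": 0.7},
    "alc_six_freq": {"zero_prob": 0.40, "mean": 1.3, "sd": 1.0},
}

#: Continuous pair noise (SD) for the peer arm of the study emulator.
DEFAULT_PEER_NOISE_SD: dict = {
    "age": 9.6,  # inflates peer age SD from 10.09 toward the observed 13.9
    "days_smoked_30": 6.0,
    "alc_freq_month": 0.8,
    "alc_typical": 0.5,
    "alc_six_freq": 0.7,
}

#: Probability a peer simply shares the survivor's category.
DEFAULT_PEER_COPY_PROB: dict = {
    "race": 0.90,
    "education": 0.80,
    "employment": 0.50,
    "smoking_status": 0.70,
}

#: Pair noise for the null/shifted validation harness (both arms identical).
DEFAULT_NULL_NOISE_SD: dict = {
    "age": 5.0,
    "days_smoked_30": 5.0,
    "alc_freq_month": 0.8,
    "alc_typical": 0.5,
    "alc_six_freq": 0.7,
}

DEFAULT_NULL_COPY_PROB: dict = {
    "race": 0.90,
    "education": 0.80,
    "employment": 0.60,
    "smoking_status": 0.70,
}

#: Funnel stage composition per arm. ``p_usable`` is the fraction of
#: candidates with workable numbers; ``p_complete`` the completion probability
#: among usable; ``stage_probs`` allocate the non-completed usable numbers.
DEFAULT_FUNNEL: dict = {
    "survivor": {
        "n_candidates": 378,
        "p_usable": 372 / 378,
        "p_complete": 100 / 372,
        "stage_probs": {
            "opted_out": 7 / 272,
            "refused": 20 / 272,
            "no_answer": 83 / 272,
            "deceased": 6 / 272,
            "ineligible": 14 / 272,
            "partial": 4 / 272,
        },
        "completes_per_hour": 0.65,
    },
    "peer": {
        # candidates (nominees) are drawn from the nomination model
        "p_usable": 85 / 91,
        "p_complete": 44 / 85,
        "stage_probs": {
            "refused": 12 / 41,
            "ineligible": 14 / 41,
            "no_answer": 15 / 41,
        },
        "completes_per_hour": 0.40,
    },
    "listed": {
        "n_candidates": 980,
        "p_usable": 544 / 980,  # numbers actually dialed
        "p_complete": 101 / 544,
        "stage_probs": {
            "refused": 117 / 443,
            "no_answer": 188 / 443,
            "ineligible": 138 / 443,
        },
        "completes_per_hour": 0.60,
    },
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort and funnel generators.

    Defaults encode the study conditions: 100 survivors, 61% nomination
    probability, 30/61 two-peer probability among nominators, 48.3% nominee
    contact success, a +/-5 year listed age window, a -7.5 year peer age
    shift, and marginals matching the published sample characteristics.
    """

    n_survivors: int = 100
    peer_nomination_prob: float = 0.61
    two_peer_prob: float = 30 / 61
    peer_contact_success: float = 0.483
    listed_completion_prob: float = 0.96
    listed_match_window_years: float = 5.0
    peer_age_shift: float = -7.5
    peer_sex_match_prob: float = 0.35
    peer_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_PEER_NOISE_SD))
    peer_copy_prob: dict = field(default_factory=lambda: dict(DEFAULT_PEER_COPY_PROB))
    null_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NULL_NOISE_SD))
    null_copy_prob: dict = field(default_factory=lambda: dict(DEFAULT_NULL_COPY_PROB))
    shift_variable: str = "age"
    missing_rate: float = 0.02
    marginals: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_MARGINALS))
    funnel: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_FUNNEL))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivors < 1:
            raise ConfigError("n_survivors must be >= 1")
        for name in (
            "peer_nomination_prob",
            "two_peer_prob",
            "peer_contact_success",
            "listed_completion_prob",
            "peer_sex_match_prob",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.listed_match_window_years <= 0:
            raise ConfigError("listed_match_window_years must be positive")
        for d in (self.peer_noise_sd, self.null_noise_sd):
            for k, v in d.items():
                if v < 0:
                    raise ConfigError(f"noise SD for {k} must be >= 0, got {v}")
        if self.marginals["age"]["sd"] <= 0:
            raise ConfigError("age SD must be positive")
        for arm, spec in self.funnel.items():
            if sum(spec["stage_probs"].values()) > 1.0 + 1e-9:
                raise ConfigError(f"funnel stage probabilities for {arm} sum above 1")

    @classmethod
    def perfect_peer_fidelity(cls, n_survivors: int = 100, **kw) -> "GeneratorConfig":
        """Degenerate fidelity: every realized peer equals its survivor exactly."""
        return cls(
            n_survivors=n_survivors,
            peer_age_shift=0.0,
            peer_sex_match_prob=1.0,
            peer_noise_sd={k: 0.0 for k in DEFAULT_PEER_NOISE_SD},
            peer_copy_prob={k: 1.0 for k in DEFAULT_PEER_COPY_PROB},
            missing_rate=0.0,
            **kw,
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: generator config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        base = cls()
        for key in ("marginals", "funnel", "peer_noise_sd", "peer_copy_prob",
                    "null_noise_sd", "null_copy_prob"):
            if key in doc:
                merged = copy.deepcopy(getattr(base, key))
                _deep_update(merged, doc[key])
                doc[key] = merged
        return cls(**doc)


def _deep_update(dst: dict, src: dict) -> None:
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _deep_update(dst[k], v)
        else:
            dst[k] = v


def _categorical(rng, n, probs: dict) -> np.ndarray:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n, p=p)]


def _zero_inflated(rng, n, params: dict) -> np.ndarray:
    """Point mass at zero plus a normal truncated below at zero."""
    zero = rng.random(n) < params["zero_prob"]
    pos = np.abs(rng.normal(params["mean"], params["sd"], n))
    return np.where(zero, 0.0, pos)


def _draw_smoking(rng, n, params: dict, age: np.ndarray) -> dict:
    """A coherent smoking profile: ever/current status, ages, 30-day days."""
    ever = rng.random(n) < params["ever_prob"]
    p_cur_given_ever = min(1.0, params["current_prob"] / max(params["ever_prob"], 1e-12))
    current = ever & (rng.random(n) < p_cur_given_ever)
    age_first = np.clip(
        rng.normal(params["age_first_mean"], params["age_first_sd"], n), 10.0, None
    )
    age_first = np.minimum(age_first, age - 1.0)
    frac = rng.random(n)  # quit point as fraction of the smoking-eligible span
    age_last = age_first + frac * (age - age_first)
    days = np.clip(
        np.rint(rng.normal(params["current_days_mean"], params["current_days_sd"], n)),
        1,
        30,
    ).astype(int)
    return {
        "ever": ever,
        "current": current,
        "age_first": age_first,
        "age_last": age_last,
        "days30": days,
    }


def _perturb_smoking(rng, surv: dict, age_comp: np.ndarray, copy_prob: float,
                     params: dict, noise_sd_days: float) -> dict:
    """Comparison-subject smoking: copy the survivor's profile or redraw."""
    n = len(age_comp)
    keep = rng.random(n) < copy_prob
    fresh = _draw_smoking(rng, n, params, age_comp)
    ever = np.where(keep, surv["ever"], fresh["ever"])
    current = np.where(keep, surv["current"], fresh["current"])
    age_first = np.where(keep, np.minimum(surv["age_first"], age_comp - 1.0), fresh["age_first"])
    age_last = np.where(keep, np.clip(surv["age_last"], age_first, age_comp), fresh["age_last"])
    days_noise = np.rint(rng.normal(0.0, noise_sd_days, n)) if noise_sd_days > 0 else np.zeros(n)
    days = np.where(
        keep,
        np.clip(surv["days30"] + days_noise, 1, 30),
        fresh["days30"],
    ).astype(int)
    return {"ever": ever, "current": current.astype(bool), "age_first": age_first,
            "age_last": age_last, "days30": days}


def _draw_population(rng, n, marginals: dict) -> dict:
    age = np.clip(
        rng.normal(marginals["age"]["mean"], marginals["age"]["sd"], n),
        marginals["age"]["min"],
        None,
    )
    cols = {
        "age": age,
        "sex": np.where(rng.random(n) < marginals["sex"]["male"], "male", "female").astype(object),
        "race": _categorical(rng, n, marginals["race"]),
        "education": _categorical(rng, n, marginals["education"]),
        "employment": _categorical(rng, n, marginals["employment"]),
        "smoking": _draw_smoking(rng, n, marginals["smoking"], age),
    }
    for v in _ALC_VARS:
        cols[v] = _zero_inflated(rng, n, marginals[v])
    return cols


def _smoking_fields(profile: dict, i: int, age: float) -> dict:
    ever = bool(profile["ever"][i])
    current = bool(profile["current"][i]) and ever
    return {
        "age_first_cig": float(profile["age_first"][i]) if ever else None,
        "age_last_cig": (
            None if current or not ever else float(min(profile["age_last"][i], age))
        ),
        "is_current_smoker": current,
        "days_smoked_30": int(profile["days30"][i]) if current else 0,
    }


_MISSABLE = ("education", "employment", "days_smoked_30") + _ALC_VARS


def _apply_missingness(rng, participants: list[Participant], rate: float) -> None:
    if rate <= 0:
        return
    for p in participants:
        drop = rng.random(len(_MISSABLE)) < rate
        for col, d in zip(_MISSABLE, drop):
            if d:
                setattr(p, col, None)


def _make_participant(sid, group, link, sex, race, age, education, employment,
                      smoking_fields, alc) -> Participant:
    return Participant(
        subject_id=sid,
        group=group,
        survivor_link=link,
        sex=sex,
        race=race,
        age=float(age),
        education=education,
        employment=employment,
        alc_freq_month=float(alc[0]),
        alc_typical=float(alc[1]),
        alc_six_freq=float(alc[2]),
        cancer_history=(group == "survivor"),
        **smoking_fields,
    )


def _presence(rng, cfg: GeneratorConfig):
    """Which peer slots and listed matches are realized, per survivor."""
    n = cfg.n_survivors
    nominates = rng.random(n) < cfg.peer_nomination_prob
    two = rng.random(n) < cfg.two_peer_prob
    n_nominees = nominates.astype(int) * (1 + two.astype(int))
    peer_done = np.zeros((n, 2), dtype=bool)
    for slot in range(2):
        reached = rng.random(n) < cfg.peer_contact_success
        peer_done[:, slot] = (n_nominees > slot) & reached
    listed_done = rng.random(n) < cfg.listed_completion_prob
    return nominates, n_nominees, peer_done, listed_done


def nomination_counts(config: GeneratorConfig | None = None, seed: int | None = None) -> dict:
    """Realized nomination funnel for one cohort draw.

    Returns the number of survivors nominating at least one peer, total
    nominees, and completed peers, from the same presence model
    :func:`generate_cohort` uses (identical seed gives identical counts).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    _draw_population(rng, cfg.n_survivors, cfg.marginals)  # keep stream aligned
    nominates, n_nominees, peer_done, _ = _presence(rng, cfg)
    return {
        "n_nominators": int(nominates.sum()),
        "n_nominees": int(n_nominees.sum()),
        "n_completed_peers": int(peer_done.sum()),
    }


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> CohortTable:
    """Generate a study-like cohort with arm-specific match fidelity.

    Peers resemble their survivor (shared categories with high probability,
    continuous values perturbed around the survivor's, ages shifted younger);
    listed subjects share the survivor's sex exactly and age within the
    matching window, with every other variable drawn from the population
    independently of the survivor.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_survivors
    surv = _draw_population(rng, n, cfg.marginals)
    _, _, peer_done, listed_done = _presence(rng, cfg)

    participants: list[Participant] = []
    sids = [f"S{i + 1:04d}" for i in range(n)]
    for i, sid in enumerate(sids):
        participants.append(
            _make_participant(
                sid, "survivor", sid, surv["sex"][i], surv["race"][i], surv["age"][i],
                surv["education"][i], surv["employment"][i],
                _smoking_fields(surv["smoking"], i, surv["age"][i]),
                [surv[v][i] for v in _ALC_VARS],
            )
        )

    for slot in range(2):
        sex_match = rng.random(n) < cfg.peer_sex_match_prob
        sex = np.where(
            sex_match,
            surv["sex"],
            np.where(np.char.equal(surv["sex"].astype(str), "male"), "female", "male"),
        ).astype(object)
        age = np.clip(
            surv["age"] + cfg.peer_age_shift + rng.normal(0.0, cfg.peer_noise_sd["age"], n),
            18.0,
            None,
        )
        cats = {}
        for var in ("race", "education", "employment"):
            fresh = _categorical(rng, n, cfg.marginals[var])
            keep = rng.random(n) < cfg.peer_copy_prob[var]
            cats[var] = np.where(keep, surv[var], fresh).astype(object)
        smoking = _perturb_smoking(
            rng, surv["smoking"], age, cfg.peer_copy_prob["smoking_status"],
            cfg.marginals["smoking"], cfg.peer_noise_sd["days_smoked_30"],
        )
        alc = {
            v: np.maximum(0.0, surv[v] + rng.normal(0.0, cfg.peer_noise_sd[v], n))
            for v in _ALC_VARS
        }
        for i, sid in enumerate(sids):
            if not peer_done[i, slot]:
                continue
            pid = f"P{i + 1:04d}-{slot + 1}"
            participants.append(
                _make_participant(
                    pid, "peer", sid, sex[i], cats["race"][i], age[i],
                    cats["education"][i], cats["employment"][i],
                    _smoking_fields(smoking, i, age[i]),
                    [alc[v][i] for v in _ALC_VARS],
                )
            )

    listed_pop = _draw_population(rng, n, cfg.marginals)
    w = cfg.listed_match_window_years
    listed_age = surv["age"] + rng.uniform(-w, w, n)
    listed_age = np.maximum(listed_age, 18.0)
    # the hard window must survive the floor; survivor ages are far above 18+w
    listed_age = np.where(
        np.abs(listed_age - surv["age"]) > w, surv["age"], listed_age
    )
    for i, sid in enumerate(sids):
        if not listed_done[i]:
            continue
        lid = f"L{i + 1:04d}"
        participants.append(
            _make_participant(
                lid, "listed", sid, surv["sex"][i], listed_pop["race"][i], listed_age[i],
                listed_pop["education"][i], listed_pop["employment"][i],
                _smoking_fields(listed_pop["smoking"], i, listed_age[i]),
                [listed_pop[v][i] for v in _ALC_VARS],
            )
        )

    _apply_missingness(rng, participants, cfg.missing_rate)
    return CohortTable.from_participants(participants)


def generate_shifted_cohort(
    config: GeneratorConfig | None = None, shift: float = 0.0, seed: int | None = None
) -> CohortTable:
    """Validation-harness cohort: identical pair fidelity for both arms, plus
    an optional location shift on the designated variable for the listed arm.

    With ``shift=0`` this is the exchangeability null of the match-quality
    test (and is what :func:`generate_null_cohort` returns). The shift is in
    the designated variable's units; listed pair distances become
    stochastically larger while peers are untouched. The listed age window is
    deliberately not enforced here — the harness trades the hard constraint
    for exact exchangeability and an unbounded shift ladder.
    """
    if shift < 0:
        raise ConfigError("shift must be non-negative")
    cfg = config or GeneratorConfig()
    if cfg.shift_variable not in set(DEFAULT_NULL_NOISE_SD):
        raise ConfigError(
            f"shift_variable {cfg.shift_variable!r} must be continuous with a "
            f"configured null noise SD"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_survivors
    surv = _draw_population(rng, n, cfg.marginals)
    _, _, peer_done, listed_done = _presence(rng, cfg)

    participants: list[Participant] = []
    sids = [f"S{i + 1:04d}" for i in range(n)]
    for i, sid in enumerate(sids):
        participants.append(
            _make_participant(
                sid, "survivor", sid, surv["sex"][i], surv["race"][i], surv["age"][i],
                surv["education"][i], surv["employment"][i],
                _smoking_fields(surv["smoking"], i, surv["age"][i]),
                [surv[v][i] for v in _ALC_VARS],
            )
        )

    def comparison_arrays(arm_shift: float) -> dict:
        """Draw one comparison subject per survivor from the shared null law."""
        out = {}
        d_age = rng.normal(0.0, cfg.null_noise_sd["age"], n)
        age_shift = arm_shift if cfg.shift_variable == "age" else 0.0
        age = np.maximum(surv["age"] + d_age + age_shift, 18.0)
        out["age"] = age
        out["sex"] = surv["sex"].copy()
        for var in ("race", "education", "employment"):
            fresh = _categorical(rng, n, cfg.marginals[var])
            keep = rng.random(n) < cfg.null_copy_prob[var]
            out[var] = np.where(keep, surv[var], fresh).astype(object)
        out["smoking"] = _perturb_smoking(
            rng, surv["smoking"], age, cfg.null_copy_prob["smoking_status"],
            cfg.marginals["smoking"], cfg.null_noise_sd["days_smoked_30"],
        )
        for v in _ALC_VARS:
            delta = arm_shift if cfg.shift_variable == v else 0.0
            out[v] = np.maximum(0.0, surv[v] + rng.normal(0.0, cfg.null_noise_sd[v], n) + delta)
        return out

    for slot in range(2):
        peer = comparison_arrays(0.0)
        for i, sid in enumerate(sids):
            if not peer_done[i, slot]:
                continue
            pid = f"P{i + 1:04d}-{slot + 1}"
            participants.append(
                _make_participant(
                    pid, "peer", sid, peer["sex"][i], peer["race"][i], peer["age"][i],
                    peer["education"][i], peer["employment"][i],
                    _smoking_fields(peer["smoking"], i, peer["age"][i]),
                    [peer[v][i] for v in _ALC_VARS],
                )
            )

    listed = comparison_arrays(float(shift))
    for i, sid in enumerate(sids):
        if not listed_done[i]:
            continue
        lid = f"L{i + 1:04d}"
        participants.append(
            _make_participant(
                lid, "listed", sid, listed["sex"][i], listed["race"][i], listed["age"][i],
                listed["education"][i], listed["employment"][i],
                _smoking_fields(listed["smoking"], i, listed["age"][i]),
                [listed[v][i] for v in _ALC_VARS],
            )
        )

    _apply_missingness(rng, participants, cfg.missing_rate)
    return CohortTable.from_participants(participants)


def generate_null_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> CohortTable:
    """Exchangeability-null cohort: both arms share the pair-distance law."""
    return generate_shifted_cohort(config, shift=0.0, seed=seed)


def generate_recruitment_ledger(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> dict[str, RecruitmentLedger]:
    """One stochastic recruitment funnel per arm, internally consistent.

    Candidate counts for the peer arm come from the nomination model; the
    other arms start from configured candidate pools. Usable numbers are
    binomial; completions binomial among usable; the remaining usable numbers
    are allocated multinomially across the configured outcome stages, with any
    residual probability mass falling into ``not_used``. Stage counts plus
    completions always sum exactly to the candidates entering.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ledgers: dict[str, RecruitmentLedger] = {}
    for arm in ("survivor", "peer", "listed"):
        spec = cfg.funnel[arm]
        if arm == "peer":
            nominators = rng.binomial(cfg.n_survivors, cfg.peer_nomination_prob)
            two = rng.binomial(nominators, cfg.two_peer_prob)
            n_candidates = int(nominators + two)
        else:
            n_candidates = int(spec["n_candidates"])
        n_usable = int(rng.binomial(n_candidates, spec["p_usable"]))
        n_completed = int(rng.binomial(n_usable, spec["p_complete"]))
        remaining = n_usable - n_completed
        names = list(spec["stage_probs"])
        probs = np.asarray([spec["stage_probs"][s] for s in names], dtype=float)
        resid = max(0.0, 1.0 - probs.sum())
        alloc = rng.multinomial(remaining, np.append(probs, resid) / (probs.sum() + resid))
        stage_counts = {s: int(c) for s, c in zip(names, alloc[:-1])}
        stage_counts["not_used"] = int(alloc[-1]) + (n_candidates - n_usable)
        ledgers[arm] = RecruitmentLedger(
            arm=arm,
            n_candidates=n_candidates,
            n_usable_numbers=n_usable,
            n_completed=n_completed,
            completes_per_hour=float(spec["completes_per_hour"]),
            hourly_rate=25.0,
            stage_counts=stage_counts,
        )
    return ledgers


# ---------------------------------------------------------------------------
# Simulation harnesses


@dataclass
class SimulationSummary:
    """Replicate p-values and the rejection rate of a simulation study."""

    alpha: float
    n_replicates: int
    p_values: np.ndarray
    rejection_rate: float
    ci_low: float
    ci_high: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_replicates": self.n_replicates,
            "rejection_rate": self.rejection_rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_values": np.asarray(self.p_values).tolist(),
            **self.extras,
        }


def binomial_acceptance_interval(n: int, p0: float, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial central interval for the observed proportion under p0."""
    from scipy.stats import binom

    lo = (1 - conf) / 2
    return (binom.ppf(lo, n, p0) / n, binom.ppf(1 - lo, n, p0) / n)


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=(n, 2))


def _quality_pvalue(cohort, variable: str, n_permutations: int, seed: int,
                    peer_rule: str = "first") -> float:
    spec = VariableSpec(variable, "continuous")
    dists = compute_pair_distances(cohort, spec, peer_rule)
    res = permutation_test_partially_paired(
        dists, n_permutations=n_permutations, seed=seed, method="monte_carlo"
    )
    return res.p_one_sided


def type_one_error_simulation(
    config: GeneratorConfig | None = None,
    variable: str | None = None,
    n_replicates: int = 1000,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    peer_rule: str = "first",
) -> SimulationSummary:
    """Empirical size of the one-sided match-quality test under the null.

    Each replicate draws a fresh exchangeability-null cohort and runs the
    Monte Carlo permutation test on the designated variable; the rejection
    rate at ``alpha`` estimates the test's type-I error.
    """
    cfg = config or GeneratorConfig()
    var = variable or cfg.shift_variable
    seeds = _replicate_seeds(seed, n_replicates)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = generate_null_cohort(cfg, seed=int(seeds[r, 0]))
        pvals[r] = _quality_pvalue(cohort, var, n_permutations, int(seeds[r, 1]), peer_rule)
    rate = float(np.mean(pvals <= alpha))
    lo, hi = binomial_acceptance_interval(n_replicates, alpha)
    return SimulationSummary(
        alpha=alpha,
        n_replicates=n_replicates,
        p_values=pvals,
        rejection_rate=rate,
        ci_low=float(lo),
        ci_high=float(hi),
        extras={"variable": var, "n_permutations": n_permutations, "design": "null"},
    )


def power_simulation(
    config: GeneratorConfig | None = None,
    shifts: tuple = (0.0, 0.5, 1.0, 2.0),
    variable: str | None = None,
    n_replicates: int = 500,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    peer_rule: str = "first",
) -> dict[float, SimulationSummary]:
    """Empirical power across a shift ladder, in units of the pair-noise SD.

    Shift ``s`` displaces the listed arm's designated variable by
    ``s * null_noise_sd[variable]``; power should be non-decreasing in ``s``.
    """
    cfg = config or GeneratorConfig()
    var = variable or cfg.shift_variable
    sd = cfg.null_noise_sd[var]
    out: dict[float, SimulationSummary] = {}
    for s in shifts:
        seeds = _replicate_seeds(seed + int(round(1000 * s)), n_replicates)
        pvals = np.empty(n_replicates)
        for r in range(n_replicates):
            cohort = generate_shifted_cohort(cfg, shift=s * sd, seed=int(seeds[r, 0]))
            pvals[r] = _quality_pvalue(cohort, var, n_permutations, int(seeds[r, 1]), peer_rule)
        rate = float(np.mean(pvals <= alpha))
        lo, hi = binomial_acceptance_interval(n_replicates, alpha)
        out[float(s)] = SimulationSummary(
            alpha=alpha,
            n_replicates=n_replicates,
            p_values=pvals,
            rejection_rate=rate,
            ci_low=float(lo),
            ci_high=float(hi),
            extras={
                "variable": var,
                "shift_sd_units": float(s),
                "shift_value": float(s * sd),
                "n_permutations": n_permutations,
                "design": "shifted",
            },
        )
    return out
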