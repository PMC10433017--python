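"""Synthetic cohorts of ranked differential-diagnosis lists.

No patient-level data from studies of commercial DDx generators is
publicly available, so analyses here run on synthetic cohorts that
reproduce the *statistical structure* such a study exhibits:

* several generators with different marginal top-10 hit rates;
* positively correlated hits across generators, induced by a latent
  per-case difficulty (a random intercept shared by all generators);
* partial overlap between the candidate lists of different generators,
  controlled by a shared per-case candidate pool;
* a common/uncommon disease stratification in which uncommon diseases are
  harder for every generator;
* two physician replicates per case: the index generator (an automated
  history-taking system) produces one list per patient, cloned across
  replicates, while the other generators' lists vary by replicate.

The hit model: generator g hits the truth on a case with probability
``expit(skill_g - difficulty)`` where ``difficulty ~ N(shift·1[uncommon],
sd²)`` is drawn once per case.  When a generator hits, the truth's rank is
truncated-geometric on 1..10; all remaining slots are distractors drawn
without replacement from a case-level pool shared across generators (with
probability ``pool_overlap_weight``) or from a generator-private pool.
Shared, private pools and the truth are mutually disjoint, so
``pool_overlap_weight = 0`` yields disjoint distractor supports.

`calibrate_skill` inverts the marginal hit rate analytically (Gauss–Hermite
quadrature over the difficulty mixture), so a cohort can be pinned to
target marginals such as the 46%/41%/27% observed for three real systems.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .combine import MAX_LIST_LENGTH, RankedDDxList

__all__ = [
    "INDEX_GENERATOR",
    "STUDY_HIT_RATES",
    "ConfigurationError",
    "CohortValidationError",
    "Diagnosis",
    "SimulationConfig",
    "CaseRecord",
    "generate_cohort",
    "marginal_hit_rate",
    "calibrate_skill",
    "study_config",
    "write_cohort",
    "read_cohort",
]

#: Generator id of the automated history-taking system anchoring the study.
INDEX_GENERATOR = "index"

#: Marginal top-10 hit rates of the three systems in the motivating study
#: (index system, Isabel-like second system, third system).
STUDY_HIT_RATES: Mapping[str, float] = {
    INDEX_GENERATOR: 0.46,
    "second": 0.41,
    "third": 0.27,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its constraints."""


class CohortValidationError(ValueError):
    """Raised when a cohort file fails schema validation."""


@dataclass(frozen=True)
class Diagnosis:
    """A diagnosis; equality is identity of the opaque id token."""

    id: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("diagnosis id must be non-empty")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    ``generator_skills`` maps generator id to a log-odds offset of hitting
    the truth; it must contain :data:`INDEX_GENERATOR` and its iteration
    order fixes generator priority in downstream combinations.
    """

    n_cases: int = 103
    n_replicates: int = 2
    generator_skills: Mapping[str, float] = field(
        default_factory=lambda: {INDEX_GENERATOR: 0.0, "second": -0.2, "third": -0.8}
    )
    difficulty_sd: float = 1.0
    stratum_fraction_common: float = 64 / 103
    stratum_difficulty_shift: float = 1.6
    truth_rank_geometric_p: float = 0.35
    pool_size_case: int = 15
    pool_overlap_weight: float = 0.55
    replicate_resample_prob: float = 0.3
    vocabulary_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "generator_skills", dict(self.generator_skills))
        self.validate()

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if INDEX_GENERATOR not in self.generator_skills:
            raise ConfigurationError(
                f"generator_skills must include the {INDEX_GENERATOR!r} generator"
            )
        if self.difficulty_sd < 0:
            raise ConfigurationError("difficulty_sd must be non-negative")
        for name in (
            "stratum_fraction_common",
            "pool_overlap_weight",
            "replicate_resample_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.truth_rank_geometric_p <= 1.0:
            raise ConfigurationError("truth_rank_geometric_p must lie in (0, 1]")
        if self.pool_size_case < MAX_LIST_LENGTH:
            raise ConfigurationError(
                f"pool_size_case must be >= {MAX_LIST_LENGTH} so a full list "
                "can be drawn from one pool"
            )
        # 1 truth + one shared pool + one private pool per generator, all disjoint
        needed = 1 + self.pool_size_case * (1 + len(self.generator_skills))
        if self.vocabulary_size < needed:
            raise ConfigurationError(
                f"vocabulary_size={self.vocabulary_size} is too small to fill "
                f"{MAX_LIST_LENGTH} unique slots per list from disjoint pools: "
                f"need >= 1 + pool_size_case * (1 + n_generators) = {needed}"
            )

    @property
    def generators(self) -> tuple[str, ...]:
        return tuple(self.generator_skills)

    @property
    def other_generators(self) -> tuple[str, ...]:
        return tuple(g for g in self.generator_skills if g != INDEX_GENERATOR)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        return cls(**dict(data))


@dataclass(frozen=True)
class CaseRecord:
    """One patient case under one physician replicate.

    Holds the confirmed truth diagnosis, the common/uncommon stratum and
    one ranked list per generator.  The index list is identical across
    replicates of a case (the automated system interviews each patient
    once); only the other generators' lists vary by replicate.
    """

    case_id: str
    replicate_id: str
    truth: str
    stratum: str
    lists: Mapping[str, RankedDDxList]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lists", dict(self.lists))
        if self.stratum not in ("common", "uncommon"):
            raise ValueError(f"stratum must be 'common' or 'uncommon', got {self.stratum!r}")
        if not self.truth:
            raise ValueError("truth diagnosis id must be non-empty")
        if INDEX_GENERATOR not in self.lists:
            raise ValueError(
                f"case {self.case_id!r} replicate {self.replicate_id!r} has no "
                f"{INDEX_GENERATOR!r} list"
            )

    @property
    def index_list(self) -> RankedDDxList:
        return self.lists[INDEX_GENERATOR]

    @property
    def other_lists(self) -> tuple[RankedDDxList, ...]:
        return tuple(v for k, v in self.lists.items() if k != INDEX_GENERATOR)


# ---------------------------------------------------------------------------
# marginal hit-rate calibration


def _difficulty_mixture(config_like) -> tuple[tuple[float, float], tuple[float, float]]:
    """(mean, weight) of the two difficulty components (common, uncommon)."""
    f = config_like.stratum_fraction_common
    return (0.0, f), (config_like.stratum_difficulty_shift, 1.0 - f)


def marginal_hit_rate(
    skill: float,
    difficulty_sd: float,
    stratum_fraction_common: float = 1.0,
    stratum_difficulty_shift: float = 0.0,
    n_quad: int = 80,
) -> float:
    """Analytic marginal P(hit) = E[expit(skill - difficulty)].

    Difficulty is a two-component normal mixture: N(0, sd²) with weight
    ``stratum_fraction_common`` and N(shift, sd²) otherwise.  Evaluated by
    Gauss–Hermite quadrature; exact (up to quadrature error) for sd > 0 and
    trivially exact for sd = 0.
    """
    means_weights = (
        (0.0, stratum_fraction_common),
        (stratum_difficulty_shift, 1.0 - stratum_fraction_common),
    )
    if difficulty_sd == 0.0:
        return float(
            sum(w * expit(skill - m) for m, w in means_weights)
        )
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    total = 0.0
    for m, w in means_weights:
        if w == 0.0:
            continue
        x = m + np.sqrt(2.0) * difficulty_sd * nodes
        total += w * float(np.sum(weights * expit(skill - x)) / np.sqrt(np.pi))
    return total


def calibrate_skill(
    target_rate: float,
    difficulty_sd: float,
    stratum_fraction_common: float = 1.0,
    stratum_difficulty_shift: float = 0.0,
) -> float:
    """Skill (log-odds offset) whose analytic marginal hit rate equals target."""
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly in (0, 1)")

    def gap(s: float) -> float:
        return (
            marginal_hit_rate(
                s, difficulty_sd, stratum_fraction_common, stratum_difficulty_shift
            )
            - target_rate
        )

    lo, hi = -30.0, 30.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def study_config(
    seed: int = 0,
    n_cases: int = 103,
    hit_rates: Mapping[str, float] | None = None,
    **overrides,
) -> SimulationConfig:
    """A configuration emulating the motivating study's structure.

    103 patients, 2 physician replicates, three generators with marginal
    top-10 hit rates calibrated to 46% / 41% / 27%, a 64/39 common/uncommon
    split with uncommon diseases harder for every generator, and candidate
    pools tuned so the pairwise shared-diagnosis count has median about 2
    and the three-way count median about 1.
    """
    hit_rates = dict(STUDY_HIT_RATES if hit_rates is None else hit_rates)
    base = SimulationConfig(seed=seed, n_cases=n_cases)
    sd = overrides.get("difficulty_sd", base.difficulty_sd)
    f_common = overrides.get("stratum_fraction_common", base.stratum_fraction_common)
    shift = overrides.get("stratum_difficulty_shift", base.stratum_difficulty_shift)
    skills = {
        g: calibrate_skill(rate, sd, f_common, shift) for g, rate in hit_rates.items()
    }
    return dataclasses.replace(
        base,
        seed=seed,
        n_cases=n_cases,
        generator_skills=skills,
        **overrides,
    )


# ---------------------------------------------------------------------------
# generation


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # per-case substream keyed by a counter: cohorts are prefix-stable
    # under changes of n_cases
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(case_index,)))


def _truncated_geometric_rank(
    rng: np.random.Generator, p: float, n: int = MAX_LIST_LENGTH
) -> int:
    """Rank in 1..n with P(r) ∝ (1-p)^(r-1); degenerate at 1 when p = 1."""
    if p >= 1.0:
        return 1
    q = 1.0 - p
    pmf = p * q ** np.arange(n)
    pmf /= pmf.sum()
    return int(rng.choice(n, p=pmf)) + 1


def _draw_distractors(
    rng: np.random.Generator,
    n_slots: int,
    shared_pool: Sequence[str],
    private_pool: Sequence[str],
    overlap_weight: float,
    forbidden: set[str],
) -> list[str]:
    """Fill ``n_slots`` distractor slots, per-slot coin choosing the pool."""
    chosen: list[str] = []
    used = set(forbidden)
    for _ in range(n_slots):
        use_shared = rng.random() < overlap_weight
        pools = (shared_pool, private_pool) if use_shared else (private_pool, shared_pool)
        picked = None
        for pool in pools:
            avail = [d for d in pool if d not in used]
            if avail:
                picked = avail[int(rng.integers(len(avail)))]
                break
        if picked is None:  # both pools exhausted; cannot occur with valid config
            raise ConfigurationError(
                "candidate pools exhausted while filling distractor slots"
            )
        chosen.append(picked)
        used.add(picked)
    return chosen


def _build_list(
    rng: np.random.Generator,
    generator_id: str,
    truth: str,
    hit: bool,
    truth_rank: int,
    shared_pool: Sequence[str],
    private_pool: Sequence[str],
    config: SimulationConfig,
) -> RankedDDxList:
    n_distract = MAX_LIST_LENGTH - (1 if hit else 0)
    distractors = _draw_distractors(
        rng,
        n_distract,
        shared_pool,
        private_pool,
        config.pool_overlap_weight,
        forbidden={truth},
    )
    if hit:
        entries = distractors[: truth_rank - 1] + [truth] + distractors[truth_rank - 1 :]
    else:
        entries = distractors
    return RankedDDxList(generator_id, tuple(entries))


def _resample_list(
    rng: np.random.Generator,
    base: RankedDDxList,
    truth: str,
    shared_pool: Sequence[str],
    private_pool: Sequence[str],
    config: SimulationConfig,
) -> RankedDDxList:
    """Replicate-2+ variant of a list: redraw distractor slots independently.

    A second physician enters the history with different keywords, so a
    generator's list varies between replicates; the hit status and the
    truth's rank are properties of the (case, generator) pair and are kept.
    """
    entries = list(base.entries)
    current = set(entries)
    for i, d in enumerate(entries):
        if d == truth:
            continue
        if rng.random() >= config.replicate_resample_prob:
            continue
        use_shared = rng.random() < config.pool_overlap_weight
        pools = (shared_pool, private_pool) if use_shared else (private_pool, shared_pool)
        replacement = None
        for pool in pools:
            avail = [x for x in pool if x not in current and x != truth]
            if avail:
                replacement = avail[int(rng.integers(len(avail)))]
                break
        if replacement is None:
            continue  # pools exhausted for this slot; keep the original
        current.discard(d)
        current.add(replacement)
        entries[i] = replacement
    return RankedDDxList(base.generator_id, tuple(entries))


def generate_cohort(config: SimulationConfig) -> list[CaseRecord]:
    """Generate ``n_cases × n_replicates`` case records.

    Identical config and seed give a bit-identical cohort.  Every list has
    exactly 10 unique diagnosis ids; the truth appears in a list iff that
    generator hit.  Per-case latent difficulty is shared by all generators
    and replicates, inducing positive hit correlation.
    """
    config.validate()
    vocab = [f"dx{i:05d}" for i in range(config.vocabulary_size)]
    records: list[CaseRecord] = []
    for ci in range(config.n_cases):
        rng = _case_rng(config.seed, ci)
        case_id = f"case{ci:05d}"
        stratum = "common" if rng.random() < config.stratum_fraction_common else "uncommon"
        difficulty = rng.normal(0.0, config.difficulty_sd) if config.difficulty_sd > 0 else 0.0
        if stratum == "uncommon":
            difficulty += config.stratum_difficulty_shift
        truth = vocab[int(rng.integers(config.vocabulary_size))]
        # disjoint pools: shared case pool, then one private pool per generator
        candidates = [d for d in vocab if d != truth]
        perm = rng.permutation(len(candidates))
        p = config.pool_size_case
        shared_pool = [candidates[j] for j in perm[:p]]
        private_pools: dict[str, list[str]] = {}
        offset = p
        for g in config.generators:
            private_pools[g] = [candidates[j] for j in perm[offset : offset + p]]
            offset += p

        per_generator: dict[str, list[RankedDDxList]] = {}
        for g, skill in config.generator_skills.items():
            hit = bool(rng.random() < expit(skill - difficulty))
            truth_rank = (
                _truncated_geometric_rank(rng, config.truth_rank_geometric_p)
                if hit
                else 0
            )
            first = _build_list(
                rng, g, truth, hit, truth_rank, shared_pool, private_pools[g], config
            )
            lists = [first]
            for _ in range(1, config.n_replicates):
                if g == INDEX_GENERATOR:
                    lists.append(first)  # one automated interview per patient
                else:
                    lists.append(
                        _resample_list(
                            rng, first, truth, shared_pool, private_pools[g], config
                        )
                    )
            per_generator[g] = lists

        for r in range(config.n_replicates):
            records.append(
                CaseRecord(
                    case_id=case_id,
                    replicate_id=f"rep{r + 1}",
                    truth=truth,
                    stratum=stratum,
                    lists={g: per_generator[g][r] for g in config.generators},
                )
            )
    return records


# ---------------------------------------------------------------------------
# interchange format


def _cohort_frames(cohort: Sequence[CaseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    case_rows = []
    list_rows = []
    for rec in cohort:
        case_rows.append(
            {
                "case_id": rec.case_id,
                "replicate_id": rec.replicate_id,
                "truth_id": rec.truth,
                "stratum": rec.stratum,
            }
        )
        for g, lst in rec.lists.items():
            for rank, d in enumerate(lst.entries, start=1):
                list_rows.append(
                    {
                        "case_id": rec.case_id,
                        "replicate_id": rec.replicate_id,
                        "generator_id": g,
                        "rank": rank,
                        "diagnosis_id": d,
                    }
                )
    return pd.DataFrame(case_rows), pd.DataFrame(list_rows)


def write_cohort(
    cohort: Sequence[CaseRecord], path: str | Path, format: str = "csv"
) -> None:
    """Write a cohort to ``path``.

    ``csv``: ``path`` is a directory receiving ``cases.csv`` (case table)
    and ``lists.csv`` (long-form ranked lists).  ``json``: ``path`` is a
    single file with one object per case record.
    """
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        cases, lists = _cohort_frames(cohort)
        cases.to_csv(path / "cases.csv", index=False)
        lists.to_csv(path / "lists.csv", index=False)
    elif format == "json":
        payload = [
            {
                "case_id": rec.case_id,
                "replicate_id": rec.replicate_id,
                "truth": rec.truth,
                "stratum": rec.stratum,
                "lists": {g: list(lst.entries) for g, lst in rec.lists.items()},
            }
            for rec in cohort
        ]
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown cohort format {format!r}")


def _build_records(
    case_table: pd.DataFrame, lists_by_key: dict[tuple[str, str], dict[str, list[str]]]
) -> list[CaseRecord]:
    records = []
    for _, row in case_table.iterrows():
        key = (str(row["case_id"]), str(row["replicate_id"]))
        gen_lists = lists_by_key.get(key, {})
        if not gen_lists:
            raise CohortValidationError(
                f"case {key[0]!r} replicate {key[1]!r} has no ranked lists"
            )
        records.append(
            CaseRecord(
                case_id=key[0],
                replicate_id=key[1],
                truth=str(row["truth_id"]),
                stratum=str(row["stratum"]),
                lists={
                    g: RankedDDxList(g, tuple(entries))
                    for g, entries in gen_lists.items()
                },
            )
        )
    return records


def read_cohort(path: str | Path, format: str = "csv") -> list[CaseRecord]:
    """Read and validate a cohort written by :func:`write_cohort`.

    Malformed rows are rejected with row-numbered messages.  Lists must
    have exactly 10 rows with ranks 1..10 and unique diagnoses — shorter
    lists indicate an incompletely conducted interview and are excluded
    from this study design.
    """
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = []
        for i, obj in enumerate(payload):
            try:
                lists = {}
                for g, entries in obj["lists"].items():
                    if len(entries) != MAX_LIST_LENGTH:
                        raise CohortValidationError(
                            f"generator {g!r} list has {len(entries)} entries; "
                            f"exactly {MAX_LIST_LENGTH} required"
                        )
                    lists[g] = RankedDDxList(g, tuple(entries))
                records.append(
                    CaseRecord(
                        case_id=obj["case_id"],
                        replicate_id=obj["replicate_id"],
                        truth=obj["truth"],
                        stratum=obj["stratum"],
                        lists=lists,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise CohortValidationError(f"record {i}: {exc}") from exc
        return records
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")

    cases = pd.read_csv(path / "cases.csv", dtype=str)
    lists = pd.read_csv(
        path / "lists.csv",
        dtype={
            "case_id": str,
            "replicate_id": str,
            "generator_id": str,
            "diagnosis_id": str,
        },
    )
    required = {"case_id", "replicate_id", "generator_id", "rank", "diagnosis_id"}
    if missing := required - set(lists.columns):
        raise CohortValidationError(f"lists.csv missing columns: {sorted(missing)}")
    if missing := {"case_id", "replicate_id", "truth_id", "stratum"} - set(cases.columns):
        raise CohortValidationError(f"cases.csv missing columns: {sorted(missing)}")

    errors: list[str] = []
    seen_keys: set[tuple] = set()
    lists_by_key: dict[tuple[str, str], dict[str, dict[int, str]]] = {}
    for i, row in enumerate(lists.itertuples(index=False), start=2):  # 1 = header
        try:
            rank = int(row.rank)
        except (TypeError, ValueError):
            errors.append(f"lists.csv row {i}: rank {row.rank!r} is not an integer")
            continue
        if not 1 <= rank <= MAX_LIST_LENGTH:
            errors.append(
                f"lists.csv row {i}: rank {rank} outside 1..{MAX_LIST_LENGTH}"
            )
            continue
        key = (row.case_id, row.replicate_id, row.generator_id, rank)
        if key in seen_keys:
            errors.append(
                f"lists.csv row {i}: duplicate (case, replicate, generator, rank) key {key}"
            )
            continue
        seen_keys.add(key)
        slot = lists_by_key.setdefault((row.case_id, row.replicate_id), {}).setdefault(
            row.generator_id, {}
        )
        if row.diagnosis_id in slot.values():
            errors.append(
                f"lists.csv row {i}: duplicate diagnosis {row.diagnosis_id!r} within "
                f"list ({row.case_id}, {row.replicate_id}, {row.generator_id})"
            )
            continue
        slot[rank] = row.diagnosis_id
    for (case_id, rep_id), gens in lists_by_key.items():
        for g, by_rank in gens.items():
            if len(by_rank) != MAX_LIST_LENGTH:
                errors.append(
                    f"list ({case_id}, {rep_id}, {g}) has {len(by_rank)} entries; "
                    f"exactly {MAX_LIST_LENGTH} required (ranks 1..{MAX_LIST_LENGTH})"
                )
    if errors:
        raise CohortValidationError("; ".join(errors))

    ordered = {
        key: {g: [by_rank[r] for r in range(1, MAX_LIST_LENGTH + 1)] for g, by_rank in gens.items()}
        for key, gens in lists_by_key.items()
    }
    return _build_records(cases, ordered)
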