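"""CPT-AX task structure and synthetic two-group cohort generation.

The cued continuous performance task (CPT-AX) presents a continuous
stream of shapes: a designated cue (A), a designated target (X) and 11
distractors.  Only a target immediately preceded by the cue is a "go"
event requiring a speeded button press; every other trial is "no-go".
A session is 4 blocks of 100 trials with, per block, 10 go (A-X) pairs,
10 cue-without-target trials and 10 uncued-target trials; stimuli show
for 250 ms with a 1,400 ms interstimulus interval, giving a 1,650 ms
onset-to-onset response deadline.

The synthetic cohort emulates a very-preterm (VP) and a term-born group
of school-age children whose go-trial behaviour is generated by a
diffusion process: each child carries latent drift rate, boundary
separation and nondecision time, with drift negatively coupled to the
child's parent-rated inattention (SWAN score).  No-go responses come
from a small per-trial Bernoulli commission process.  Latent fields are
synthetic provenance only — analysis stages never read them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .ddm import DDMParameters, DiffusionSample, simulate_diffusion_trials

__all__ = [
    "STIMULUS_DURATION_MS",
    "ISI_MS",
    "DEADLINE_MS",
    "N_BLOCKS",
    "TRIALS_PER_BLOCK",
    "GO_PER_BLOCK",
    "CUE_ONLY_PER_BLOCK",
    "UNCUED_TARGET_PER_BLOCK",
    "N_DISTRACTORS",
    "TrialRecord",
    "Session",
    "ChildRecord",
    "GroupConfig",
    "CohortConfig",
    "ConfigurationError",
    "generate_trial_sequence",
    "generate_cohort",
    "simulate_child_session",
]

STIMULUS_DURATION_MS = 250
ISI_MS = 1400
#: Response deadline: onset-to-onset interval (stimulus + ISI).
DEADLINE_MS = STIMULUS_DURATION_MS + ISI_MS

N_BLOCKS = 4
TRIALS_PER_BLOCK = 100
GO_PER_BLOCK = 10
CUE_ONLY_PER_BLOCK = 10
UNCUED_TARGET_PER_BLOCK = 10
N_DISTRACTORS = 11

#: Minimum number of trials between the end of one go pair and the cue
#: of the next.
MIN_TRIALS_BETWEEN_GO_PAIRS = 2

#: Commission (false-alarm) RTs are drawn uniformly on this window (ms).
COMMISSION_RT_RANGE_MS = (300.0, 1650.0)


class ConfigurationError(ValueError):
    """Invalid cohort configuration (negative SD, zero group size, ...)."""


@dataclass
class TrialRecord:
    """One stimulus event of a CPT-AX session.

    ``trial_type`` classifies the event for scoring: ``go`` is a target
    immediately preceded by the cue (response required); ``cue_only`` a
    cue not followed by the target; ``uncued_target`` a target not
    preceded by the cue; ``filler`` everything else (distractors and the
    cue that opens a go pair).  ``rt_ms`` is present iff ``responded``.
    """

    block_index: int
    trial_index: int
    stimulus_role: str
    trial_type: str
    responded: bool = False
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.responded != (self.rt_ms is not None):
            raise ValueError("rt_ms must be present iff responded is true")
        if self.rt_ms is not None and not self.rt_ms > 0:
            raise ValueError(f"rt_ms must be positive, got {self.rt_ms}")


@dataclass
class Session:
    """An ordered 400-trial CPT-AX session with its timing constants."""

    trials: list[TrialRecord]
    stimulus_duration_ms: int = STIMULUS_DURATION_MS
    isi_ms: int = ISI_MS
    deadline_ms: int = DEADLINE_MS
    seed: int | None = None

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        if len(self.trials) != N_BLOCKS * TRIALS_PER_BLOCK:
            raise ValueError(f"expected 400 trials, got {len(self.trials)}")
        if self.deadline_ms != self.stimulus_duration_ms + self.isi_ms:
            raise ValueError("deadline must equal stimulus duration + ISI")
        for b in range(1, N_BLOCKS + 1):
            block = [t for t in self.trials if t.block_index == b]
            if len(block) != TRIALS_PER_BLOCK:
                raise ValueError(f"block {b} has {len(block)} trials")
            counts = {"go": 0, "cue_only": 0, "uncued_target": 0}
            for t in block:
                if t.trial_type in counts:
                    counts[t.trial_type] += 1
            if counts["go"] != GO_PER_BLOCK:
                raise ValueError(f"block {b}: {counts['go']} go trials")
            if counts["cue_only"] != CUE_ONLY_PER_BLOCK:
                raise ValueError(f"block {b}: {counts['cue_only']} cue_only trials")
            if counts["uncued_target"] != UNCUED_TARGET_PER_BLOCK:
                raise ValueError(
                    f"block {b}: {counts['uncued_target']} uncued_target trials"
                )
        for i, t in enumerate(self.trials):
            if t.trial_type == "go":
                if t.stimulus_role != "target":
                    raise ValueError(f"trial {i}: go trial is not a target")
                if i == 0 or self.trials[i - 1].stimulus_role != "cue":
                    raise ValueError(f"trial {i}: go trial not preceded by cue")
            elif t.stimulus_role == "target" and i > 0:
                if self.trials[i - 1].stimulus_role == "cue":
                    raise ValueError(f"trial {i}: undesignated cue-target pair")

    def go_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.trials) if t.trial_type == "go"]

    def to_frame(self, child_id: str | None = None) -> pd.DataFrame:
        """Trial-level table (one row per trial, CSV-ready)."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "block_index": t.block_index,
                    "trial_index": t.trial_index,
                    "stimulus_role": t.stimulus_role,
                    "trial_type": t.trial_type,
                    "responded": int(t.responded),
                    "rt_ms": t.rt_ms if t.responded else None,
                }
            )
        frame = pd.DataFrame(rows)
        if child_id is not None:
            frame.insert(0, "child_id", child_id)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "Session":
        """Rebuild a session from its trial-level table."""
        trials = []
        for row in frame.itertuples(index=False):
            responded = bool(int(row.responded))
            rt = float(row.rt_ms) if responded else None
            trials.append(
                TrialRecord(
                    block_index=int(row.block_index),
                    trial_index=int(row.trial_index),
                    stimulus_role=str(row.stimulus_role),
                    trial_type=str(row.trial_type),
                    responded=responded,
                    rt_ms=rt,
                )
            )
        return cls(trials=trials, seed=seed)


@dataclass
class ChildRecord:
    """One child of the cohort.

    The ``true_*`` and ``commission_rate`` fields are latent generator
    state (synthetic provenance): they drive the behavioural simulation
    and are exposed only for validation; analysis stages consume the
    fitted parameters instead.
    """

    child_id: str
    group: str  # "VP" or "term"
    age_years: float
    sex: str  # "F" or "M"
    swan_inattention: float | None
    true_v: float | None = None
    true_a: float | None = None
    true_ter: float | None = None
    commission_rate: float | None = None

    def __post_init__(self) -> None:
        if self.true_a is not None and not self.true_a > 0:
            raise ValueError("true_a must be positive")
        if self.true_ter is not None and self.true_ter < 0:
            raise ValueError("true_ter must be nonnegative")
        if self.commission_rate is not None and not 0 <= self.commission_rate <= 1:
            raise ValueError("commission_rate must lie in [0, 1]")

    def latent_parameters(self, s: float = 0.1) -> DDMParameters:
        if None in (self.true_v, self.true_a, self.true_ter):
            raise ValueError(f"child {self.child_id} has no latent parameters")
        return DDMParameters(v=self.true_v, a=self.true_a, ter=self.true_ter, s=s)


@dataclass
class GroupConfig:
    """Generator distributions for one group."""

    n: int
    age_mean: float
    age_sd: float
    swan_mean: float
    swan_sd: float
    v_mean: float
    v_sd: float
    a_mean: float
    a_sd: float
    ter_mean: float
    ter_sd: float
    prop_female: float

    def validate(self, name: str) -> None:
        if self.n < 1:
            raise ConfigurationError(f"{name}: group size must be >= 1, got {self.n}")
        for attr in ("age_sd", "swan_sd", "v_sd", "a_sd", "ter_sd"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{name}.{attr} must be >= 0")
        if not 0 <= self.prop_female <= 1:
            raise ConfigurationError(f"{name}.prop_female must lie in [0, 1]")


# Defaults reproduce the study's cohort structure: 33 VP / 32 term
# children aged ~9-10 years, SWAN inattention means of -0.70 (VP) and
# -6.58 (term), and diffusion-parameter means of (v, a, Ter) =
# (.211, .112, .253) vs (.191, .112, .267).  Between-child SDs are
# recovered from the reported standard errors (SE * sqrt(n)).
_VP_DEFAULTS = dict(
    n=33, age_mean=9.6, age_sd=1.0, swan_mean=-0.70, swan_sd=9.89,
    v_mean=0.211, v_sd=0.090, a_mean=0.112, a_sd=0.023,
    ter_mean=0.253, ter_sd=0.075, prop_female=0.455,
)
_TERM_DEFAULTS = dict(
    n=32, age_mean=9.1, age_sd=1.1, swan_mean=-6.58, swan_sd=12.23,
    v_mean=0.191, v_sd=0.090, a_mean=0.112, a_sd=0.023,
    ter_mean=0.267, ter_sd=0.075, prop_female=0.406,
)


@dataclass
class CohortConfig:
    """Full synthetic-cohort configuration.

    ``swan_to_v_slope`` couples inattention to drift: each child's
    latent drift is the group mean plus slope times the within-group
    z-score of their SWAN inattention, plus residual noise.  The default
    slope is calibrated so that the pooled age-partialed correlation
    between SWAN inattention and *fitted* drift rate is about -0.37 on
    40-trial sessions; the residual drift SD is reduced accordingly so
    the marginal drift SD stays at the group value.

    ``commission_alpha``/``commission_beta`` parameterise the Beta
    distribution of per-child false-alarm rates (default mean 2.4%).

    ``n_swan_missing_term`` marks that many term-born children as
    missing their SWAN score (the study lost one), so listwise analyses
    run on N-1 children while the multivariate group comparison keeps
    the full N.
    """

    vp: GroupConfig = field(default_factory=lambda: GroupConfig(**_VP_DEFAULTS))
    term: GroupConfig = field(default_factory=lambda: GroupConfig(**_TERM_DEFAULTS))
    swan_to_v_slope: float = -0.050
    commission_alpha: float = 2.0
    commission_beta: float = 81.3
    ter_floor: float = 0.05
    n_swan_missing_term: int = 1
    seed: int = 0

    def validate(self) -> None:
        self.vp.validate("vp")
        self.term.validate("term")
        if self.commission_alpha <= 0 or self.commission_beta <= 0:
            raise ConfigurationError("commission Beta parameters must be positive")
        if self.n_swan_missing_term < 0 or self.n_swan_missing_term > self.term.n:
            raise ConfigurationError("n_swan_missing_term out of range")
        if self.ter_floor < 0:
            raise ConfigurationError("ter_floor must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        for grp in ("vp", "term"):
            if grp in data and isinstance(data[grp], dict):
                data[grp] = GroupConfig(**data[grp])
        return cls(**data)


# ---------------------------------------------------------------------------
# Trial-sequence generation
# ---------------------------------------------------------------------------

def _place_go_pairs(rng: np.random.Generator) -> np.ndarray:
    """Uniformly draw 10 go-pair start positions in one 100-trial block.

    A pair occupies (p, p+1); consecutive pairs are separated by at
    least MIN_TRIALS_BETWEEN_GO_PAIRS intervening trials, i.e. starts
    differ by >= 4.  The draw uses the gap bijection: choosing 10
    distinct sorted values r from {0..71} and setting p_i = r_i + 3*i
    enumerates exactly the valid configurations, uniformly.
    """
    n = GO_PER_BLOCK
    span = MIN_TRIALS_BETWEEN_GO_PAIRS + 2  # start-to-start spacing
    width = TRIALS_PER_BLOCK - 2 - (span - 1) * (n - 1)
    r = np.sort(rng.choice(width + 1, size=n, replace=False))
    return r + (span - 1) * np.arange(n)


def _build_block(rng: np.random.Generator, block_index: int) -> list[TrialRecord]:
    roles = [None] * TRIALS_PER_BLOCK
    types = [None] * TRIALS_PER_BLOCK

    starts = _place_go_pairs(rng)
    for p in starts:
        roles[p] = "cue"
        types[p] = "filler"
        roles[p + 1] = "target"
        types[p + 1] = "go"

    free = [i for i in range(TRIALS_PER_BLOCK) if roles[i] is None]

    # Uncued targets: anywhere free except position 0 (so no block can
    # start with a target and form an accidental pair across blocks).
    candidates = [i for i in free if i != 0]
    uncued = rng.choice(len(candidates), size=UNCUED_TARGET_PER_BLOCK, replace=False)
    uncued_pos = {candidates[i] for i in uncued}
    for i in uncued_pos:
        roles[i] = "target"
        types[i] = "uncued_target"

    # Cue-only trials: free positions whose successor (within the
    # block) is not a target, so no undesignated cue-target pair forms.
    free = [i for i in free if i not in uncued_pos]
    candidates = [
        i
        for i in free
        if i == TRIALS_PER_BLOCK - 1 or roles[i + 1] != "target"
    ]
    cue_only = rng.choice(len(candidates), size=CUE_ONLY_PER_BLOCK, replace=False)
    cue_only_pos = {candidates[i] for i in cue_only}
    for i in cue_only_pos:
        roles[i] = "cue"
        types[i] = "cue_only"

    for i in range(TRIALS_PER_BLOCK):
        if roles[i] is None:
            roles[i] = f"distractor_{rng.integers(1, N_DISTRACTORS + 1)}"
            types[i] = "filler"

    return [
        TrialRecord(
            block_index=block_index,
            trial_index=i + 1,
            stimulus_role=roles[i],
            trial_type=types[i],
        )
        for i in range(TRIALS_PER_BLOCK)
    ]


def generate_trial_sequence(seed: int) -> Session:
    """Generate a pseudorandomised 400-trial CPT-AX session template.

    Each of the 4 blocks independently receives 10 go pairs (with at
    least two intervening trials between pairs), 10 cue-only and 10
    uncued-target trials; the remaining slots are distractors.  The
    same template is shared by all children of a cohort, mirroring
    identical orders across participants.

    Deterministic for a given seed; block orders differ within a session.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for b in range(1, N_BLOCKS + 1):
        trials.extend(_build_block(rng, b))
    session = Session(trials=trials, seed=seed)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    """Draw N(mean, sd) conditioned on exceeding ``lower`` (by resampling)."""
    if sd == 0.0:
        if mean < lower:
            raise ConfigurationError(
                f"degenerate distribution at {mean} below bound {lower}"
            )
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > lower:
            return x
    raise ConfigurationError(
        f"truncation bound {lower} rejects virtually all of N({mean}, {sd})"
    )


def _make_child(
    rng: np.random.Generator,
    child_id: str,
    group: str,
    cfg: GroupConfig,
    config: CohortConfig,
) -> ChildRecord:
    age = rng.normal(cfg.age_mean, cfg.age_sd)
    swan = rng.normal(cfg.swan_mean, cfg.swan_sd)
    sex = "F" if rng.random() < cfg.prop_female else "M"

    swan_z = 0.0 if cfg.swan_sd == 0 else (swan - cfg.swan_mean) / cfg.swan_sd
    slope = config.swan_to_v_slope
    resid_var = cfg.v_sd**2 - slope**2
    if resid_var < 0:
        raise ConfigurationError(
            "swan_to_v_slope exceeds the group drift SD; no residual variance left"
        )
    v_center = cfg.v_mean + slope * swan_z
    v = _truncated_normal(rng, v_center, math.sqrt(resid_var), 0.0)
    a = _truncated_normal(rng, cfg.a_mean, cfg.a_sd, 0.0)
    ter = _truncated_normal(rng, cfg.ter_mean, cfg.ter_sd, config.ter_floor)
    commission = rng.beta(config.commission_alpha, config.commission_beta)

    return ChildRecord(
        child_id=child_id,
        group=group,
        age_years=age,
        sex=sex,
        swan_inattention=swan,
        true_v=v,
        true_a=a,
        true_ter=ter,
        commission_rate=commission,
    )


def generate_cohort(config: CohortConfig) -> list[ChildRecord]:
    """Generate the synthetic two-group cohort.

    Each child receives an independent RNG substream spawned from the
    master seed, so the cohort is reproducible and children are
    statistically independent.  Drift is coupled to the within-group
    SWAN z-score through ``config.swan_to_v_slope`` with the residual
    SD shrunk to preserve the marginal drift SD; v and a are truncated
    positive, Ter at ``config.ter_floor``.
    """
    config.validate()
    n_total = config.vp.n + config.term.n
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    children: list[ChildRecord] = []
    i = 0
    for group, cfg in (("VP", config.vp), ("term", config.term)):
        for k in range(cfg.n):
            rng = np.random.default_rng(streams[i])
            i += 1
            children.append(
                _make_child(rng, f"{group.lower()}{k + 1:02d}", group, cfg, config)
            )
    # Mark trailing term children as missing their SWAN rating.
    for child in children[n_total - config.n_swan_missing_term:]:
        child.swan_inattention = None
    return children


def cohort_to_frame(children: Iterable[ChildRecord]) -> pd.DataFrame:
    """Cohort table with latent fields prefixed ``synthetic_``."""
    rows = []
    for c in children:
        rows.append(
            {
                "child_id": c.child_id,
                "group": c.group,
                "age_years": c.age_years,
                "sex": c.sex,
                "swan_inattention": c.swan_inattention,
                "synthetic_true_v": c.true_v,
                "synthetic_true_a": c.true_a,
                "synthetic_true_ter": c.true_ter,
                "synthetic_commission_rate": c.commission_rate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavioural simulation
# ---------------------------------------------------------------------------

def simulate_child_session(
    child: ChildRecord,
    session_template: Session,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 0.001,
) -> Session:
    """Fill a session template with one child's simulated responses.

    Go trials run the child's latent diffusion process: upper-boundary
    absorption is a response with RT = (Ter + decision time) * 1000 ms,
    lower-boundary absorption a withheld response (miss), and any RT
    beyond the response deadline is censored to a miss.  Each no-go
    trial independently elicits a commission with the child's latent
    false-alarm probability; commission RTs are uniform on 300-1,650 ms.

    The template is not modified; a new Session is returned.
    """
    params = child.latent_parameters()
    if child.commission_rate is None:
        raise ValueError(f"child {child.child_id} has no commission rate")
    if rng is None:
        rng = np.random.default_rng(seed)

    go_idx = session_template.go_indices()
    sample = simulate_diffusion_trials(params, len(go_idx), dt=dt, rng=rng)
    deadline = session_template.deadline_ms

    trials: list[TrialRecord] = []
    go_pos = {idx: k for k, idx in enumerate(go_idx)}
    for i, t in enumerate(session_template.trials):
        responded = False
        rt_ms: float | None = None
        if t.trial_type == "go":
            k = go_pos[i]
            if sample.upper[k]:
                rt = 1000.0 * sample.total_rt[k]
                if rt <= deadline:
                    responded = True
                    rt_ms = rt
        else:
            if rng.random() < child.commission_rate:
                responded = True
                rt_ms = rng.uniform(*COMMISSION_RT_RANGE_MS)
        trials.append(
            TrialRecord(
                block_index=t.block_index,
                trial_index=t.trial_index,
                stimulus_role=t.stimulus_role,
                trial_type=t.trial_type,
                responded=responded,
                rt_ms=rt_ms,
            )
        )
    return Session(
        trials=trials,
        stimulus_duration_ms=session_template.stimulus_duration_ms,
        isi_ms=session_template.isi_ms,
        deadline_ms=session_template.deadline_ms,
        seed=session_template.seed,
    )
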