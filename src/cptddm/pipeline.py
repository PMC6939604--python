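"""End-to-end orchestration: simulate, score, fit, goodness-of-fit, stats.

A run is fully determined by a :class:`RunConfig` (cohort configuration
plus numerical settings and a master seed).  Every stochastic stage
draws its seed from the master seed, so rerunning the same config into
a fresh directory reproduces every output file byte for byte.  Stage
timings are reported on stderr only; the on-disk log is deterministic.

Outputs (all CSV/JSON/YAML, one directory per run):

========================  ====================================================
trials.csv                trial-level responses, one row per child x trial
cohort.csv                demographics + latent generator fields (synthetic_*)
measures.csv              standard measures + EZ input moments per child
ddm_parameters.csv        fitted (v, a, Ter) per child with exclusion flags
gof.csv                   supersubject goodness-of-fit per group
adjusted_means.csv        age-adjusted marginal means per group and measure
mancova.csv               Pillai's trace tests (group, age)
partial_correlations.csv  age-partialed correlations, pooled / VP / term
fisher_comparisons.csv    between-group r-to-z tests per measure
regression_stepwise.csv   hierarchical stepwise models
regression_interaction.csv forced-entry interaction models
manifest.json             seeds, config hash, exclusions, analysis Ns
run.log                   deterministic stage log
config.yaml               resolved configuration
========================  ====================================================
"""
from __future__ import annotations

import hashlib
import json
import math
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ChildRecord,
    CohortConfig,
    Session,
    TrialRecord,
    cohort_to_frame,
    generate_cohort,
    generate_trial_sequence,
    simulate_child_session,
)
from .ddm import (
    DEFAULT_SCALING,
    SummaryStats,
    ez_fit,
    goodness_of_fit,
)
from .inference import (
    P_ENTER_DEFAULT,
    P_REMOVE_DEFAULT,
    age_adjusted_means,
    fisher_compare,
    hierarchical_stepwise_regression,
    interaction_regression,
    mancova_pillai,
    partial_correlation,
)
from .scoring import InsufficientData, ez_inputs_from_session, score_session

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_stage",
    "score_stage",
    "fit_stage",
    "gof_stage",
    "stats_stage",
    "fixture_toy_session",
    "build_toy_session",
    "MEASURE_COLUMNS",
]

#: The seven measures entering the multivariate comparison and the
#: correlation table, in reporting order.
MEASURE_COLUMNS = [
    "commission_pct",
    "hit_rate_pct",
    "mrt_ms",
    "sdrt_ms",
    "v",
    "a",
    "ter",
]

#: Candidates for the stepwise block (measures correlated with
#: inattention in at least one group).
STEPWISE_CANDIDATES = ["hit_rate_pct", "sdrt_ms", "v"]

EXCLUSION_PERFECT = "perfect_accuracy"
EXCLUSION_CHANCE = "chance_accuracy"
EXCLUSION_INSUFFICIENT = "insufficient_hits"


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scaling_s: float = DEFAULT_SCALING
    sim_dt: float = 0.001
    gof_n_trials: int = 1000
    p_enter: float = P_ENTER_DEFAULT
    p_remove: float = P_REMOVE_DEFAULT
    seed: int = 0
    verbose: bool = False

    def resolve_seeds(self) -> dict[str, int]:
        """Derive per-stage seeds from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        seq, coh, sess, gof = (
            int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(4)
        )
        return {"sequence": seq, "cohort": coh, "sessions": sess, "gof": gof}

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], dict):
            data["cohort"] = CohortConfig.from_dict(data["cohort"])
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_stage(
    config: RunConfig,
) -> tuple[Session, list[ChildRecord], pd.DataFrame, pd.DataFrame]:
    """Generate the task template, cohort and all simulated sessions.

    Returns (template, children, trials table, cohort table).
    """
    seeds = config.resolve_seeds()
    template = generate_trial_sequence(seeds["sequence"])
    cohort_cfg = CohortConfig.from_dict(config.cohort.to_dict())
    cohort_cfg.seed = seeds["cohort"]
    children = generate_cohort(cohort_cfg)

    session_streams = np.random.SeedSequence(seeds["sessions"]).spawn(len(children))
    frames = []
    for child, stream in zip(children, session_streams):
        session = simulate_child_session(
            child, template, rng=np.random.default_rng(stream), dt=config.sim_dt
        )
        frames.append(session.to_frame(child_id=child.child_id))
    trials = pd.concat(frames, ignore_index=True)
    return template, children, trials, cohort_to_frame(children)


def score_stage(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every child's session: standard measures + EZ input moments."""
    rows = []
    for child_id, frame in trials.groupby("child_id", sort=False):
        session = Session.from_frame(frame)
        m = score_session(session)
        row = {
            "child_id": child_id,
            "hit_rate_pct": m.hit_rate_pct,
            "commission_pct": m.commission_pct,
            "mrt_ms": m.mrt_ms,
            "sdrt_ms": m.sdrt_ms,
            "n_hits": m.n_hits,
        }
        try:
            ez = ez_inputs_from_session(session)
            row.update(pc=ez.pc, mrt_s=ez.mrt, vrt_s2=ez.vrt)
        except InsufficientData:
            row.update(pc=m.hit_rate_pct / 100.0, mrt_s=math.nan, vrt_s2=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_stage(measures: pd.DataFrame, s: float = DEFAULT_SCALING) -> pd.DataFrame:
    """Fit EZ parameters per child, flagging children that cannot be fitted.

    Children at 100% accuracy are excluded (the closed form is
    undefined there and edge corrections are unreliable at 40 trials);
    exact-chance accuracy and fewer than two hits are likewise flagged.
    """
    rows = []
    for row in measures.itertuples(index=False):
        out = {
            "child_id": row.child_id,
            "v": math.nan,
            "a": math.nan,
            "ter": math.nan,
            "s": s,
            "pc": row.pc,
            "mrt_s": row.mrt_s,
            "vrt_s2": row.vrt_s2,
            "excluded_flag": 0,
            "exclusion_reason": "",
        }
        if not math.isfinite(row.vrt_s2):
            out.update(excluded_flag=1, exclusion_reason=EXCLUSION_INSUFFICIENT)
        elif row.pc in (0.0, 1.0):
            reason = EXCLUSION_PERFECT if row.pc == 1.0 else EXCLUSION_INSUFFICIENT
            out.update(excluded_flag=1, exclusion_reason=reason)
        elif row.pc == 0.5:
            out.update(excluded_flag=1, exclusion_reason=EXCLUSION_CHANCE)
        else:
            params = ez_fit(SummaryStats(row.pc, row.mrt_s, row.vrt_s2), s=s)
            out.update(v=params.v, a=params.a, ter=params.ter)
        rows.append(out)
    return pd.DataFrame(rows)


def build_analysis_table(
    cohort: pd.DataFrame, measures: pd.DataFrame, params: pd.DataFrame
) -> pd.DataFrame:
    """Merge demographics, measures and fitted parameters per child.

    Latent ``synthetic_*`` columns are deliberately dropped: analysis
    stages must not see generator state.
    """
    demo = cohort[["child_id", "group", "age_years", "sex", "swan_inattention"]]
    table = demo.merge(measures, on="child_id").merge(
        params[["child_id", "v", "a", "ter", "excluded_flag", "exclusion_reason"]],
        on="child_id",
    )
    return table


def cohort_replicate(config: RunConfig) -> pd.DataFrame:
    """One synthetic cohort taken straight to its analysis table.

    Object-route shortcut for replicate studies: simulates, scores and
    fits every child in memory without building trial-level frames.
    Identical statistical content to the full pipeline's analysis table.
    """
    seeds = config.resolve_seeds()
    template = generate_trial_sequence(seeds["sequence"])
    cohort_cfg = CohortConfig.from_dict(config.cohort.to_dict())
    cohort_cfg.seed = seeds["cohort"]
    children = generate_cohort(cohort_cfg)
    session_streams = np.random.SeedSequence(seeds["sessions"]).spawn(len(children))

    rows = []
    for child, stream in zip(children, session_streams):
        session = simulate_child_session(
            child, template, rng=np.random.default_rng(stream), dt=config.sim_dt
        )
        m = score_session(session)
        row = {
            "child_id": child.child_id,
            "group": child.group,
            "age_years": child.age_years,
            "sex": child.sex,
            "swan_inattention": child.swan_inattention,
            "hit_rate_pct": m.hit_rate_pct,
            "commission_pct": m.commission_pct,
            "mrt_ms": m.mrt_ms,
            "sdrt_ms": m.sdrt_ms,
            "n_hits": m.n_hits,
            "v": math.nan,
            "a": math.nan,
            "ter": math.nan,
            "excluded_flag": 1,
            "exclusion_reason": EXCLUSION_INSUFFICIENT,
        }
        try:
            ez = ez_inputs_from_session(session)
            if ez.pc == 1.0:
                row["exclusion_reason"] = EXCLUSION_PERFECT
            elif ez.pc == 0.5:
                row["exclusion_reason"] = EXCLUSION_CHANCE
            else:
                p = ez_fit(ez, s=config.scaling_s)
                row.update(
                    v=p.v, a=p.a, ter=p.ter, excluded_flag=0, exclusion_reason=""
                )
        except InsufficientData:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def gof_stage(
    analysis: pd.DataFrame,
    n_trials: int = 1000,
    seed: int | None = None,
    dt: float = 0.001,
    s: float = DEFAULT_SCALING,
) -> pd.DataFrame:
    """Group-averaged supersubject goodness of fit on included children."""
    included = analysis[analysis["excluded_flag"] == 0]
    return goodness_of_fit(included, n_trials=n_trials, seed=seed, dt=dt, s=s)


def stats_stage(
    analysis: pd.DataFrame,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> dict:
    """Run the full inferential battery on the analysis table.

    Children flagged at the fitting stage are excluded throughout; the
    multivariate comparison uses every child with complete measures,
    while correlation/regression additionally lose children without a
    SWAN rating (listwise deletion).
    """
    included = analysis[analysis["excluded_flag"] == 0].copy()

    mancova = mancova_pillai(included, MEASURE_COLUMNS)
    adjusted = age_adjusted_means(included, MEASURE_COLUMNS)

    # Age-partialed correlations with inattention, pooled and per group.
    swan = included.dropna(subset=["swan_inattention"])
    corr_rows = []
    group_r: dict[tuple[str, str], tuple[float, int]] = {}
    scopes = [("pooled", swan)] + [
        (g, swan[swan["group"] == g]) for g in sorted(swan["group"].unique())
    ]
    for scope, sub in scopes:
        for measure in MEASURE_COLUMNS:
            res = partial_correlation(
                sub[measure], sub["swan_inattention"], sub["age_years"]
            )
            corr_rows.append(
                {"scope": scope, "measure": measure, "r": res.r, "n": res.n,
                 "p": res.p}
            )
            if scope != "pooled":
                group_r[(scope, measure)] = (res.r, res.n)
    correlations = pd.DataFrame(corr_rows)

    fisher_rows = []
    groups = sorted(swan["group"].unique())
    if len(groups) == 2:
        g1, g2 = groups
        for measure in MEASURE_COLUMNS:
            r1, n1 = group_r[(g1, measure)]
            r2, n2 = group_r[(g2, measure)]
            cmp_ = fisher_compare(r1, n1, r2, n2)
            fisher_rows.append(
                {"measure": measure, "group_1": g1, "group_2": g2,
                 "z": cmp_.z, "p": cmp_.p}
            )
    fisher = pd.DataFrame(fisher_rows)

    stepwise = hierarchical_stepwise_regression(
        included, p_enter=p_enter, p_remove=p_remove
    )
    interaction = interaction_regression(included)

    return {
        "mancova": mancova,
        "adjusted_means": adjusted,
        "correlations": correlations,
        "fisher": fisher,
        "stepwise": stepwise,
        "interaction": interaction,
    }


def _regression_frame(models: list) -> pd.DataFrame:
    rows = []
    for m in models:
        for pred in m.predictors:
            rows.append(
                {
                    "model": m.label,
                    "predictor": pred,
                    "beta": m.beta[pred],
                    "p_coef": m.coef_p[pred],
                    "r2": m.r2,
                    "delta_r2": m.delta_r2,
                    "F": m.f,
                    "df1": m.df1,
                    "df2": m.df2,
                    "p_model": m.p,
                    "n": m.n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Execute the full pipeline and write every output to ``out_dir``.

    Deterministic: identical (config, seed) produce byte-identical
    directories.  Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        if config.verbose:
            print(msg, file=sys.stderr)

    t0 = time.perf_counter()
    seeds = config.resolve_seeds()
    log(f"cptddm {__version__} | config {config.config_hash()}")
    log(f"seeds: {json.dumps(seeds, sort_keys=True)}")

    def stage(name):
        print(f"[{name}] {time.perf_counter() - t0:.1f}s", file=sys.stderr)

    template, children, trials, cohort = simulate_stage(config)
    stage("simulate")
    log(f"simulate: {len(children)} children x {len(template.trials)} trials")

    measures = score_stage(trials)
    stage("score")
    log(f"score: {len(measures)} sessions scored")

    params = fit_stage(measures, s=config.scaling_s)
    stage("fit")
    excl = params[params["excluded_flag"] == 1]
    excl_counts = excl["exclusion_reason"].value_counts().to_dict()
    log(f"fit: {int((params['excluded_flag'] == 0).sum())} fitted, "
        f"exclusions {json.dumps(excl_counts, sort_keys=True)}")

    analysis = build_analysis_table(cohort, measures, params)
    gof = gof_stage(
        analysis,
        n_trials=config.gof_n_trials,
        seed=seeds["gof"],
        dt=config.sim_dt,
        s=config.scaling_s,
    )
    stage("gof")

    results = stats_stage(analysis, p_enter=config.p_enter, p_remove=config.p_remove)
    stage("stats")
    n_mancova = results["mancova"].n
    n_regression = results["stepwise"][0].n
    log(f"stats: MANCOVA N = {n_mancova}, regression N = {n_regression}")

    # --- write everything -------------------------------------------------
    config.to_yaml(out / "config.yaml")
    trials.to_csv(out / "trials.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    measures.to_csv(out / "measures.csv", index=False)
    params.to_csv(out / "ddm_parameters.csv", index=False)
    gof.to_csv(out / "gof.csv", index=False)
    results["adjusted_means"].to_csv(out / "adjusted_means.csv", index=False)
    results["mancova"].table.to_csv(out / "mancova.csv", index=False)
    results["correlations"].to_csv(out / "partial_correlations.csv", index=False)
    results["fisher"].to_csv(out / "fisher_comparisons.csv", index=False)
    _regression_frame(results["stepwise"]).to_csv(
        out / "regression_stepwise.csv", index=False
    )
    _regression_frame(results["interaction"]).to_csv(
        out / "regression_interaction.csv", index=False
    )

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "n_children": len(children),
        "n_fitted": int((params["excluded_flag"] == 0).sum()),
        "exclusions": excl_counts,
        "excluded_children": excl["child_id"].tolist(),
        "analysis_n": {"mancova": int(n_mancova), "regression": int(n_regression)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    stage("done")
    return out


# ---------------------------------------------------------------------------
# Hand-constructed fixture session
# ---------------------------------------------------------------------------

def build_toy_session() -> Session:
    """Deterministically construct the 400-trial toy session.

    Layout per block: go pairs start at positions 0, 10, ..., 90 (cue
    then go target); cue-only trials sit at positions 4, 14, ..., 94;
    uncued targets at 7, 17, ..., 97; every other slot is a distractor
    with identity cycling through the 11 shapes.

    Responses (identical across blocks, hand-countable):

    * 38 go trials answered in-window with RTs 410, 420, ..., 780 ms
      (mean 595 ms, sample variance 100 * 38 * 39 / 12 = 12,350 ms^2);
    * the first go trial of blocks 1 and 3 answered at 150 ms
      (anticipatory: rejected, counts as a miss);
    * 9 no-go responses at 500 ms: the first cue-only (position 4) and
      first uncued target (position 7) of every block, plus the
      distractor at block 1 position 2.

    Hence hit rate 38/40 = 95%, commission 9/360 = 2.5%,
    MRT 595 ms, SDRT sqrt(12350) ~ 111.13 ms.
    """
    trials: list[TrialRecord] = []
    go_counter = 0
    hit_counter = 0
    for b in range(1, 5):
        roles = {}
        types = {}
        for p in range(0, 100, 10):
            roles[p] = "cue"
            types[p] = "filler"
            roles[p + 1] = "target"
            types[p + 1] = "go"
        for p in range(4, 100, 10):
            roles[p] = "cue"
            types[p] = "cue_only"
        for p in range(7, 100, 10):
            roles[p] = "target"
            types[p] = "uncued_target"
        for i in range(100):
            if i not in roles:
                roles[i] = f"distractor_{(b * 7 + i) % 11 + 1}"
                types[i] = "filler"

        for i in range(100):
            ttype = types[i]
            responded = False
            rt = None
            if ttype == "go":
                go_counter += 1
                if go_counter in (1, 21):  # anticipatory responses
                    responded, rt = True, 150.0
                else:
                    responded, rt = True, 410.0 + 10.0 * hit_counter
                    hit_counter += 1
            elif (i == 4 or i == 7) or (b == 1 and i == 2):
                responded, rt = True, 500.0
            trials.append(
                TrialRecord(
                    block_index=b,
                    trial_index=i + 1,
                    stimulus_role=roles[i],
                    trial_type=ttype,
                    responded=responded,
                    rt_ms=rt,
                )
            )
    session = Session(trials=trials)
    session.validate()
    return session


def fixture_toy_session() -> Session:
    """Load the repository's toy session from its packaged CSV.

    The CSV is the stored form of :func:`build_toy_session` (see that
    docstring for the hand-counted scoring answers) and the two are
    asserted equal in the test-suite.
    """
    from importlib.resources import files

    path = files("cptddm").joinpath("data/toy_session.csv")
    with path.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return Session.from_frame(frame)
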