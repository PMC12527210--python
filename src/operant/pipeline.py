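"""End-to-end analysis pipeline: simulate (or import) a cohort, apply the
inclusion filter, compute response ratios, and run the experiment's test
battery.

The analysis battery mirrors the pre-registered structure of the task:

* *sensitivity* tests — one-sample t of each briefly-trained cue's
  within-subject response ratio against 0.5, alternative "greater"
  (responding should drop under a degraded contingency if behaviour is
  goal-directed);
* *within-subject overtraining* tests — paired one-tailed t on
  (standard − overtrained) and, where a filler cue exists,
  (filler − overtrained) ratio differences, alternative "greater"
  (overtraining should push ratios toward 0.5);
* *between-subject first-test* comparison — participants grouped by which
  cue was degraded first, comparing single-baseline-block first-test-block
  ratios (standard group vs overtrained group), pooled-variance form unless
  an F pre-check rejects variance equality at α = .05;
* correlations — programmed vs experienced ΔP (block-pooled and
  participant-mean aggregations) and, per cue, within-subject ratio vs mean
  causality rating in the cue's degraded blocks.

The event-log / block-log CSV pair is the sole contract between simulation
and analysis, so externally collected data in the same shape flows through
identical code paths.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .design import VARIANTS, BlockSpec, make_contingency
from .inference import (
    DEFAULT_CAUCHY_SCALE,
    RobustnessCurve,
    TestResult,
    bf_robustness,
    one_sample_t,
    paired_t,
    pearson_r,
    two_sample_t,
)
from .measures import (
    apply_inclusion,
    measures_table,
    participant_ratio,
    summary_grid,
)
from .simulate import BlockData, ParticipantData, simulate_cohort
from scipy import stats

__all__ = [
    "ExperimentConfig",
    "AnalysisReport",
    "SchemaError",
    "load_config",
    "run_experiment",
    "write_event_log",
    "read_event_log",
]

EVENT_COLUMNS = [
    "participant_id",
    "variant",
    "group",
    "session",
    "block_position",
    "cue",
    "phase",
    "p1",
    "p2",
    "bin_index",
    "responded",
    "outcome",
]

BLOCK_COLUMNS = [
    "participant_id",
    "variant",
    "group",
    "session",
    "position",
    "cue",
    "phase",
    "p1",
    "p2",
    "duration_bins",
    "causality_rating",
    "memory_correct",
]


class SchemaError(ValueError):
    """Raised when an event/block log violates the documented CSV schema."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Inputs of one analysis run.

    Either a simulated cohort (``n_participants``, ``preset``, ``seed``) or
    an imported one (``event_log`` + ``block_log`` paths).
    """

    variant: str
    n_participants: int = 50
    seed: int = 0
    preset: str = "goal_directed"
    event_log: str | None = None
    block_log: str | None = None
    memory_threshold: float = 0.9
    robustness_scales: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if (self.event_log is None) != (self.block_log is None):
            raise ValueError("event_log and block_log must be given together")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a JSON or TOML file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a table/object")
    if "robustness_scales" in data and data["robustness_scales"] is not None:
        data["robustness_scales"] = tuple(data["robustness_scales"])
    try:
        return ExperimentConfig(**data)
    except TypeError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc


# --- event-log I/O ---------------------------------------------------------

def write_event_log(
    cohort: Sequence[ParticipantData],
    event_path: str | Path,
    block_path: str | Path,
) -> None:
    """Write the cohort as the documented event-log / block-log CSV pair
    (one row per 1-s bin, and one row per block)."""
    event_frames: list[pd.DataFrame] = []
    block_rows: list[dict[str, Any]] = []
    for p in cohort:
        for b in p.blocks:
            s = b.spec
            n = s.duration_bins
            event_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.full(n, p.participant_id),
                        "variant": p.variant,
                        "group": p.counterbalance_group or "",
                        "session": np.full(n, s.session),
                        "block_position": np.full(n, s.position),
                        "cue": s.cue,
                        "phase": s.phase,
                        "p1": s.contingency.p_outcome_given_action,
                        "p2": s.contingency.p_outcome_given_no_action,
                        "bin_index": np.arange(n),
                        "responded": b.responded.astype(int),
                        "outcome": b.outcomes.astype(int),
                    }
                )
            )
            block_rows.append(
                {
                    "participant_id": p.participant_id,
                    "variant": p.variant,
                    "group": p.counterbalance_group or "",
                    "session": s.session,
                    "position": s.position,
                    "cue": s.cue,
                    "phase": s.phase,
                    "p1": s.contingency.p_outcome_given_action,
                    "p2": s.contingency.p_outcome_given_no_action,
                    "duration_bins": s.duration_bins,
                    "causality_rating": b.causality_rating,
                    "memory_correct": int(b.memory_correct),
                }
            )
    pd.concat(event_frames, ignore_index=True)[EVENT_COLUMNS].to_csv(
        event_path, index=False
    )
    pd.DataFrame(block_rows)[BLOCK_COLUMNS].to_csv(block_path, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")


def read_event_log(
    event_path: str | Path,
    block_path: str | Path,
) -> list[ParticipantData]:
    """Read an event-log / block-log CSV pair back into a cohort.

    Validates the schema (binary responded/outcome flags, probabilities in
    [0, 1], ratings on the −100..100 scale, and bin counts matching each
    block's declared duration) and raises :class:`SchemaError` naming the
    offending rows or blocks.  Round-trips with :func:`write_event_log`.
    """
    events = pd.read_csv(event_path, keep_default_na=False)
    blocks = pd.read_csv(block_path, keep_default_na=False)
    _require_columns(events, EVENT_COLUMNS, "event log")
    _require_columns(blocks, BLOCK_COLUMNS, "block log")

    bad = events.index[~events["responded"].isin([0, 1])].tolist()
    if bad:
        raise SchemaError(f"event log: responded not in {{0,1}} at rows {bad[:10]}")
    bad = events.index[~events["outcome"].isin([0, 1])].tolist()
    if bad:
        raise SchemaError(f"event log: outcome not in {{0,1}} at rows {bad[:10]}")
    for col in ("p1", "p2"):
        bad = blocks.index[(blocks[col] < 0) | (blocks[col] > 1)].tolist()
        if bad:
            raise SchemaError(f"block log: {col} outside [0,1] at rows {bad[:10]}")
    bad = blocks.index[
        (blocks["causality_rating"] < -100) | (blocks["causality_rating"] > 100)
    ].tolist()
    if bad:
        raise SchemaError(f"block log: rating outside -100..100 at rows {bad[:10]}")

    key = ["participant_id", "session", "block_position"]
    grouped = {k: g for k, g in events.groupby(key, sort=False)}

    cohort: list[ParticipantData] = []
    for pid, pblocks in blocks.groupby("participant_id", sort=True):
        pblocks = pblocks.sort_values(["session", "position"])
        variant = str(pblocks["variant"].iloc[0])
        group = str(pblocks["group"].iloc[0]) or None
        block_data: list[BlockData] = []
        for row in pblocks.itertuples(index=False):
            spec = BlockSpec(
                session=int(row.session),
                position=int(row.position),
                cue=str(row.cue),
                phase=str(row.phase),
                contingency=make_contingency(float(row.p1), float(row.p2)),
                duration_bins=int(row.duration_bins),
            )
            label = f"participant {pid} session {spec.session} block {spec.position}"
            g = grouped.get((row.participant_id, row.session, row.position))
            if g is None:
                raise SchemaError(f"{label}: no event rows")
            g = g.sort_values("bin_index")
            if len(g) != spec.duration_bins or not np.array_equal(
                g["bin_index"].to_numpy(), np.arange(spec.duration_bins)
            ):
                raise SchemaError(
                    f"{label}: expected bins 0..{spec.duration_bins - 1}, "
                    f"found {len(g)} rows"
                )
            block_data.append(
                BlockData(
                    spec=spec,
                    responded=g["responded"].to_numpy(dtype=bool),
                    outcomes=g["outcome"].to_numpy(dtype=bool),
                    causality_rating=int(row.causality_rating),
                    memory_correct=bool(int(row.memory_correct)),
                )
            )
        cohort.append(
            ParticipantData(
                participant_id=int(pid),
                variant=variant,
                counterbalance_group=group,
                blocks=block_data,
            )
        )
    return cohort


# --- analysis battery ------------------------------------------------------

def _test_to_dict(res: TestResult) -> dict[str, Any]:
    d = asdict(res)
    d["bf01"] = None if math.isnan(res.bf10) else res.bf01
    return d


def _ratio_frame(cohort: Sequence[ParticipantData]) -> pd.DataFrame:
    """Within-subject two-block-baseline ratios, one row per participant/cue."""
    rows = []
    for p in cohort:
        cues = {b.spec.cue for b in p.blocks if b.spec.phase == "habit_test"}
        for cue in sorted(cues):
            score = participant_ratio(p, cue)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "cue": cue,
                    "ratio": score.ratio,
                    "first_test_cue": p.first_test_cue(),
                }
            )
    return pd.DataFrame(rows)


def _variance_precheck(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> bool:
    """Two-sided F test of variance equality; True => use the Welch form."""
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 or v2 == 0:
        return False
    f = v1 / v2
    p = 2.0 * min(
        stats.f.sf(f, x.size - 1, y.size - 1),
        stats.f.cdf(f, x.size - 1, y.size - 1),
    )
    return bool(p < alpha)


@dataclass
class AnalysisReport:
    """Structured results of one experiment analysis."""

    variant: str
    seed: int
    config: dict[str, Any]
    config_hash: str
    version: str
    rng_info: str
    n_total: int
    n_included: int
    excluded_ids: list[int]
    group_sizes: dict[str, int]
    grid_participant: list[dict[str, Any]]
    grid_block: list[dict[str, Any]]
    ratios: dict[str, dict[str, float]]
    tests: dict[str, dict[str, Any]]
    correlations: dict[str, dict[str, Any]]
    robustness: dict[str, dict[str, list[float]]]
    missing: dict[str, int]

    def to_dict(self) -> dict[str, Any]:
        return _round_floats(asdict(self), 4)

    def to_json(self) -> str:
        """Deterministic JSON: keys sorted, floats at 4 decimals."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _round_floats(obj: Any, ndigits: int) -> Any:
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    return obj


def run_experiment(config: ExperimentConfig | dict | str | Path) -> AnalysisReport:
    """Run the full analysis battery for one experiment variant.

    Accepts an :class:`ExperimentConfig`, a plain dict of its fields, or a
    path to a JSON/TOML config file.  Identical config + seed produce a
    byte-identical :meth:`AnalysisReport.to_json`.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = ExperimentConfig(**config)

    if config.event_log is not None:
        cohort = read_event_log(config.event_log, config.block_log)
    else:
        cohort = simulate_cohort(
            config.variant, config.n_participants, config.preset, config.seed
        )
    n_total = len(cohort)
    included, excluded = apply_inclusion(cohort, config.memory_threshold)

    ratios = _ratio_frame(included)
    has_filler = "filler" in set(ratios["cue"])
    wide = ratios.pivot(index="participant_id", columns="cue", values="ratio")
    first_cue = ratios.groupby("participant_id")["first_test_cue"].first()

    missing = {
        f"ratio_{cue}": int(wide[cue].isna().sum()) for cue in wide.columns
    }

    tests: dict[str, dict[str, Any]] = {}
    inputs_note: dict[str, Any]

    def _clean(cue: str) -> np.ndarray:
        return wide[cue].dropna().to_numpy()

    # Sensitivity: ratio > 0.5 for the briefly trained cues.
    if has_filler:
        res = one_sample_t(_clean("filler"), 0.5, "greater")
        tests["sensitivity_filler"] = _test_to_dict(res)
    res = one_sample_t(_clean("standard"), 0.5, "greater")
    tests["sensitivity_standard"] = _test_to_dict(res)

    # Within-subject overtraining comparisons (listwise complete pairs).
    pair = wide[["standard", "overtrained"]].dropna()
    tests["within_standard_vs_overtrained"] = _test_to_dict(
        paired_t(pair["standard"], pair["overtrained"], "greater")
    )
    if has_filler:
        pair_f = wide[["filler", "overtrained"]].dropna()
        tests["within_filler_vs_overtrained"] = _test_to_dict(
            paired_t(pair_f["filler"], pair_f["overtrained"], "greater")
        )

    # Between-subject first-test-block comparison with a one-block baseline.
    first_ratios: dict[str, list[float]] = {"standard": [], "overtrained": []}
    for p in included:
        cue = p.first_test_cue()
        score = participant_ratio(p, cue, n_baseline=1, first_test_only=True)
        if not math.isnan(score.ratio):
            first_ratios[cue].append(score.ratio)
    gs = np.asarray(first_ratios["standard"])
    go = np.asarray(first_ratios["overtrained"])
    group_sizes = {"standard_first": int(gs.size), "overtrained_first": int(go.size)}
    if gs.size >= 2 and go.size >= 2:
        welch = _variance_precheck(gs, go)
        res = two_sample_t(gs, go, "greater", unequal_variance=welch)
        d = _test_to_dict(res)
        d["unequal_variance"] = welch
        tests["between_first_test"] = d

    # Correlations.
    table = measures_table(included)
    correlations: dict[str, dict[str, Any]] = {}
    pooled = table.dropna(subset=["delta_p_hat"])
    missing["delta_p_hat_blocks"] = int(table["delta_p_hat"].isna().sum())
    r, p = pearson_r(pooled["delta_p"], pooled["delta_p_hat"])
    correlations["programmed_vs_experienced_blocks"] = {
        "r": r, "p": p, "n": int(len(pooled)),
    }
    per_part = (
        table.groupby(["participant_id", "cue", "phase", "delta_p"], as_index=False)[
            "delta_p_hat"
        ]
        .mean()
        .dropna(subset=["delta_p_hat"])
    )
    r, p = pearson_r(per_part["delta_p"], per_part["delta_p_hat"])
    correlations["programmed_vs_experienced_participant_means"] = {
        "r": r, "p": p, "n": int(len(per_part)),
    }

    neg = table[table["phase"] == "habit_test"]
    mean_ratings = (
        neg.groupby(["participant_id", "cue"])["causality_rating"].mean().rename("rating")
    )
    for cue in sorted(set(ratios["cue"])):
        joined = (
            wide[cue]
            .rename("ratio")
            .to_frame()
            .join(mean_ratings.xs(cue, level="cue"))
            .dropna()
        )
        if len(joined) >= 3 and joined["ratio"].std() > 0 and joined["rating"].std() > 0:
            r, p = pearson_r(joined["ratio"], joined["rating"])
            correlations[f"ratio_vs_causality_{cue}"] = {
                "r": r, "p": p, "n": int(len(joined)),
            }

    # Optional robustness sweeps for every computed t-test.
    robustness: dict[str, dict[str, list[float]]] = {}
    if config.robustness_scales:
        for label, d in tests.items():
            if d.get("error"):
                continue
            curve = bf_robustness(
                d["statistic"], d["n1"], d.get("n2"), config.robustness_scales
            )
            robustness[label] = {
                "prior_scales": list(curve.prior_scales),
                "bf10_values": list(curve.bf10_values),
            }

    ratio_summary = {
        cue: {
            "mean": float(wide[cue].mean()),
            "sd": float(wide[cue].std(ddof=1)),
            "n": int(wide[cue].notna().sum()),
        }
        for cue in wide.columns
    }

    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
    }
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    return AnalysisReport(
        variant=config.variant,
        seed=config.seed,
        config=cfg_dict,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__,
        rng_info=f"numpy {np.__version__} PCG64 via SeedSequence",
        n_total=n_total,
        n_included=len(included),
        excluded_ids=excluded,
        group_sizes=group_sizes,
        grid_participant=summary_grid(included, "participant").to_dict("records"),
        grid_block=summary_grid(included, "block").to_dict("records"),
        ratios=ratio_summary,
        tests=tests,
        correlations=correlations,
        robustness=robustness,
        missing=missing,
    )
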