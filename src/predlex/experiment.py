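"""Experimental harness: counterbalanced pre/post-training runs of both
models, deviation-point-aligned aggregation, findings checks, and report
export.

Both counterbalance assignments are always executed (A: the triple's first
nonword is the trained novel item; B: the second is), each against the
original ("pre") and trained ("post") lexicon, and cell means average over
items and the two assignments.  Signals are aligned on the deviation point:
by DP-relative phoneme position for the cohort prediction model (pre-DP
positions <= 0), and by cycle relative to the DP phoneme's input onset for
the interactive-activation simulator (pre-DP cycles < 0).

The three findings checked per signal:

1. pre-training, post-DP window: expected input (source) carries less signal
   than both nonwords, which are mutually comparable;
2. post-training, post-DP window: the trained novel item patterns with the
   source, and both carry less signal than the untrained baseline;
3. the pre-DP aggregate changes between phases in the signal's expected
   direction (e.g. prediction error decreases, total lexical feedback
   increases, phoneme-layer totals are unchanged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import iam_simulator as iam
from .lexicon import ItemTriple, Lexicon, train_lexicon
from .prediction_model import PredictionConfig, error_trajectory

__all__ = [
    "AlignedResult",
    "FindingsReport",
    "run_counterbalanced",
    "check_findings",
    "export_report",
    "PREDICTION_SIGNALS",
    "IAM_SIGNALS",
    "SIGNAL_ORIENTATION",
    "FINDING3_DIRECTION",
    "default_windows",
]

PREDICTION_SIGNALS = ("prediction_error", "prob_observed")
IAM_SIGNALS = ("total_feedback", "total_word_act", "total_phoneme_act",
               "phoneme_activation")

# +1: the signal is larger for unexpected input; -1: larger for expected.
SIGNAL_ORIENTATION = {
    "prediction_error": +1,
    "prob_observed": -1,
    "total_feedback": +1,
    "total_word_act": +1,
    "total_phoneme_act": +1,
    "phoneme_activation": -1,
}

# Expected pre-DP change from pre- to post-training.
FINDING3_DIRECTION = {
    "prediction_error": "decrease",
    "prob_observed": "increase",
    "total_feedback": "increase",
    "total_word_act": "decrease",
    "total_phoneme_act": "unchanged",
}

CONDITIONS = ("source", "novel", "baseline")
PHASES = ("pre", "post")
ASSIGNMENTS = ("A", "B")
_ROLE = {"A": "novel", "B": "baseline"}

Window = tuple[int | None, int | None]


def default_windows(model: str) -> tuple[Window, Window]:
    """(post_dp_window, pre_dp_window) in DP-relative units for ``model``."""
    if model == "prediction":
        return (1, 2), (None, 0)
    if model == "iam":
        return (0, None), (None, -1)
    raise ValueError(f"unknown model: {model!r}")


@dataclass
class AlignedResult:
    """Condition x phase x DP-relative-position aggregate of one signal.

    ``cells`` holds the mean per (condition, phase, rel) over contributing
    items and both counterbalance assignments; ``per_item`` retains the
    underlying long table for window aggregates and verification.
    """

    signal_name: str
    cells: pd.DataFrame  # columns: condition, phase, rel, mean, n_items
    per_item: pd.DataFrame = field(repr=False)  # + assignment, item, value

    def cell_mean(self, condition: str, phase: str, rel: int) -> float:
        m = self.cells[
            (self.cells.condition == condition)
            & (self.cells.phase == phase)
            & (self.cells.rel == rel)
        ]
        if m.empty:
            raise KeyError(f"no cell ({condition}, {phase}, rel={rel})")
        return float(m["mean"].iloc[0])

    def window_mean(
        self,
        phase: str,
        window: Window,
        condition: str | None = None,
    ) -> float:
        """Mean of per-item values with rel inside ``window`` (inclusive,
        ``None`` = unbounded); all conditions pooled when none is given."""
        lo, hi = window
        df = self.per_item[self.per_item.phase == phase]
        if condition is not None:
            df = df[df.condition == condition]
        if lo is not None:
            df = df[df.rel >= lo]
        if hi is not None:
            df = df[df.rel <= hi]
        if df.empty:
            raise KeyError(
                f"no values for phase={phase}, condition={condition}, window={window}"
            )
        return float(df.value.mean())


def _aggregate(long: pd.DataFrame) -> dict[str, AlignedResult]:
    out = {}
    for signal, df in long.groupby("signal", sort=True):
        cells = (
            df.groupby(["condition", "phase", "rel"], sort=True)
            .agg(mean=("value", "mean"), n_items=("value", "size"))
            .reset_index()
        )
        out[str(signal)] = AlignedResult(str(signal), cells, df.reset_index(drop=True))
    return out


def _conditions_for(triple: ItemTriple, role: str) -> dict[str, tuple[str, ...]]:
    trained = getattr(triple, role)
    untrained = triple.baseline if role == "novel" else triple.novel
    return {"source": triple.source, "novel": trained, "baseline": untrained}


def run_counterbalanced(
    lex: Lexicon,
    triples: Sequence[ItemTriple],
    model: str = "prediction",
    prediction_config: PredictionConfig = PredictionConfig(),
    iam_params: iam.IAMParameters = iam.IAMParameters(),
    assignments: Sequence[str] = ASSIGNMENTS,
) -> dict[str, AlignedResult]:
    """Run both counterbalance assignments in both phases; aggregate by DP.

    Returns one :class:`AlignedResult` per signal of the chosen model.
    """
    if model not in ("prediction", "iam"):
        raise ValueError(f"unknown model: {model!r}")
    for t in triples:
        t.check_against(lex)
    rows: list[dict] = []
    for assignment in assignments:
        role = _ROLE[assignment]
        lex_by_phase = {"pre": lex, "post": train_lexicon(lex, triples, role)}
        for phase, lex_phase in lex_by_phase.items():
            if model == "iam":
                max_len = max(
                    len(f)
                    for t in triples
                    for f in (t.source, t.novel, t.baseline)
                )
                n_slices = iam.default_n_slices(max_len, lex_phase, iam_params)
                network = iam.build_network(lex_phase, iam_params, n_slices)
            for i, t in enumerate(triples):
                for condition, form in _conditions_for(t, role).items():
                    if model == "prediction":
                        rows.extend(
                            _prediction_rows(
                                lex_phase, form, t, prediction_config,
                                assignment, phase, condition, i,
                            )
                        )
                    else:
                        rows.extend(
                            _iam_rows(
                                network, form, t, iam_params,
                                assignment, phase, condition, i,
                            )
                        )
    long = pd.DataFrame(rows)
    return _aggregate(long)


def _prediction_rows(lex, form, triple, config, assignment, phase, condition, item):
    traj = error_trajectory(lex, form, config)
    rows = []
    for pos in range(1, len(form) + 1):
        pred = traj.per_position_prediction[pos - 1]
        base = {
            "signal": None,
            "assignment": assignment,
            "item": item,
            "condition": condition,
            "phase": phase,
            "rel": pos - triple.dp,
        }
        rows.append(
            {**base, "signal": "prediction_error",
             "value": float(traj.per_position_error[pos - 1])}
        )
        rows.append(
            {**base, "signal": "prob_observed", "value": pred.prob(form[pos - 1])}
        )
    return rows


def _iam_rows(network, form, triple, params, assignment, phase, condition, item):
    trace = iam.simulate(network, form, params)
    onset = iam.input_onset_cycle(triple.dp + 1, params)
    tc = iam.phoneme_timecourse(trace, form[triple.dp], triple.dp + 1, form, params)
    rows = []
    for c in range(params.n_cycles):
        base = {
            "assignment": assignment,
            "item": item,
            "condition": condition,
            "phase": phase,
            "rel": c - onset,
        }
        rows.append({**base, "signal": "total_feedback",
                     "value": float(trace.total_feedback[c])})
        rows.append({**base, "signal": "total_word_act",
                     "value": float(trace.total_word_act[c])})
        rows.append({**base, "signal": "total_phoneme_act",
                     "value": float(trace.total_phoneme_act[c])})
        rows.append({**base, "signal": "phoneme_activation", "value": float(tc[c])})
    return rows


@dataclass(frozen=True)
class FindingsReport:
    """Boolean findings for one signal plus the compared cell means."""

    signal_name: str
    finding1: bool
    finding2: bool
    finding3: bool
    details: dict
    metadata: dict

    @property
    def all_pass(self) -> bool:
        return self.finding1 and self.finding2 and self.finding3

    def to_dict(self) -> dict:
        return {
            "signal": self.signal_name,
            "finding1": self.finding1,
            "finding2": self.finding2,
            "finding3": self.finding3,
            "details": self.details,
            "metadata": self.metadata,
        }


def _rel_diff(a: float, b: float) -> float:
    denom = max(abs(a), abs(b), 1e-12)
    return abs(a - b) / denom


def check_findings(
    res: AlignedResult,
    post_dp_window: Window,
    pre_dp_window: Window,
    tol: float = 0.10,
) -> FindingsReport:
    """Evaluate the three findings predicates on one aligned signal.

    The "approximately equal" comparisons use relative difference below
    ``tol``.  Raises ``KeyError`` if a required condition x phase cell is
    missing from the result.
    """
    o = SIGNAL_ORIENTATION[res.signal_name]
    direction = FINDING3_DIRECTION[res.signal_name]

    post = {
        (cond, phase): res.window_mean(phase, post_dp_window, cond)
        for cond in CONDITIONS
        for phase in PHASES
    }
    f1 = (
        o * (post[("novel", "pre")] - post[("source", "pre")]) > 0
        and o * (post[("baseline", "pre")] - post[("source", "pre")]) > 0
        and _rel_diff(post[("novel", "pre")], post[("baseline", "pre")]) <= tol
    )
    f2 = (
        o * (post[("baseline", "post")] - post[("source", "post")]) > 0
        and o * (post[("baseline", "post")] - post[("novel", "post")]) > 0
        and _rel_diff(post[("source", "post")], post[("novel", "post")]) <= tol
    )
    pre_dp = {phase: res.window_mean(phase, pre_dp_window) for phase in PHASES}
    if direction == "decrease":
        f3 = pre_dp["post"] < pre_dp["pre"]
    elif direction == "increase":
        f3 = pre_dp["post"] > pre_dp["pre"]
    else:
        f3 = _rel_diff(pre_dp["post"], pre_dp["pre"]) <= tol

    details = {
        "post_dp": {f"{c}_{p}": post[(c, p)] for c in CONDITIONS for p in PHASES},
        "pre_dp": dict(pre_dp),
    }
    metadata = {
        "signal": res.signal_name,
        "post_dp_window": list(post_dp_window),
        "pre_dp_window": list(pre_dp_window),
        "tolerance": tol,
        "orientation": o,
        "finding3_direction": direction,
    }
    return FindingsReport(res.signal_name, bool(f1), bool(f2), bool(f3),
                          details, metadata)


def export_report(
    results: dict[str, AlignedResult],
    findings: Sequence[FindingsReport],
    out_dir: str | Path,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write tidy cell CSVs, a findings summary JSON and DP-aligned plots.

    The CSV has one row per signal x condition x phase x DP-relative
    position; plots mark the deviation point with a dashed vertical line
    between relative positions 0 and 1.  Output is deterministic for fixed
    inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames = []
    for name in sorted(results):
        c = results[name].cells.copy()
        c.insert(0, "signal", name)
        frames.append(c)
    cells = pd.concat(frames, ignore_index=True)
    paths["cells"] = out / "aligned_cells.csv"
    cells.to_csv(paths["cells"], index=False, lineterminator="\n")

    paths["findings"] = out / "findings.json"
    with paths["findings"].open("w", encoding="utf-8") as fh:
        json.dump([f.to_dict() for f in findings], fh, indent=2, sort_keys=True)
        fh.write("\n")

    if make_plots:
        for name in sorted(results):
            paths[f"fig_{name}"] = _plot_signal(results[name], out / f"fig_{name}.png")
    return paths


def _plot_signal(res: AlignedResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, phase in zip(axes, PHASES):
        for condition in CONDITIONS:
            df = res.cells[
                (res.cells.condition == condition) & (res.cells.phase == phase)
            ].sort_values("rel")
            ax.plot(df.rel, df["mean"], marker=".", label=condition)
        # positional signals have the DP between rel 0 and 1; cycle-aligned
        # signals onset the DP phoneme at rel 0
        dp_x = 0.5 if res.signal_name in PREDICTION_SIGNALS else 0.0
        ax.axvline(dp_x, linestyle="--", color="k", linewidth=1)
        ax.set_title(f"{res.signal_name} ({phase})")
        ax.set_xlabel("position relative to DP")
    axes[0].set_ylabel(res.signal_name)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
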