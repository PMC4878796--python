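"""The four in-silico experiment campaigns and their summary statistics.

Each campaign sweeps one scenario knob, runs a seeded ensemble per
setting (default 100 replicates × 100 steps) and summarises the total
β-catenin observable per step:

* :func:`wnt_sweep` — WNT stimulation, initial WNT 0..5, feedback off;
* :func:`gsk3_sweep` — GSK3 inhibition, initial GSK3 5..0;
* :func:`apc_mutation_scan` — APC-inactivating mutations, DC production
  weight 0.2 / 0.1 / 0.05 / 0;
* :func:`axin2_feedback_sweep` — WNT stimulation with AXIN2 negative
  feedback, t11→AXIN weight 0 … 0.15.

Every cell seed is derived deterministically from the campaign base
seed, and cells of the feedback sweep reuse the seeds of the plain WNT
sweep at the same WNT level, so the weight-0 column of the feedback
sweep is trace-identical to the WNT sweep under the same base seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from .core import as_weight
from .engine import EnsembleSummary, run_ensemble
from .wnt import WntScenario, build_wnt_net, total_beta_catenin

__all__ = [
    "SweepResult",
    "wnt_sweep",
    "gsk3_sweep",
    "apc_mutation_scan",
    "axin2_feedback_sweep",
    "degradation_rate",
    "FLAT_RESPONSE_THRESHOLD",
]

#: Ensemble-mean endpoint (tokens at the final step) below which a
#: response curve is called "flat".  Qualitative classification knob,
#: kept here rather than hard-coded at use sites.
FLAT_RESPONSE_THRESHOLD: float = 10.0


@dataclass
class SweepResult:
    """Ensemble summaries of total β-catenin across one parameter axis."""

    parameter: str
    values: tuple
    summaries: dict
    steps: int
    replicates: int
    base_seed: int

    def endpoint_means(self) -> dict:
        """Ensemble-mean total β-catenin at the final step, per cell."""
        return {k: float(s.mean[-1]) for k, s in self.summaries.items()}

    def to_frame(self):
        """Tidy table: parameter, value, step, mean, sd."""
        import pandas as pd

        frames = []
        for value, summary in self.summaries.items():
            frame = summary.to_frame()
            frame.insert(0, "value", [str(value)] * len(frame))
            frame.insert(0, "parameter", self.parameter)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def plot(self, path=None, title: str | None = None):
        """Mean ± SD band per cell; written to ``path`` if given."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for value, s in self.summaries.items():
            ax.plot(s.steps, s.mean, label=f"{self.parameter}={value}")
            ax.fill_between(s.steps, s.mean - s.sd, s.mean + s.sd, alpha=0.2)
        ax.set_xlabel("simulation step")
        ax.set_ylabel("total β-catenin tokens (mean ± SD)")
        ax.set_title(title or self.parameter)
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _cell(scenario: WntScenario, steps: int, replicates: int, seed: int) -> EnsembleSummary:
    net = build_wnt_net(scenario)
    return run_ensemble(
        net, steps, replicates, seed, total_beta_catenin, "total_beta_catenin"
    )


def _wnt_cell_seed(base_seed: int, wnt: int) -> int:
    # shared by wnt_sweep and axin2_feedback_sweep so that the feedback
    # sweep's weight-0 column replays the exact same traces
    return int(base_seed) + 101 * int(wnt)


def wnt_sweep(
    levels: Iterable[int] = range(6),
    steps: int = 100,
    replicates: int = 100,
    seed: int = 0,
) -> SweepResult:
    """WNT stimulation: initial WNT 0..5, GSK3 5, AXIN2 feedback off."""
    levels = tuple(levels)
    summaries = {
        wnt: _cell(
            WntScenario(initial_wnt=wnt, initial_gsk3=5, axin2_feedback_weight=0),
            steps, replicates, _wnt_cell_seed(seed, wnt),
        )
        for wnt in levels
    }
    return SweepResult("initial_wnt", levels, summaries, steps, replicates, seed)


def gsk3_sweep(
    levels: Iterable[int] = range(5, -1, -1),
    steps: int = 100,
    replicates: int = 100,
    seed: int = 0,
) -> SweepResult:
    """GSK3 inhibition: initial GSK3 5 (wildtype) down to 0 (complete)."""
    levels = tuple(levels)
    summaries = {
        gsk3: _cell(
            WntScenario(initial_wnt=0, initial_gsk3=gsk3, axin2_feedback_weight=0),
            steps, replicates, int(seed) + 211 * int(gsk3),
        )
        for gsk3 in levels
    }
    return SweepResult("initial_gsk3", levels, summaries, steps, replicates, seed)


def apc_mutation_scan(
    weights: Sequence = (0.2, 0.1, 0.05, 0),
    steps: int = 100,
    replicates: int = 100,
    seed: int = 0,
) -> SweepResult:
    """APC mutations: DC production once per 5/10/20 steps, or never."""
    weights = tuple(as_weight(w) for w in weights)
    summaries = {
        w: _cell(
            WntScenario(initial_wnt=0, initial_gsk3=5, apc_dc_production_weight=w),
            steps, replicates, int(seed) + 307 * i,
        )
        for i, w in enumerate(weights)
    }
    return SweepResult("apc_dc_production_weight", weights, summaries, steps, replicates, seed)


def axin2_feedback_sweep(
    wnt_levels: Sequence[int] = (3, 4, 5),
    feedback_weights: Sequence = (0, 0.05, 0.10, 0.15),
    steps: int = 100,
    replicates: int = 100,
    seed: int = 0,
) -> SweepResult:
    """WNT stimulation with AXIN2 feedback, t11→AXIN weight 0 … 0.15.

    Cells are keyed ``(wnt, weight)``.  All feedback weights at one WNT
    level share the same cell seed (paired design), which equals the
    :func:`wnt_sweep` seed for that level.
    """
    wnt_levels = tuple(int(w) for w in wnt_levels)
    feedback_weights = tuple(as_weight(w) for w in feedback_weights)
    summaries = {
        (wnt, fb): _cell(
            WntScenario(initial_wnt=wnt, initial_gsk3=5, axin2_feedback_weight=fb),
            steps, replicates, _wnt_cell_seed(seed, wnt),
        )
        for wnt in wnt_levels
        for fb in feedback_weights
    }
    return SweepResult(
        "(initial_wnt, axin2_feedback_weight)",
        tuple(summaries), summaries, steps, replicates, seed,
    )


def degradation_rate(
    summary: EnsembleSummary, window: tuple[int, int] = (40, 100)
) -> float:
    """β-catenin degradation, in tokens per three steps, from an ensemble.

    β-catenin is produced exactly once per step (the gene-expression
    transition is always enabled), so the cumulative degraded amount at
    step *n* is ``n − mean total β-catenin(n)``.  The rate is three
    times the least-squares slope of that series over a late window
    (default steps 40–100), excluding the initial transient.
    """
    lo, hi = window
    steps = np.asarray(summary.steps)
    if lo < steps[0] or hi > steps[-1] or lo >= hi:
        raise ValueError(f"window {window} outside the simulated range")
    mask = (steps >= lo) & (steps <= hi)
    x = steps[mask]
    degraded = x - np.asarray(summary.mean)[mask]
    slope = np.polyfit(x, degraded, 1)[0]
    return float(3.0 * slope)
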