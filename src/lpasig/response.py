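"""Replicate aggregation, fold-change computation and regulation calling.

The differential rule is a pure fold-change threshold: a probe set is
up-regulated in a cell line when its mean treated/control fluorescence
ratio strictly exceeds 1.3, and down-regulated below the reciprocal
threshold 1/1.3. No moderated statistic is involved; the boolean calls are
what the cross-cell-line attribution consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, ExpressionExperiment

UP_THRESHOLD = 1.3
DOWN_THRESHOLD = 1.0 / 1.3
#: fold-change floor in fluorescence units, applied to both numerator and
#: denominator so background-level probes cannot produce infinite folds
DEFAULT_FLOOR = 1.0


@dataclass
class FoldChangeTable:
    """Per (probe set, cell line) treated/control fold changes.

    ``folds`` has probe sets as rows and cell lines as columns. Probe sets
    with a missing value in any required condition are excluded from
    calling and listed in ``excluded`` — never silently dropped.
    ``floored`` lists probe sets whose control or treated mean fell below
    the floor in at least one line.
    """

    folds: pd.DataFrame
    floor: float
    excluded: list[str] = field(default_factory=list)
    floored: list[str] = field(default_factory=list)


@dataclass
class ResponseCalls:
    """Up/down/unchanged calls per (probe set, cell line)."""

    calls: pd.DataFrame  # values in {"up", "down", "unchanged"}
    up_threshold: float = UP_THRESHOLD
    down_threshold: float = DOWN_THRESHOLD

    def up_in(self, cell_line: str) -> pd.Index:
        col = self.calls[cell_line]
        return col.index[col == "up"]

    def down_in(self, cell_line: str) -> pd.Index:
        col = self.calls[cell_line]
        return col.index[col == "down"]


def aggregate_replicates(exp: ExpressionExperiment) -> pd.DataFrame:
    """Mean fluorescence over replicate arrays.

    Returns a frame with a (cell_line, condition) column MultiIndex. A
    single replicate passes through unchanged; a (line, condition) with no
    replicate columns is an error; NaN replicates propagate as NaN means so
    the affected probe sets can be excluded (and reported) downstream.
    """
    for line in exp.cell_lines:
        for cond in CONDITIONS:
            if exp.replicates(line, cond).shape[1] == 0:
                raise ValueError(f"({line}, {cond}) has zero replicates")
    # skipna=False: a probe set missing any replicate is excluded later,
    # not averaged over fewer arrays
    means = exp.values.T.groupby(level=["cell_line", "condition"]).mean().T
    mask = exp.values.isna().T.groupby(level=["cell_line", "condition"]).any().T
    means = means.mask(mask)
    return means[[(l, c) for l in exp.cell_lines for c in CONDITIONS]]


def compute_fold_changes(aggregated: pd.DataFrame,
                         floor: float = DEFAULT_FLOOR,
                         log2_scale: bool = False) -> FoldChangeTable:
    """Treated/control fold change per probe set and cell line.

    On the linear scale ``fold = max(treated, floor) / max(control, floor)``.
    When the input is log2 fluorescence the fold is un-logged,
    ``fold = 2**(mean_log_treated - mean_log_control)``, and no floor is
    applied (log values are already background-stabilised). Probe sets with
    any NaN mean are excluded and reported.
    """
    if floor <= 0 and not log2_scale:
        raise ValueError("floor must be positive")
    lines = list(dict.fromkeys(aggregated.columns.get_level_values(0)))
    ctrl = aggregated.loc[:, [(l, "control") for l in lines]].to_numpy(float)
    trt = aggregated.loc[:, [(l, "treated") for l in lines]].to_numpy(float)
    incomplete = np.isnan(ctrl).any(axis=1) | np.isnan(trt).any(axis=1)
    excluded = aggregated.index[incomplete].tolist()
    ctrl, trt = ctrl[~incomplete], trt[~incomplete]
    index = aggregated.index[~incomplete]

    if log2_scale:
        folds = np.exp2(trt - ctrl)
        floored: list[str] = []
    else:
        if (ctrl < 0).any() or (trt < 0).any():
            raise ValueError("negative mean fluorescence")
        hit = (ctrl < floor) | (trt < floor)
        floored = index[hit.any(axis=1)].tolist()
        folds = np.maximum(trt, floor) / np.maximum(ctrl, floor)
    table = pd.DataFrame(folds, index=index, columns=lines)
    table.columns.name = "cell_line"
    return FoldChangeTable(table, floor=floor, excluded=excluded,
                           floored=floored)


def call_regulation(folds: FoldChangeTable,
                    up_threshold: float = UP_THRESHOLD,
                    down_threshold: float = DOWN_THRESHOLD) -> ResponseCalls:
    """Call each (probe set, line) up, down or unchanged.

    Inequalities are strict ("more than" a 1.3-fold increase): a fold of
    exactly 1.3 is unchanged. An implementation using >= would shift the
    per-line counts.
    """
    if not (down_threshold < 1.0 < up_threshold):
        raise ValueError(
            f"thresholds must satisfy down < 1 < up, got "
            f"({down_threshold}, {up_threshold})")
    f = folds.folds
    calls = pd.DataFrame("unchanged", index=f.index, columns=f.columns)
    calls = calls.mask(f > up_threshold, "up").mask(f < down_threshold, "down")
    return ResponseCalls(calls, up_threshold=up_threshold,
                         down_threshold=down_threshold)


def count_regulated(calls: ResponseCalls) -> dict[str, dict]:
    """Per-line counts and identifier lists of up/down probe sets."""
    out: dict[str, dict] = {}
    for line in calls.calls.columns:
        up = calls.up_in(line)
        down = calls.down_in(line)
        out[line] = {
            "n_up": int(len(up)),
            "n_down": int(len(down)),
            "up_probe_sets": up.tolist(),
            "down_probe_sets": down.tolist(),
        }
    return out
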