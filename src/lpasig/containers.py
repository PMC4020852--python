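"""Shared in-memory containers for the attribution pipeline.

The two containers defined here travel through every stage: the replicate
fluorescence matrix of a ligand-stimulation experiment, and the binary
receptor-by-cell-line design matrix that drives attribution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treated")


@dataclass
class ExpressionExperiment:
    """Replicate-level fluorescence values from a stimulation experiment.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe-set identifier; columns are a 3-level
        MultiIndex ``(cell_line, condition, replicate)`` with condition in
        ``{"control", "treated"}``. Values are fluorescence in arbitrary
        linear units (or log2 units when ``log2_scale`` is set); NaN marks
        a missing measurement.
    log2_scale : bool
        True when the stored values are log2-transformed, as some public
        repository deposits are. Fold-change computation un-logs such data.
    metadata : dict
        Free-form provenance (source path, scale detection notes, seed).
    """

    values: pd.DataFrame
    log2_scale: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.columns, pd.MultiIndex) or v.columns.nlevels != 3:
            raise ValueError(
                "expression values need (cell_line, condition, replicate) columns"
            )
        v.columns = v.columns.set_names(["cell_line", "condition", "replicate"])
        v.index.name = "probe_set"
        if v.shape[0] == 0:
            raise ValueError("expression matrix has no data rows")
        dup = v.index[v.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate probe-set identifiers: {dup}")
        bad_cond = set(v.columns.get_level_values("condition")) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}; "
                             f"expected {CONDITIONS}")
        if not self.log2_scale:
            arr = v.to_numpy(dtype=float)
            if np.nanmin(arr) < 0:
                raise ValueError("negative fluorescence on linear scale")
        present = {(l, c) for l, c, _ in v.columns}
        for line in self.cell_lines:
            for cond in CONDITIONS:
                if (line, cond) not in present:
                    raise ValueError(f"cell line {line!r} lacks {cond} arrays")

    @property
    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for line in self.values.columns.get_level_values("cell_line"):
            seen.setdefault(line, None)
        return list(seen)

    @property
    def probe_sets(self) -> pd.Index:
        return self.values.index

    def replicates(self, cell_line: str, condition: str) -> pd.DataFrame:
        """All replicate columns for one (cell line, condition)."""
        cols = [c for c in self.values.columns
                if c[0] == cell_line and c[1] == condition]
        return self.values[cols]


@dataclass
class ReceptorDesign:
    """Binary receptor presence across cell lines.

    ``presence`` is a boolean DataFrame, receptors as rows and cell lines
    as columns. Receptors sharing an identical presence pattern are
    mutually confounded and recorded in ``confounded_pairs``.
    """

    presence: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.presence
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("design needs at least one receptor and one cell line")
        if p.index.duplicated().any() or p.columns.duplicated().any():
            raise ValueError("duplicate receptor or cell-line names in design")
        vals = p.to_numpy()
        if not np.isin(vals, [0, 1, True, False]).all():
            raise ValueError("design entries must be binary")
        self.presence = p.astype(bool)
        self.presence.index.name = "receptor"
        self.presence.columns.name = "cell_line"

    @property
    def receptors(self) -> list[str]:
        return list(self.presence.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.presence.columns)

    def positive_lines(self, receptor: str) -> list[str]:
        row = self._row(receptor)
        return [c for c in self.presence.columns if row[c]]

    def negative_lines(self, receptor: str) -> list[str]:
        row = self._row(receptor)
        return [c for c in self.presence.columns if not row[c]]

    @property
    def confounded_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        recs = self.receptors
        for i, r in enumerate(recs):
            for s in recs[i + 1:]:
                if self.presence.loc[r].equals(self.presence.loc[s]):
                    pairs.append((r, s))
        return pairs

    def _row(self, receptor: str) -> pd.Series:
        if receptor not in self.presence.index:
            raise KeyError(f"receptor {receptor!r} not in design "
                           f"(have {self.receptors})")
        return self.presence.loc[receptor]


def paper_design() -> ReceptorDesign:
    """The three-line, four-receptor LPA design used throughout the tests.

    PC3 expresses LPA1/2/3/6, MDA-MB-231 expresses LPA1/2 and MCF-7
    expresses LPA2/6, so LPA1 is the only receptor shared by PC3 and
    MDA-MB-231 and absent from MCF-7.
    """
    presence = pd.DataFrame(
        {
            "PC3": [True, True, True, True],
            "MDA-MB-231": [True, True, False, False],
            "MCF-7": [False, True, False, True],
        },
        index=["LPA1", "LPA2", "LPA3", "LPA6"],
    )
    return ReceptorDesign(presence)
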