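"""Receptor-specific attribution of ligand-response genes by set logic.

A probe set is attributed to a receptor when it is called up-regulated in
*every* cell line expressing that receptor and not up-regulated in *every*
line lacking it. With cell lines drawn from unrelated cancers, genes that
respond in all receptor-positive lines but no receptor-negative line are
unlikely to be cell-type-specific, so the intersection isolates genes
downstream of that one receptor.

Whether the design permits this at all is an identifiability question:
a receptor needs enough positive lines (default 2, to exclude cell-type
effects), at least one negative line (to exclude ubiquitous responses),
and a presence pattern not shared with another receptor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ReceptorDesign
from .response import ResponseCalls

MIN_POSITIVE_DEFAULT = 2
MIN_NEGATIVE_DEFAULT = 1

IDENTIFIABLE = "identifiable"
NO_NEGATIVE_LINE = "no_negative_line"
INSUFFICIENT_POSITIVE = "insufficient_positive_lines"


@dataclass
class ReceptorStatus:
    receptor: str
    n_positive_lines: int
    n_negative_lines: int
    status: str  # identifiable | no_negative_line | insufficient_positive_lines | confounded_with:<r>

    @property
    def identifiable(self) -> bool:
        return self.status == IDENTIFIABLE


@dataclass
class IdentifiabilityReport:
    per_receptor: dict[str, ReceptorStatus]
    min_positive: int
    min_negative: int

    def __getitem__(self, receptor: str) -> ReceptorStatus:
        return self.per_receptor[receptor]

    def identifiable_receptors(self) -> list[str]:
        return [r for r, s in self.per_receptor.items() if s.identifiable]


@dataclass
class AttributionResult:
    """Probe sets (and, after gene collapse, distinct genes) attributed
    to one receptor, together with the line sets the logic used."""

    receptor: str
    positive_lines: list[str]
    negative_lines: list[str]
    probe_sets: frozenset[str]
    genes: frozenset[str] | None = None
    n_unannotated: int = 0
    direction: str = "up"
    thresholds: dict = field(default_factory=dict)

    @property
    def n_probe_sets(self) -> int:
        return len(self.probe_sets)

    @property
    def n_genes(self) -> int | None:
        return None if self.genes is None else len(self.genes)


def derive_receptor_profile(receptor_fluorescence: pd.DataFrame,
                            presence_threshold: float | pd.Series | None = None,
                            background: pd.DataFrame | None = None,
                            ) -> ReceptorDesign:
    """Threshold receptor probe fluorescence into a binary design matrix.

    Parameters
    ----------
    receptor_fluorescence : DataFrame
        One fluorescence value (replicate mean) per receptor (rows) and
        cell line (columns). NaN entries are an error.
    presence_threshold : float or per-line Series, optional
        A receptor is called present in a line when its fluorescence
        strictly exceeds the line's threshold. When omitted, the threshold
        defaults to 3x the 10th percentile of that line's full probe
        fluorescence distribution, which requires ``background``.
    background : DataFrame, optional
        Probe x cell-line fluorescence used for the percentile default.
    """
    f = receptor_fluorescence
    if f.isna().any().any():
        missing = [(r, c) for r in f.index for c in f.columns
                   if pd.isna(f.loc[r, c])]
        raise ValueError(f"missing receptor probe values: {missing}")
    if presence_threshold is None:
        if background is None:
            raise ValueError(
                "supply presence_threshold or a background matrix for the "
                "percentile-based default")
        thresholds = 3.0 * background[f.columns].quantile(0.10)
    elif np.isscalar(presence_threshold):
        thresholds = pd.Series(float(presence_threshold), index=f.columns)
    else:
        thresholds = pd.Series(presence_threshold).reindex(f.columns)
        if thresholds.isna().any():
            raise ValueError("per-line thresholds missing for some lines")
    presence = f.gt(thresholds, axis=1)
    return ReceptorDesign(presence,
                          metadata={"presence_threshold": thresholds.to_dict()})


def check_identifiability(design: ReceptorDesign,
                          min_positive: int = MIN_POSITIVE_DEFAULT,
                          min_negative: int = MIN_NEGATIVE_DEFAULT,
                          ) -> IdentifiabilityReport:
    """Classify each receptor of the design.

    A receptor is identifiable iff it has at least ``min_positive``
    positive lines, at least ``min_negative`` negative lines, and a
    presence pattern unique among the receptors. Failure statuses are
    reported in that precedence: no negative line, then too few positive
    lines, then confounding.
    """
    confounded: dict[str, str] = {}
    for a, b in design.confounded_pairs:
        confounded.setdefault(a, b)
        confounded.setdefault(b, a)
    report: dict[str, ReceptorStatus] = {}
    for r in design.receptors:
        n_pos = len(design.positive_lines(r))
        n_neg = len(design.negative_lines(r))
        if n_neg < min_negative:
            status = NO_NEGATIVE_LINE
        elif n_pos < min_positive:
            status = INSUFFICIENT_POSITIVE
        elif r in confounded:
            status = f"confounded_with:{confounded[r]}"
        else:
            status = IDENTIFIABLE
        report[r] = ReceptorStatus(r, n_pos, n_neg, status)
    return IdentifiabilityReport(report, min_positive, min_negative)


def attribute(calls: ResponseCalls, design: ReceptorDesign, receptor: str,
              force: bool = False, strict_negative: bool = False,
              direction: str = "up",
              min_positive: int = MIN_POSITIVE_DEFAULT,
              min_negative: int = MIN_NEGATIVE_DEFAULT) -> AttributionResult:
    """Attribute regulated probe sets to one receptor.

    A probe set is attributed iff its call equals ``direction`` in every
    receptor-positive line and differs from ``direction`` in every
    receptor-negative line. By default the negative-line condition is
    "not up" (unchanged or down); ``strict_negative`` additionally
    rejects probe sets that move in the opposite direction there.

    ``direction="down"`` runs the mirror analysis on down calls.
    A non-identifiable receptor raises unless ``force`` is given, in which
    case a warning records that the attribution is not receptor-specific.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if receptor not in design.receptors:
        raise KeyError(f"receptor {receptor!r} not in design")
    status = check_identifiability(design, min_positive, min_negative)[receptor]
    if not status.identifiable:
        if not force:
            raise ValueError(
                f"receptor {receptor!r} is not identifiable "
                f"({status.status}); pass force=True to attribute anyway")
        warnings.warn(
            f"attributing to non-identifiable receptor {receptor!r} "
            f"({status.status}); the result is not receptor-specific",
            stacklevel=2)

    pos = design.positive_lines(receptor)
    neg = design.negative_lines(receptor)
    missing = [l for l in pos + neg if l not in calls.calls.columns]
    if missing:
        raise ValueError(f"cell lines {missing} absent from response calls")

    c = calls.calls
    ok = pd.Series(True, index=c.index)
    for line in pos:
        ok &= c[line] == direction
    for line in neg:
        if strict_negative:
            ok &= c[line] == "unchanged"
        else:
            ok &= c[line] != direction
    return AttributionResult(
        receptor=receptor, positive_lines=pos, negative_lines=neg,
        probe_sets=frozenset(c.index[ok]), direction=direction,
        thresholds={"up_threshold": calls.up_threshold,
                    "down_threshold": calls.down_threshold,
                    "strict_negative": strict_negative})


def collapse_to_genes(result: AttributionResult,
                      annotation: dict[str, str]) -> AttributionResult:
    """Collapse attributed probe sets to distinct gene symbols.

    Probe sets without an annotation entry are never silently dropped:
    they are counted in ``n_unannotated`` and remain in ``probe_sets``.
    """
    genes = frozenset(annotation[ps] for ps in result.probe_sets
                      if ps in annotation)
    n_unannotated = sum(1 for ps in result.probe_sets if ps not in annotation)
    return AttributionResult(
        receptor=result.receptor, positive_lines=result.positive_lines,
        negative_lines=result.negative_lines, probe_sets=result.probe_sets,
        genes=genes, n_unannotated=n_unannotated, direction=result.direction,
        thresholds=result.thresholds)
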