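"""End-to-end composition of the attribution stages."""
from __future__ import annotations

from .attribution import AttributionResult, attribute, collapse_to_genes
from .containers import ExpressionExperiment, ReceptorDesign
from .response import (DEFAULT_FLOOR, DOWN_THRESHOLD, UP_THRESHOLD,
                       aggregate_replicates, call_regulation,
                       compute_fold_changes, count_regulated)


def run_attribution_pipeline(exp: ExpressionExperiment,
                             design: ReceptorDesign,
                             receptor: str,
                             annotation: dict[str, str] | None = None,
                             up_threshold: float = UP_THRESHOLD,
                             down_threshold: float = DOWN_THRESHOLD,
                             floor: float = DEFAULT_FLOOR,
                             force: bool = False,
                             strict_negative: bool = False,
                             ) -> tuple[AttributionResult, dict]:
    """Replicate means -> fold changes -> calls -> receptor attribution.

    Returns the (gene-collapsed, when an annotation is given) attribution
    result together with the per-line up/down counts. This is the single
    call a user needs to go from a raw replicate table to a receptor
    signature.
    """
    aggregated = aggregate_replicates(exp)
    folds = compute_fold_changes(aggregated, floor=floor,
                                 log2_scale=exp.log2_scale)
    calls = call_regulation(folds, up_threshold=up_threshold,
                            down_threshold=down_threshold)
    counts = count_regulated(calls)
    result = attribute(calls, design, receptor, force=force,
                       strict_negative=strict_negative)
    if annotation is not None:
        result = collapse_to_genes(result, annotation)
    return result, counts
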