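"""End-to-end screen analysis: counts in, interaction scores out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counting import CountMatrix
from .library import LibraryDesign
from .model import ModelFit, ScoreParams, fit_interaction_model, score_gene_pairs
from .normalize import (
    call_essential_guides,
    compute_lfc,
    estimate_size_factors,
    filter_min_t0,
    reference_elements,
    substitute_mismatch_variants,
    EssentialCalls,
    DEFAULT_MIN_T0,
    DEFAULT_PSEUDO,
    ESSENTIAL_LFC_THRESHOLD,
)


@dataclass
class ScreenResult:
    size_factors: pd.Series
    lfc: pd.DataFrame
    essential_calls: EssentialCalls
    fit: ModelFit
    scores: pd.DataFrame


def analyze_screen(
    cm: CountMatrix,
    design: LibraryDesign,
    pseudo: float = DEFAULT_PSEUDO,
    min_t0: int = DEFAULT_MIN_T0,
    essential_threshold: float = ESSENTIAL_LFC_THRESHOLD,
    score_params: ScoreParams = ScoreParams(),
    reference_mode: str = "nt_nt",
    seed: int = 0,
) -> ScreenResult:
    """Run the standard analysis chain on a counted screen.

    Size factors from NT-anchored median-of-ratios, T0 read filter, LFC
    with pseudo-count, essential-guide calling, mismatch-variant
    substitution, model fit, and interaction scoring.
    """
    factors = estimate_size_factors(cm, reference_elements(design, reference_mode))
    filtered = filter_min_t0(cm, min_reads=min_t0)
    lfc = compute_lfc(filtered, factors, pseudo=pseudo)
    calls = call_essential_guides(lfc, design, threshold=essential_threshold)
    lfc_sub = substitute_mismatch_variants(lfc, calls, design)
    fit = fit_interaction_model(lfc_sub, design, seed=seed)
    scores = score_gene_pairs(fit, score_params)
    return ScreenResult(
        size_factors=factors,
        lfc=lfc_sub,
        essential_calls=calls,
        fit=fit,
        scores=scores,
    )
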