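"""Count normalization, log fold changes, and essential-guide handling.

Size factors follow the median-of-ratios scheme anchored on the
non-targeting control constructs: for each reference element the
geometric mean across samples forms a pseudo-reference profile, and a
sample's factor is the median of its counts' ratios to that profile.
Factors are therefore close to 1 and normalized counts stay on the raw
count scale, which is what gives the fixed pseudo-count of 10 its
meaning (it stabilizes LFCs exactly where counts are comparable to 10).
The cost of that convention is that a *global* rescaling of every
sample leaves the factors unchanged, so LFCs of low-count elements are
not exactly invariant to overall sequencing depth — the pseudo-count
deliberately shrinks them depth-dependently.

LFC per element and replicate is
``log2((n_T14 + p) / (n_T0 + p))`` with normalized counts
``n = count / factor`` and pseudo-count ``p = 10``; normalization is
applied here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .library import LibraryDesign

DEFAULT_PSEUDO = 10.0
DEFAULT_MIN_T0 = 50
ESSENTIAL_LFC_THRESHOLD = -3.0


def reference_elements(design: LibraryDesign, mode: str = "nt_nt") -> list[str]:
    """Element ids anchoring the size-factor estimate.

    ``nt_nt`` (default): the 225 NT x NT constructs, the purest null
    set. ``any_nt``: every element containing at least one NT guide.
    """
    if mode == "nt_nt":
        return [e.element_id for e in design.elements if e.pair_class == "nt_nt"]
    if mode == "any_nt":
        return [
            e.element_id
            for e in design.elements
            if e.pair_class in ("nt_nt", "targeting_nt")
        ]
    raise ValueError(f"unknown reference mode {mode!r}")


def estimate_size_factors(cm: CountMatrix, reference: list[str]) -> pd.Series:
    """Median-of-ratios size factors over a reference element set.

    Only reference elements with strictly positive counts in every
    sample enter the estimate (the geometric mean is undefined
    otherwise).
    """
    ref = [r for r in reference if r in cm.counts.index]
    if not ref:
        raise ValueError("no reference elements present in count matrix")
    sub = cm.counts.loc[ref].astype(float)
    pos = sub[(sub > 0).all(axis=1)]
    if pos.empty:
        raise ValueError(
            "no reference element has positive counts in all samples; "
            "cannot estimate size factors"
        )
    logs = np.log(pos.values)
    log_geomean_row = logs.mean(axis=1)  # pseudo-reference, per element
    ratios = np.exp(logs - log_geomean_row[:, None])
    median_ratio = np.median(ratios, axis=0)
    factors = pd.Series(median_ratio, index=cm.counts.columns, name="size_factor")
    if (factors <= 0).any():
        raise ValueError("non-positive size factor estimated")
    return factors


def filter_min_t0(cm: CountMatrix, min_reads: int = DEFAULT_MIN_T0) -> CountMatrix:
    """Keep elements with raw T0 counts >= ``min_reads`` in every replicate."""
    t0_cols = []
    for rep in cm.replicates:
        t0_cols.append(cm.sample_for(rep, "T0"))  # raises if a replicate lacks T0
    keep = (cm.counts[t0_cols] >= min_reads).all(axis=1)
    out = CountMatrix(
        counts=cm.counts.loc[keep].copy(),
        samples=cm.samples.copy(),
        meta=dict(cm.meta),
    )
    out.meta["t0_filter"] = {
        "min_reads": int(min_reads),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    return out


def compute_lfc(
    cm: CountMatrix,
    factors: pd.Series,
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Per-element, per-replicate log2 fold change T14 vs T0.

    Raw counts go in; the size factors are applied here and nowhere
    else, so normalization happens exactly once.
    """
    missing = set(cm.counts.columns) - set(factors.index)
    if missing:
        raise ValueError(f"no size factor for samples: {sorted(missing)}")
    cols = {}
    for rep in cm.replicates:
        s0 = cm.sample_for(rep, "T0")
        s14 = cm.sample_for(rep, "T14")
        n0 = cm.counts[s0] / factors[s0]
        n14 = cm.counts[s14] / factors[s14]
        cols[rep] = np.log2((n14 + pseudo) / (n0 + pseudo))
    lfc = pd.DataFrame(cols)
    lfc.index.name = "element_id"
    if not np.isfinite(lfc.values).all():
        raise ValueError("non-finite LFC produced (check pseudo-count and factors)")
    lfc.attrs["pseudo"] = pseudo
    lfc.attrs["t0_filter"] = cm.meta.get("t0_filter")
    return lfc


@dataclass
class EssentialCalls:
    """Per-guide essentiality from NT-partner depletion."""

    table: pd.DataFrame  # index guide_id; columns mean_nt_lfc, essential
    threshold: float

    @property
    def essential_guides(self) -> set[str]:
        return set(self.table.index[self.table["essential"]])


def call_essential_guides(
    lfc: pd.DataFrame,
    design: LibraryDesign,
    threshold: float = ESSENTIAL_LFC_THRESHOLD,
) -> EssentialCalls:
    """Flag guides whose mean NT-partner LFC is below ``threshold`` (strict).

    A guide's single-knockdown phenotype is read out from its elements
    where the partner is a non-targeting control, averaged over those
    elements and replicates.
    """
    nt_elements: dict[str, list[str]] = {}
    for e in design.elements:
        if e.pair_class != "targeting_nt":
            continue
        gid = e.guide_a if e.gene_b == "NT" else e.guide_b
        nt_elements.setdefault(gid, []).append(e.element_id)

    rows = []
    for g in sorted(g.guide_id for g in design.targeting_guides()):
        eids = [i for i in nt_elements.get(g, []) if i in lfc.index]
        if not eids:
            warnings.warn(
                f"guide {g}: no NT-partner elements survive filtering; "
                "excluded from essential calls",
                stacklevel=2,
            )
            continue
        mean = float(lfc.loc[eids].values.mean())
        rows.append({"guide_id": g, "mean_nt_lfc": mean, "essential": mean < threshold})
    table = pd.DataFrame(rows).set_index("guide_id") if rows else pd.DataFrame(
        columns=["mean_nt_lfc", "essential"]
    )
    return EssentialCalls(table=table, threshold=threshold)


def substitute_mismatch_variants(
    lfc: pd.DataFrame,
    calls: EssentialCalls,
    design: LibraryDesign,
) -> pd.DataFrame:
    """Replace essential perfect guides by their mismatched variants.

    A perfect guide with a strong single-knockdown phenotype depletes
    its constructs so fast that interaction phenotypes saturate; when
    the library carries a partial-knockdown variant of such a guide,
    every element containing the perfect guide is dropped and the
    variant's elements carry the gene from then on. Essential guides
    without a variant are kept, with a warning.
    """
    variants_of: dict[str, list[str]] = {}
    for g in design.guides.values():
        if g.guide_type == "mismatch":
            variants_of.setdefault(g.parent_guide_id, []).append(g.guide_id)

    drop_guides: set[str] = set()
    for gid in sorted(calls.essential_guides):
        g = design.guides.get(gid)
        if g is None or g.guide_type != "perfect":
            continue
        if variants_of.get(gid):
            drop_guides.add(gid)
        else:
            warnings.warn(
                f"essential guide {gid} has no mismatched variant; kept as is",
                stacklevel=2,
            )
    if not drop_guides:
        return lfc
    drop_elements = {
        e.element_id
        for e in design.elements
        if e.guide_a in drop_guides or e.guide_b in drop_guides
    }
    out = lfc.loc[~lfc.index.isin(drop_elements)].copy()
    out.attrs.update(lfc.attrs)
    out.attrs["substituted_guides"] = sorted(drop_guides)
    return out
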