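"""Combinatorial dual-guide CRISPRi library design.

A dual-guide construct expresses two sgRNAs from a single cassette:
position *a* upstream, position *b* downstream. The library pairs guides
so that every unordered pair of targeted genes is queried in exactly one
(randomly assigned) orientation, every guide is paired with a panel of 15
non-targeting (NT) controls in both orientations, guides within a gene
are paired with each other, and all 15 x 15 NT-NT combinations serve as
negative controls.

Genes with a strong knockout growth phenotype receive, per transcription
start site, their top-ranked guide plus a mismatched variant engineered
for partial knockdown (so that double-knockdown phenotypes of essential
genes stay measurable); all other genes receive their top two guides.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel gene symbol for non-targeting control guides.
NT_GENE = "NT"

# Constant cassette regions flanking the two protospacers in each oligo.
# Case is meaningful to the synthesis vendor and is preserved verbatim.
OLIGO_UPSTREAM = "AACTGCGATCGCTAATGTCCACCTTGTTG"
OLIGO_LINKER = "gtttcagagcgagacgtgcctgcaggatacgtctcagaaacatg"
OLIGO_DOWNSTREAM = "GTTTAAGAGCTAAGCTGGTTCTCCAGTGCCTTATT"
PROTOSPACER_LEN = 20
OLIGO_LEN = (
    len(OLIGO_UPSTREAM) + len(OLIGO_LINKER) + len(OLIGO_DOWNSTREAM) + 2 * PROTOSPACER_LEN
)  # 148

GUIDE_TYPES = ("perfect", "mismatch", "non_targeting")
PAIR_CLASSES = ("inter_gene", "intra_gene", "targeting_nt", "nt_nt")

_DNA = frozenset("ACGT")

# Mismatch-variant selection: empirical relative activity window and target.
ACTIVITY_TARGET = 0.47
ACTIVITY_HALF_WINDOW = 0.15
PREDICTED_TARGET = 0.5
MIN_SPECIFICITY = 0.15


class NoAdmissibleVariantError(LookupError):
    """No mismatched variant passes the specificity/activity rules."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: its 20-nt protospacer plus design annotations."""

    guide_id: str
    gene: str
    protospacer: str
    guide_type: str = "perfect"
    tss_id: str = "P1"
    parent_guide_id: str = ""
    empirical_activity: float | None = None
    predicted_activity: float | None = None
    specificity_score: float | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"guide {self.guide_id}: protospacer must be {PROTOSPACER_LEN} nt, "
                f"got {len(self.protospacer)}"
            )
        if not set(self.protospacer) <= _DNA:
            raise ValueError(f"guide {self.guide_id}: protospacer has non-ACGT characters")
        if self.guide_type not in GUIDE_TYPES:
            raise ValueError(f"guide {self.guide_id}: unknown guide_type {self.guide_type!r}")
        if self.guide_type == "mismatch" and not self.parent_guide_id:
            raise ValueError(f"mismatch guide {self.guide_id} requires parent_guide_id")
        if self.guide_type == "non_targeting" and self.gene != NT_GENE:
            raise ValueError(f"non-targeting guide {self.guide_id} must use gene={NT_GENE!r}")

    @property
    def is_targeting(self) -> bool:
        return self.guide_type != "non_targeting"


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene design metadata: tier and strong-knockout status."""

    gene: str
    tier: int
    strong_ko_phenotype: bool
    tss_ids: tuple[str, ...] = ("P1",)

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError(f"{self.gene}: tier must be 1, 2 or 3")
        if not self.tss_ids:
            raise ValueError(f"{self.gene}: needs at least one TSS")


@dataclass(frozen=True, slots=True)
class LibraryElement:
    """An ordered dual-guide construct (position a, position b)."""

    element_id: str
    guide_a: str
    guide_b: str
    gene_a: str
    gene_b: str
    protospacer_a: str
    protospacer_b: str
    pair_class: str

    @property
    def oligo(self) -> str:
        return (
            OLIGO_UPSTREAM
            + self.protospacer_a
            + OLIGO_LINKER
            + self.protospacer_b
            + OLIGO_DOWNSTREAM
        )


@dataclass
class LibraryDesign:
    """A full dual-guide library: elements plus the guide table behind them."""

    elements: list[LibraryElement]
    guides: dict[str, GuideRecord]
    orientation_seed: int
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stats:
            self.stats = library_stats(self)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements]

    def targeting_guides(self) -> list[GuideRecord]:
        return [g for g in self.guides.values() if g.is_targeting]

    def nt_guides(self) -> list[GuideRecord]:
        return [g for g in self.guides.values() if not g.is_targeting]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element_id": e.element_id,
                "guide_a": e.guide_a,
                "guide_b": e.guide_b,
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "pair_class": e.pair_class,
                "protospacer_a": e.protospacer_a,
                "protospacer_b": e.protospacer_b,
            }
            for e in self.elements
        ]
        return pd.DataFrame(rows)

    def guides_frame(self) -> pd.DataFrame:
        cols = [
            "guide_id", "gene", "protospacer", "guide_type", "tss_id",
            "parent_guide_id", "empirical_activity", "predicted_activity",
            "specificity_score", "rank_score",
        ]
        return pd.DataFrame(
            [{c: getattr(g, c) for c in cols} for g in self.guides.values()]
        )


def assign_tiers(gene_table: pd.DataFrame) -> list[GeneMeta]:
    """Divide genes into design tiers from prior-screen evidence.

    Tier 1: essential for growth in K562 cells. Tier 2: significant hit
    in at least four CRISPRi screens. Tier 3: everything else. The tier
    selects which ranking statistic orders a gene's candidate guides.

    ``gene_table`` needs columns ``gene``, ``essential_in_K562``,
    ``n_screens_hit`` and optionally ``strong_ko_phenotype`` / ``tss_ids``
    (comma-separated or list).
    """
    required = ("essential_in_K562", "n_screens_hit")
    metas: list[GeneMeta] = []
    for row in gene_table.to_dict("records"):
        gene = row.get("gene")
        for col in required:
            if col not in row or pd.isna(row[col]):
                raise ValueError(f"gene {gene!r}: missing flag {col!r}")
        if bool(row["essential_in_K562"]):
            tier = 1
        elif int(row["n_screens_hit"]) >= 4:
            tier = 2
        else:
            tier = 3
        tss = row.get("tss_ids", "P1")
        if isinstance(tss, str):
            tss = tuple(t.strip() for t in tss.split(",") if t.strip())
        else:
            tss = tuple(tss)
        metas.append(
            GeneMeta(
                gene=gene,
                tier=tier,
                strong_ko_phenotype=bool(row.get("strong_ko_phenotype", False)),
                tss_ids=tss or ("P1",),
            )
        )
    return metas


def rank_guides(tier: int, candidates: list[GuideRecord]) -> list[GuideRecord]:
    """Order a gene's candidate guides, strongest first.

    Tiers 1 and 2 rank by growth phenotype (more negative = stronger
    depletion = better), tier 3 by an activity regression score (higher =
    better). Ties break on guide_id so the order is a deterministic total
    order.
    """
    if not candidates:
        raise ValueError("rank_guides: empty candidate list")
    genes = {c.gene for c in candidates}
    if len(genes) > 1:
        raise ValueError(f"rank_guides: candidates span multiple genes {sorted(genes)}")
    for c in candidates:
        if c.rank_score is None:
            raise ValueError(f"guide {c.guide_id}: rank_score missing")
    if tier in (1, 2):
        key = lambda g: (g.rank_score, g.guide_id)  # most negative first
    elif tier == 3:
        key = lambda g: (-g.rank_score, g.guide_id)  # highest score first
    else:
        raise ValueError(f"unknown tier {tier}")
    return sorted(candidates, key=key)


def select_mismatch_variant(
    parent: GuideRecord, variants: list[GuideRecord]
) -> GuideRecord:
    """Pick the partial-knockdown variant of a top guide.

    Variants with on-target specificity below 0.15 are excluded. Among
    the rest, prefer a variant whose measured relative activity lies in
    0.47 +/- 0.15, taking the one nearest 0.47; lacking any such
    measurement, fall back to the variant with predicted activity
    nearest 0.5. Ties break on guide_id.
    """
    for v in variants:
        if v.parent_guide_id != parent.guide_id:
            raise ValueError(
                f"variant {v.guide_id} does not derive from {parent.guide_id}"
            )
    ok = [
        v
        for v in variants
        if v.specificity_score is not None and v.specificity_score >= MIN_SPECIFICITY
    ]
    if not ok:
        raise NoAdmissibleVariantError(
            f"no admissible mismatched variant for guide {parent.guide_id}"
        )
    lo = ACTIVITY_TARGET - ACTIVITY_HALF_WINDOW
    hi = ACTIVITY_TARGET + ACTIVITY_HALF_WINDOW
    empirical = [
        v
        for v in ok
        if v.empirical_activity is not None and lo <= v.empirical_activity <= hi
    ]
    if empirical:
        return min(
            empirical,
            key=lambda v: (abs(v.empirical_activity - ACTIVITY_TARGET), v.guide_id),
        )
    predicted = [v for v in ok if v.predicted_activity is not None]
    if not predicted:
        raise NoAdmissibleVariantError(
            f"no variant of {parent.guide_id} with usable activity annotation"
        )
    return min(
        predicted,
        key=lambda v: (abs(v.predicted_activity - PREDICTED_TARGET), v.guide_id),
    )


def select_gene_guides(
    meta: GeneMeta,
    ranked: dict[str, list[GuideRecord]],
    variants: dict[str, list[GuideRecord]] | None = None,
) -> list[GuideRecord]:
    """Choose the library guides for one gene, per transcription start site.

    Strong-knockout genes get their top guide plus its mismatched variant
    (falling back to the top two perfect guides if no admissible variant
    exists); other genes get their top two perfect guides.
    """
    variants = variants or {}
    chosen: list[GuideRecord] = []
    for tss in meta.tss_ids:
        lst = ranked.get(tss)
        if not lst:
            raise ValueError(f"gene {meta.gene}: no ranked guides for TSS {tss!r}")
        top = lst[0]
        if meta.strong_ko_phenotype:
            try:
                var = select_mismatch_variant(top, variants.get(top.guide_id, []))
                chosen.extend([top, var])
                continue
            except NoAdmissibleVariantError:
                warnings.warn(
                    f"gene {meta.gene} TSS {tss}: no admissible mismatched variant; "
                    "falling back to top two perfect guides",
                    stacklevel=2,
                )
        if len(lst) < 2:
            raise ValueError(
                f"gene {meta.gene}: TSS {tss!r} has fewer than two candidate guides"
            )
        chosen.extend(lst[:2])
    return chosen


def classify_pair(guide_a: GuideRecord, guide_b: GuideRecord) -> str:
    if not guide_a.is_targeting and not guide_b.is_targeting:
        return "nt_nt"
    if not guide_a.is_targeting or not guide_b.is_targeting:
        return "targeting_nt"
    return "intra_gene" if guide_a.gene == guide_b.gene else "inter_gene"


def _element(guide_a: GuideRecord, guide_b: GuideRecord) -> LibraryElement:
    return LibraryElement(
        element_id=f"{guide_a.guide_id}:{guide_b.guide_id}",
        guide_a=guide_a.guide_id,
        guide_b=guide_b.guide_id,
        gene_a=guide_a.gene,
        gene_b=guide_b.gene,
        protospacer_a=guide_a.protospacer,
        protospacer_b=guide_b.protospacer,
        pair_class=classify_pair(guide_a, guide_b),
    )


def build_pair_set(
    guides: list[GuideRecord],
    nt_guides: list[GuideRecord],
    orientation_seed: int = 0,
) -> LibraryDesign:
    """Assemble the full dual-guide element set from selected guides.

    Every unordered gene pair is realized in one orientation drawn from a
    seeded RNG (gene pairs visited in lexicographic order, so the design
    is reproducible); within the chosen orientation all guide
    cross-products are emitted. Same-gene guide pairs are realized once,
    in guide_id-sorted orientation. Every targeting guide is paired with
    all 15 NT guides in both orientations, and all 225 NT x NT pairs are
    included as negative controls.
    """
    if len(nt_guides) != 15:
        raise ValueError(f"expected exactly 15 non-targeting guides, got {len(nt_guides)}")
    for g in nt_guides:
        if g.is_targeting:
            raise ValueError(f"{g.guide_id} passed as NT but is targeting")
    all_guides = list(guides) + list(nt_guides)
    ids = [g.guide_id for g in all_guides]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate guide_ids: {dup}")

    by_gene: dict[str, list[GuideRecord]] = {}
    for g in guides:
        if not g.is_targeting:
            raise ValueError(f"{g.guide_id}: NT guides must be passed via nt_guides")
        by_gene.setdefault(g.gene, []).append(g)
    for gene, lst in by_gene.items():
        if len(lst) < 2:
            raise ValueError(f"gene {gene} has fewer than two guides")
        lst.sort(key=lambda g: g.guide_id)

    genes = sorted(by_gene)
    rng = np.random.default_rng(orientation_seed)
    elements: list[LibraryElement] = []

    # Inter-gene: one orientation per unordered gene pair, all guide combos.
    for g1, g2 in itertools.combinations(genes, 2):
        a, b = (g1, g2) if rng.integers(0, 2) == 0 else (g2, g1)
        for ga in by_gene[a]:
            for gb in by_gene[b]:
                elements.append(_element(ga, gb))

    # Intra-gene: each unordered distinct-guide pair once, canonical order.
    for gene in genes:
        for ga, gb in itertools.combinations(by_gene[gene], 2):
            elements.append(_element(ga, gb))

    # Targeting x NT, both orientations.
    nts = sorted(nt_guides, key=lambda g: g.guide_id)
    for gene in genes:
        for g in by_gene[gene]:
            for nt in nts:
                elements.append(_element(g, nt))
                elements.append(_element(nt, g))

    # NT x NT: all 15 x 15 ordered combinations (includes self-pairs).
    for nt1 in nts:
        for nt2 in nts:
            elements.append(_element(nt1, nt2))

    eids = [e.element_id for e in elements]
    if len(set(eids)) != len(eids):
        raise ValueError("duplicate element_ids in design (guide reused across positions?)")

    return LibraryDesign(
        elements=elements,
        guides={g.guide_id: g for g in all_guides},
        orientation_seed=orientation_seed,
    )


def library_stats(design: LibraryDesign) -> dict:
    """Recompute design summary counts from the element list."""
    by_class = {c: 0 for c in PAIR_CLASSES}
    genes: set[str] = set()
    for e in design.elements:
        by_class[e.pair_class] += 1
        if e.gene_a != NT_GENE:
            genes.add(e.gene_a)
        if e.gene_b != NT_GENE:
            genes.add(e.gene_b)
    G = len(genes)
    return {
        "n_elements": len(design.elements),
        "n_genes": G,
        "n_targeting_guides": sum(1 for g in design.guides.values() if g.is_targeting),
        "gene_level_interactions": G * (G - 1) // 2,
        "guide_level_interactions": by_class["inter_gene"] + by_class["intra_gene"],
        "pair_class_counts": by_class,
    }


def emit_oligo_pool(design: LibraryDesign) -> pd.DataFrame:
    """Emit the synthesis oligo per element (constant regions + protospacers)."""
    rows = []
    for e in design.elements:
        for proto in (e.protospacer_a, e.protospacer_b):
            if not set(proto) <= _DNA:
                raise ValueError(f"element {e.element_id}: non-ACGT protospacer")
        rows.append({"element_id": e.element_id, "oligo": e.oligo})
    return pd.DataFrame(rows)


def parse_oligo(oligo: str) -> tuple[str, str]:
    """Recover (protospacer_a, protospacer_b) from an emitted oligo."""
    if not oligo.startswith(OLIGO_UPSTREAM) or not oligo.endswith(OLIGO_DOWNSTREAM):
        raise ValueError("oligo does not match constant cassette regions")
    core = oligo[len(OLIGO_UPSTREAM) : -len(OLIGO_DOWNSTREAM)]
    a, sep, b = core.partition(OLIGO_LINKER)
    if not sep or len(a) != PROTOSPACER_LEN or len(b) != PROTOSPACER_LEN:
        raise ValueError("oligo core does not split into two 20-mers around the linker")
    return a, b
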