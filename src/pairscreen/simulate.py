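"""Synthetic dual-guide screens with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a combinatorial library over synthetic genes, skewed (lognormal) T0
construct abundances, exponential depletion/enrichment over ~10
population doublings driven by the guide-efficacy / gene-effect /
interaction model, Poisson count sampling at a configurable mean depth,
and paired FASTQ reads whose first 22 bp contain the protospacers.

Truth phenotypes are parameterized directly on the 14-day LFC scale
(the per-doubling rate is phi / 10), so fitted parameters compare to
true ones without unit conversion.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .library import NT_GENE, GuideRecord, LibraryDesign, build_pair_set
from .counting import CountMatrix, PairIndex, SEARCH_WINDOW
from . import model as _model

#: doublings over which one unit of phenotype equals one unit of LFC
PHENOTYPE_DOUBLINGS = 10.0

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults mirror the screen being emulated: 15 NT controls, ~10
    population doublings between T0 and T14, mean T0 coverage of 500
    reads per construct, two biological replicates, and an essential
    fraction of 0.18. Essential genes carry a full-efficacy guide plus a
    partial-knockdown mismatched variant (activity drawn from the
    0.3-0.7 selection window); other genes carry perfect guides.
    """

    n_genes: int = 60
    guides_per_gene: int = 2
    n_nt: int = 15
    frac_essential: float = 0.18
    frac_interacting: float = 0.10
    y_essential_range: tuple[float, float] = (-5.0, -3.0)
    y_neutral_sd: float = 0.3
    s_range: tuple[float, float] = (-3.0, -1.0)
    x_perfect_range: tuple[float, float] = (0.7, 1.0)
    x_mismatch_range: tuple[float, float] = (0.3, 0.7)
    doublings: float = 10.0
    depth_per_element: float = 500.0
    abundance_skew: float = 0.5
    seq_error_rate: float = 0.001
    n_replicates: int = 2
    read_length: int = 30
    nb_dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_essential", "frac_interacting"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_element <= 0:
            raise ValueError("depth_per_element must be positive")
        if self.n_genes < 2 or self.guides_per_gene < 1:
            raise ValueError("need at least 2 genes and 1 guide per gene")
        if self.read_length < SEARCH_WINDOW:
            raise ValueError(f"read_length must be >= {SEARCH_WINDOW}")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must be a probability")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("y_essential_range", "s_range", "x_perfect_range", "x_mismatch_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SimTruth:
    """Ground-truth parameters and the library they live on."""

    library: LibraryDesign
    x: pd.Series  # guide_id -> true efficacy (0 for NT)
    y: pd.Series  # gene -> true effect on the 14-day LFC scale
    s: pd.Series  # all unordered gene pairs -> true interaction (0 = none)
    phi: pd.Series  # element_id -> expected construct phenotype
    config: SimConfig

    def interacting_pairs(self) -> list[tuple[str, str]]:
        return [p for p, v in self.s.items() if v < 0]


def _random_protospacers(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=20))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def element_phenotype(
    element, x: pd.Series, y: pd.Series, s: pd.Series
) -> float:
    """Expected LFC-scale phenotype of one construct under the model."""
    if element.pair_class == "nt_nt":
        return 0.0
    if element.pair_class == "targeting_nt":
        gid, gene = (
            (element.guide_a, element.gene_a)
            if element.gene_b == NT_GENE
            else (element.guide_b, element.gene_b)
        )
        return float(x[gid] * y[gene])
    xa, xb = float(x[element.guide_a]), float(x[element.guide_b])
    if element.pair_class == "intra_gene":
        return (1 - (1 - xa) * (1 - xb)) * float(y[element.gene_a])
    key = tuple(sorted((element.gene_a, element.gene_b)))
    return (
        xa * float(y[element.gene_a])
        + xb * float(y[element.gene_b])
        + xa * xb * float(s[key])
    )


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw a library and ground-truth parameters; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    n_ess = int(round(config.frac_essential * config.n_genes))
    essential = set(rng.choice(genes, size=n_ess, replace=False))

    n_guides_upper = config.n_genes * (config.guides_per_gene + 1) + config.n_nt
    protos = iter(_random_protospacers(rng, n_guides_upper))

    guides: list[GuideRecord] = []
    x_true: dict[str, float] = {}
    for gene in genes:
        if gene in essential:
            top = f"{gene}_g1"
            var = f"{gene}_g1_mm"
            guides.append(GuideRecord(top, gene, next(protos), "perfect"))
            guides.append(
                GuideRecord(var, gene, next(protos), "mismatch", parent_guide_id=top)
            )
            xs = {
                top: rng.uniform(*config.x_perfect_range),
                var: rng.uniform(*config.x_mismatch_range),
            }
        else:
            xs = {}
            for k in range(1, config.guides_per_gene + 1):
                gid = f"{gene}_g{k}"
                guides.append(GuideRecord(gid, gene, next(protos), "perfect"))
                xs[gid] = rng.uniform(*config.x_perfect_range)
        # identifiability anchor: each gene's strongest guide has efficacy 1
        peak = max(xs.values())
        for gid, v in xs.items():
            x_true[gid] = v / peak

    nt_guides = [
        GuideRecord(f"NT_{i:02d}", NT_GENE, next(protos), "non_targeting")
        for i in range(1, config.n_nt + 1)
    ]
    for g in nt_guides:
        x_true[g.guide_id] = 0.0

    library = build_pair_set(guides, nt_guides, orientation_seed=config.seed)

    y_true = {
        gene: (
            rng.uniform(*config.y_essential_range)
            if gene in essential
            else rng.normal(0.0, config.y_neutral_sd)
        )
        for gene in genes
    }

    pairs = list(itertools.combinations(genes, 2))
    n_inter = int(round(config.frac_interacting * len(pairs)))
    inter_idx = rng.choice(len(pairs), size=n_inter, replace=False) if n_inter else []
    s_true = {p: 0.0 for p in pairs}
    for i in inter_idx:
        s_true[pairs[i]] = rng.uniform(*config.s_range)

    x = pd.Series(x_true, name="x_true")
    y = pd.Series(y_true, name="y_true")
    s = pd.Series(s_true, name="s_true")
    s.index = pd.MultiIndex.from_tuples(s.index, names=["gene_a", "gene_b"])
    phi = pd.Series(
        {e.element_id: element_phenotype(e, x, y, s) for e in library.elements},
        name="phi",
    )
    return SimTruth(library=library, x=x, y=y, s=s, phi=phi, config=config)


def simulate_screen_counts(truth: SimTruth, config: SimConfig) -> CountMatrix:
    """Sample the T0/T14 count matrix for all replicates.

    One lognormal abundance profile is drawn per screen (replicates
    split from a common transduced pool), growth over ``doublings``
    rescales abundances by 2^(phi * doublings / 10), T14 totals are
    renormalized to the T0 sequencing depth, and counts are Poisson (or
    negative binomial when ``nb_dispersion`` is set).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(truth.library.elements)
    skew = config.abundance_skew
    log_a = rng.normal(-0.5 * skew**2, skew, size=n) if skew > 0 else np.zeros(n)
    abundance = config.depth_per_element * np.exp(log_a)

    growth = 2.0 ** (truth.phi.values * config.doublings / PHENOTYPE_DOUBLINGS)
    t14_mean = abundance * growth
    t14_mean *= abundance.sum() / t14_mean.sum()  # same sequencing depth as T0

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.nb_dispersion:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            return rng.poisson(lam)
        return rng.poisson(mean)

    data = {}
    meta = []
    for rep in range(1, config.n_replicates + 1):
        for tp, mean in (("T0", abundance), ("T14", t14_mean)):
            sid = f"R{rep}_{tp}"
            data[sid] = draw(mean)
            meta.append({"sample_id": sid, "replicate": f"R{rep}", "timepoint": tp})
    counts = pd.DataFrame(
        data, index=pd.Index(truth.phi.index, name="element_id"), dtype="int64"
    )
    samples = pd.DataFrame(meta).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_POW4 = (4 ** np.arange(20, dtype=np.uint64)).astype(np.uint64)


def _encode(seq: str) -> np.ndarray:
    """DNA string -> base codes 0..3."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(mat: np.ndarray, start: int) -> np.ndarray:
    """Pack each row's 20-mer at ``start`` into a single uint64."""
    win = mat[:, start : start + 20].astype(np.uint64)
    return win @ _POW4


def _build_reads(
    rng: np.random.Generator,
    protos: np.ndarray,  # (n_reads, 20) base codes
    read_length: int,
    lib_kmer_codes: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Protospacer + random filler, no spurious in-window library 20-mers."""
    n = len(protos)
    filler = rng.integers(0, 4, size=(n, read_length - 20), dtype=np.uint8)
    reads = np.hstack([protos, filler])
    # reject fillers creating a library 20-mer at in-window offsets 1 or 2
    for _ in range(8):
        bad = np.isin(_kmer_codes(reads, 1), lib_kmer_codes) | np.isin(
            _kmer_codes(reads, 2), lib_kmer_codes
        )
        if not bad.any():
            break
        reads[bad, 20:] = rng.integers(
            0, 4, size=(int(bad.sum()), read_length - 20), dtype=np.uint8
        )
    if error_rate > 0:
        hits = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=int(hits.sum()), dtype=np.uint8)
        reads[hits] = (reads[hits] + shift) % 4
    return reads


def simulate_fastq(
    counts: CountMatrix,
    truth: SimTruth,
    config: SimConfig,
    out_dir: str | Path,
    compress: bool = False,
) -> pd.DataFrame:
    """Write paired FASTQ files realizing a count matrix; returns a sample sheet.

    Read 1 starts with the position-a protospacer, read 2 with the
    position-b protospacer, each padded with random filler to
    ``read_length``. Filler is rejection-sampled so no spurious library
    20-mer appears in the first 22 bp. Reads are shuffled within each
    sample so file order carries no information.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lib = truth.library
    proto_a = np.vstack([_encode(e.protospacer_a) for e in lib.elements])
    proto_b = np.vstack([_encode(e.protospacer_b) for e in lib.elements])
    lib_kmer_codes = np.unique(
        np.concatenate([proto_a.astype(np.uint64) @ _POW4, proto_b.astype(np.uint64) @ _POW4])
    )
    eid_pos = {e.element_id: k for k, e in enumerate(lib.elements)}
    qual = b"I" * config.read_length
    suffix = ".fastq.gz" if compress else ".fastq"

    def dump(path: Path, sid: str, reads: np.ndarray) -> None:
        letters = _BASE_BYTES[reads]
        seqs = np.ascontiguousarray(letters).view(f"S{config.read_length}").ravel()
        blob = b"".join(
            b"@%s.%d\n%s\n+\n%s\n" % (sid.encode(), i, seq, qual)
            for i, seq in enumerate(seqs)
        )
        opener = gzip.open if compress else open
        with opener(path, "wb") as fh:
            fh.write(blob)

    rows = []
    for k, sid in enumerate(counts.counts.columns):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, k]))
        col = counts.counts[sid]
        pos = np.repeat(
            np.array([eid_pos[e] for e in col.index], dtype=np.int64), col.values
        )
        rng.shuffle(pos)
        r1 = _build_reads(
            rng, proto_a[pos], config.read_length, lib_kmer_codes, config.seq_error_rate
        )
        r2 = _build_reads(
            rng, proto_b[pos], config.read_length, lib_kmer_codes, config.seq_error_rate
        )
        p1 = out_dir / f"{sid}_R1{suffix}"
        p2 = out_dir / f"{sid}_R2{suffix}"
        dump(p1, sid, r1)
        dump(p2, sid, r2)
        row = counts.samples.loc[sid]
        rows.append(
            {
                "sample_id": sid,
                "fastq_r1": str(p1),
                "fastq_r2": str(p2),
                "replicate": row["replicate"],
                "timepoint": row["timepoint"],
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    fit: _model.ModelFit,
    scores: pd.DataFrame,
    truth: SimTruth,
    cutoff: float = -1.0,
) -> dict:
    """Compare a fit and its scores against simulation ground truth.

    Reports Pearson correlations of gene effects and (truly interacting)
    pair effects, recall/precision of synthetic-lethal calls at
    ``cutoff`` against pairs with true s <= cutoff, and the
    false-positive rate among truly non-interacting pairs. Pairs dropped
    by the pipeline count as not called (recall reflects the whole
    pipeline, not just the fit).
    """
    common_genes = [g for g in fit.y.index if g in truth.y.index]
    if not common_genes:
        raise ValueError("fitted and true gene sets are disjoint")
    if set(fit.y.index) - set(truth.y.index):
        raise ValueError("fit contains genes absent from the simulation truth")

    score_pairs = {
        tuple(sorted((r["gene_a"], r["gene_b"]))): float(r["sensitive_score"])
        for r in scores.to_dict("records")
    }
    truth_pairs = {tuple(k): float(v) for k, v in truth.s.items()}
    if set(score_pairs) - set(truth_pairs):
        raise ValueError("score table contains gene pairs absent from the truth")

    r_y = float(np.corrcoef(truth.y.loc[common_genes], fit.y.loc[common_genes])[0, 1])

    inter = [p for p, v in truth_pairs.items() if v < 0]
    fitted_s = {tuple(k): float(v) for k, v in fit.s.items()}
    inter_common = [p for p in inter if p in fitted_s]
    r_s = (
        float(
            np.corrcoef(
                [truth_pairs[p] for p in inter_common],
                [fitted_s[p] for p in inter_common],
            )[0, 1]
        )
        if len(inter_common) >= 2
        else float("nan")
    )

    true_sl = {p for p, v in truth_pairs.items() if v <= cutoff}
    called = {p for p, v in score_pairs.items() if v <= cutoff}
    recall = len(called & true_sl) / len(true_sl) if true_sl else float("nan")
    precision = len(called & true_sl) / len(called) if called else float("nan")
    null_pairs = {p for p, v in truth_pairs.items() if v == 0}
    fpr = (
        len(called & null_pairs) / len(null_pairs) if null_pairs else float("nan")
    )
    return {
        "r_y": r_y,
        "r_s_interacting": r_s,
        "recall": recall,
        "precision": precision,
        "false_positive_rate": fpr,
        "n_true_sl": len(true_sl),
        "n_called": len(called),
        "n_interacting": len(inter),
    }
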