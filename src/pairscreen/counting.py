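"""Paired-read counting: exact protospacer matching into a count matrix.

Each sequencing read pair reports one dual-guide construct: read 1
carries the position-a protospacer, read 2 the position-b protospacer.
Matching is exact (Hamming distance 0) over 20-mers anywhere in the
first 22 bp of each read, i.e. window start offsets 0, 1 and 2. A pair
is counted only when both reads resolve and the (a, b) guide combination
exists in the library.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam

from .library import NT_GENE, PROTOSPACER_LEN, LibraryDesign

SEARCH_WINDOW = 22  # first 22 bp of each read are searched
_OFFSETS = range(SEARCH_WINDOW - PROTOSPACER_LEN + 1)  # 0, 1, 2
_READ_ALPHABET = frozenset("ACGTN")

TIMEPOINTS = ("T0", "T14")

UNASSIGNED_REASONS = (
    "too_short",
    "bad_bases",
    "no_match_a",
    "no_match_b",
    "invalid_pair",
    "ambiguous",
)


@dataclass
class PairIndex:
    """Exact-match lookup from 20-mers to guides and valid guide pairs."""

    position_a_map: dict[str, str]
    position_b_map: dict[str, str]
    valid_pairs: dict[tuple[str, str], str]

    @property
    def element_ids(self) -> list[str]:
        return list(self.valid_pairs.values())


@dataclass
class CountMatrix:
    """Integer counts per library element x sample, plus sample metadata.

    ``counts``: DataFrame indexed by element_id with one column per
    sample. ``samples``: DataFrame indexed by sample_id with columns
    ``replicate`` and ``timepoint`` (T0 or T14).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must equal samples index (same order)")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"unknown timepoints: {sorted(bad)}")

    @property
    def replicates(self) -> list[str]:
        return sorted(self.samples["replicate"].unique())

    def sample_for(self, replicate: str, timepoint: str) -> str:
        sel = self.samples[
            (self.samples["replicate"] == replicate)
            & (self.samples["timepoint"] == timepoint)
        ]
        if len(sel) != 1:
            raise ValueError(
                f"replicate {replicate!r} has {len(sel)} samples at {timepoint}"
                " (need exactly one)"
            )
        return sel.index[0]


class ReadAssignment(NamedTuple):
    element_id: str | None
    reason: str  # "assigned" or one of UNASSIGNED_REASONS


def build_index(design: LibraryDesign) -> PairIndex:
    """Index a library design for exact paired matching.

    Within each position the 20-mer -> guide map must be injective;
    a protospacer shared by two guides in the same position would make
    read assignment ambiguous by construction and is rejected.
    """
    pos_a: dict[str, str] = {}
    pos_b: dict[str, str] = {}
    valid: dict[tuple[str, str], str] = {}
    for e in design.elements:
        for proto, gid, pos in (
            (e.protospacer_a, e.guide_a, pos_a),
            (e.protospacer_b, e.guide_b, pos_b),
        ):
            prev = pos.get(proto)
            if prev is not None and prev != gid:
                raise ValueError(
                    f"protospacer {proto} maps to both {prev} and {gid} "
                    "within one position"
                )
            pos[proto] = gid
        valid[(e.guide_a, e.guide_b)] = e.element_id
    return PairIndex(position_a_map=pos_a, position_b_map=pos_b, valid_pairs=valid)


def _scan(read: str, mapping: dict[str, str]) -> set[str]:
    """Guides whose 20-mer occurs within the read's first 22 bp."""
    window = read[:SEARCH_WINDOW]
    hits = set()
    for off in _OFFSETS:
        kmer = window[off : off + PROTOSPACER_LEN]
        if len(kmer) < PROTOSPACER_LEN:
            break
        gid = mapping.get(kmer)
        if gid is not None:
            hits.add(gid)
    return hits


def assign_read_pair(read1: str, read2: str, index: PairIndex) -> ReadAssignment:
    """Resolve one read pair to a library element, or say why not."""
    read1, read2 = read1.upper(), read2.upper()
    if len(read1) < SEARCH_WINDOW or len(read2) < SEARCH_WINDOW:
        return ReadAssignment(None, "too_short")
    if not (
        set(read1[:SEARCH_WINDOW]) <= _READ_ALPHABET
        and set(read2[:SEARCH_WINDOW]) <= _READ_ALPHABET
    ):
        return ReadAssignment(None, "bad_bases")
    hits_a = _scan(read1, index.position_a_map)
    if len(hits_a) > 1:
        return ReadAssignment(None, "ambiguous")
    hits_b = _scan(read2, index.position_b_map)
    if len(hits_b) > 1:
        return ReadAssignment(None, "ambiguous")
    if not hits_a:
        return ReadAssignment(None, "no_match_a")
    if not hits_b:
        return ReadAssignment(None, "no_match_b")
    key = (hits_a.pop(), hits_b.pop())
    eid = index.valid_pairs.get(key)
    if eid is None:
        return ReadAssignment(None, "invalid_pair")
    return ReadAssignment(eid, "assigned")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_pairs(path1: str, path2: str) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in itertools.zip_longest(f1, f2):
            if r1 is None or r2 is None:
                raise ValueError(f"R1/R2 read counts differ: {path1} vs {path2}")
            yield r1.sequence, r2.sequence


def count_screen(
    sample_sheet: pd.DataFrame,
    index: PairIndex,
    rc_read2: bool = False,
) -> tuple[CountMatrix, dict]:
    """Count all samples of a screen from paired FASTQ files.

    ``sample_sheet`` columns: sample_id, fastq_r1, fastq_r2, replicate,
    timepoint. The matrix covers *all* library elements, including
    never-observed ones (zero counts). Set ``rc_read2`` for chemistries
    where read 2 is sequenced in reverse complement of the stored
    position-b protospacer.

    Returns the CountMatrix and a per-sample assignment log satisfying
    assigned + unassigned = total reads.
    """
    required = {"sample_id", "fastq_r1", "fastq_r2", "replicate", "timepoint"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sample_sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in sample sheet")

    element_ids = index.element_ids
    data: dict[str, pd.Series] = {}
    log: dict[str, dict] = {}
    for row in sample_sheet.to_dict("records"):
        sid = row["sample_id"]
        if row["timepoint"] not in TIMEPOINTS:
            raise ValueError(f"sample {sid}: unknown timepoint {row['timepoint']!r}")
        counts: dict[str, int] = {}
        reasons = {r: 0 for r in UNASSIGNED_REASONS}
        total = assigned = 0
        for r1, r2 in _read_pairs(row["fastq_r1"], row["fastq_r2"]):
            total += 1
            if rc_read2:
                r2 = reverse_complement(r2)
            res = assign_read_pair(r1, r2, index)
            if res.element_id is None:
                reasons[res.reason] += 1
            else:
                assigned += 1
                counts[res.element_id] = counts.get(res.element_id, 0) + 1
        data[sid] = pd.Series(counts, dtype="int64")
        log[sid] = {
            "total_reads": total,
            "assigned": assigned,
            "unassigned": reasons,
        }
        assert assigned + sum(reasons.values()) == total

    counts_df = (
        pd.DataFrame(data, index=pd.Index(element_ids, name="element_id"))
        .fillna(0)
        .astype("int64")
    )
    samples = sample_sheet.set_index("sample_id")[["replicate", "timepoint"]]
    counts_df = counts_df[list(samples.index)]
    return CountMatrix(counts=counts_df, samples=samples), log


def coverage_qc(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample coverage summary used to judge sample quality."""
    rows = []
    for sid in cm.counts.columns:
        col = cm.counts[sid]
        rows.append(
            {
                "sample_id": sid,
                "total_reads": int(col.sum()),
                "mean_per_element": float(col.mean()),
                "median_per_element": float(col.median()),
                "zero_fraction": float((col == 0).mean()),
            }
        )
    qc = pd.DataFrame(rows).set_index("sample_id")
    qc["flagged"] = qc["zero_fraction"] >= 1.0
    return qc
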