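"""Plain-text readers and writers for the pipeline's tables.

All artifacts are TSV/CSV/JSON/FASTA so they diff and version cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counting import CountMatrix
from .library import GuideRecord, LibraryDesign, LibraryElement
from .model import ModelFit


def write_library(design: LibraryDesign, elements_path, guides_path=None) -> None:
    """Write the element table (and optionally the guide table) as TSV."""
    df = design.to_frame()
    df["oligo"] = [e.oligo for e in design.elements]
    df.to_csv(elements_path, sep="\t", index=False)
    if guides_path is not None:
        design.guides_frame().to_csv(guides_path, sep="\t", index=False)


def read_library(elements_path, guides_path=None, orientation_seed: int = -1) -> LibraryDesign:
    """Reconstruct a LibraryDesign from its TSV tables.

    Without the guide table, guide annotations (type, mismatch parent)
    are inferred from the element table: NT guides from the NT gene
    sentinel, everything else as perfect guides. Pass ``guides_path``
    when mismatch-variant substitution must be possible downstream.
    """
    df = pd.read_csv(elements_path, sep="\t", dtype=str)
    guides: dict[str, GuideRecord] = {}
    if guides_path is not None:
        gdf = pd.read_csv(guides_path, sep="\t")
        for row in gdf.to_dict("records"):
            guides[row["guide_id"]] = GuideRecord(
                guide_id=row["guide_id"],
                gene=row["gene"],
                protospacer=row["protospacer"],
                guide_type=row["guide_type"],
                tss_id=str(row.get("tss_id", "P1")),
                parent_guide_id=(
                    "" if pd.isna(row.get("parent_guide_id")) else str(row["parent_guide_id"])
                ),
            )
    else:
        for row in df.to_dict("records"):
            for side in ("a", "b"):
                gid = row[f"guide_{side}"]
                if gid in guides:
                    continue
                gene = row[f"gene_{side}"]
                guides[gid] = GuideRecord(
                    guide_id=gid,
                    gene=gene,
                    protospacer=row[f"protospacer_{side}"],
                    guide_type="non_targeting" if gene == "NT" else "perfect",
                )
    elements = [
        LibraryElement(
            element_id=row["element_id"],
            guide_a=row["guide_a"],
            guide_b=row["guide_b"],
            gene_a=row["gene_a"],
            gene_b=row["gene_b"],
            protospacer_a=row["protospacer_a"],
            protospacer_b=row["protospacer_b"],
            pair_class=row["pair_class"],
        )
        for row in df.to_dict("records")
    ]
    return LibraryDesign(elements=elements, guides=guides, orientation_seed=orientation_seed)


def write_oligo_fasta(design: LibraryDesign, path) -> None:
    records = [
        SeqRecord(Seq(e.oligo), id=e.element_id, description="")
        for e in design.elements
    ]
    SeqIO.write(records, str(path), "fasta")


def write_counts(cm: CountMatrix, counts_path, samples_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        cm.samples.to_csv(samples_path)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="element_id")
    samples = pd.read_csv(samples_path, index_col="sample_id")
    return CountMatrix(counts=counts[list(samples.index)].astype("int64"), samples=samples)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lfc(lfc: pd.DataFrame, path) -> None:
    lfc.to_csv(path, sep="\t")


def read_lfc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="element_id")


def write_fit(fit: ModelFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def read_fit(path) -> ModelFit:
    return ModelFit.from_dict(json.loads(Path(path).read_text()))


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
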