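"""Read assignment and screen counting: exact matching, conservation, QC."""

import random
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pairscreen import (
    CountMatrix,
    GuideRecord,
    SimConfig,
    assign_read_pair,
    build_index,
    count_screen,
    coverage_qc,
    simulate_fastq,
    simulate_screen_counts,
    simulate_truth,
)
from pairscreen.counting import reverse_complement
from pairscreen.library import LibraryDesign

from conftest import fresh_protospacer


FILLER = "TTTTTTTTTTTTTTTTTTTT"


@pytest.fixture(scope="module")
def mini_index(mini_design):
    return build_index(mini_design)


@pytest.fixture(scope="module")
def an_element(mini_design):
    return next(e for e in mini_design.elements if e.pair_class == "inter_gene")


class TestBuildIndex:
    def test_map_sizes_and_valid_pairs(self, mini_design, mini_index):
        protos = {g.protospacer for g in mini_design.guides.values()}
        assert set(mini_index.position_a_map) <= protos
        assert len(mini_index.valid_pairs) == len(mini_design.elements)

    def test_duplicate_protospacer_within_position_rejected(self, mini_design):
        shared = fresh_protospacer()
        e0 = mini_design.elements[0]
        clash_a = GuideRecord("dupA_g1", "DUPA", shared)
        clash_b = GuideRecord("dupB_g1", "DUPB", shared)
        bad = LibraryDesign(
            elements=[
                e0,
                type(e0)(
                    element_id="dupA_g1:dupB_g1",
                    guide_a="dupA_g1",
                    guide_b="dupB_g1",
                    gene_a="DUPA",
                    gene_b="DUPB",
                    protospacer_a=shared,
                    protospacer_b=fresh_protospacer(),
                    pair_class="inter_gene",
                ),
                type(e0)(
                    element_id="dupB_g1:dupA_g1",
                    guide_a="dupB_g1",
                    guide_b="dupA_g1",
                    gene_a="DUPB",
                    gene_b="DUPA",
                    protospacer_a=shared,
                    protospacer_b=fresh_protospacer(),
                    pair_class="inter_gene",
                ),
            ],
            guides={**mini_design.guides, "dupA_g1": clash_a, "dupB_g1": clash_b},
            orientation_seed=0,
        )
        with pytest.raises(ValueError, match="maps to both"):
            build_index(bad)


class TestAssignReadPair:
    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_in_window_offsets_assign(self, mini_index, an_element, offset):
        r1 = "A" * offset + an_element.protospacer_a + FILLER
        r2 = "C" * offset + an_element.protospacer_b + FILLER
        res = assign_read_pair(r1, r2, mini_index)
        assert res.element_id == an_element.element_id

    def test_offset_three_is_outside_window(self, mini_index, an_element):
        r1 = "AAA" + an_element.protospacer_a + FILLER
        r2 = an_element.protospacer_b + FILLER
        assert assign_read_pair(r1, r2, mini_index).reason == "no_match_a"

    def test_single_substitution_breaks_match(self, mini_index, an_element):
        proto = an_element.protospacer_a
        mutated = proto[:10] + ("A" if proto[10] != "A" else "C") + proto[11:]
        res = assign_read_pair(mutated + FILLER, an_element.protospacer_b + FILLER, mini_index)
        assert res.reason == "no_match_a"

    def test_read2_mismatch_reports_no_match_b(self, mini_index, an_element):
        res = assign_read_pair(
            an_element.protospacer_a + FILLER, "G" * 22 + FILLER, mini_index
        )
        assert res.reason == "no_match_b"

    def test_unpaired_guides_report_invalid_pair(self, mini_design, mini_index):
        # inter-gene pairs exist in only one orientation; the reverse is invalid
        e = next(x for x in mini_design.elements if x.pair_class == "inter_gene")
        res = assign_read_pair(
            e.protospacer_b + FILLER, e.protospacer_a + FILLER, mini_index
        )
        assert res.reason in ("invalid_pair", "no_match_a", "no_match_b")

    def test_short_read_and_bad_bases(self, mini_index, an_element):
        assert assign_read_pair("ACGT", "ACGT", mini_index).reason == "too_short"
        res = assign_read_pair("X" * 22, an_element.protospacer_b + FILLER, mini_index)
        assert res.reason == "bad_bases"

    def test_overlapping_kmers_are_ambiguous(self, nt_guides):
        core = "ACGTA" * 5  # 25 bases; windows at offsets 0 and 1 both valid
        g1 = GuideRecord("amb1_g1", "AMB1", core[:20])
        g1b = GuideRecord("amb1_g2", "AMB1", fresh_protospacer())
        g2 = GuideRecord("amb2_g1", "AMB2", core[1:21])
        g2b = GuideRecord("amb2_g2", "AMB2", fresh_protospacer())
        from pairscreen import build_pair_set

        lib = build_pair_set([g1, g1b, g2, g2b], nt_guides, orientation_seed=0)
        index = build_index(lib)
        res = assign_read_pair(core + "T" * 5, g1b.protospacer + FILLER, index)
        assert res.reason == "ambiguous"


def _write_fastq(path: Path, reads: list[str]) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture(scope="module")
def tiny_screen():
    cfg = SimConfig(
        n_genes=5, depth_per_element=40, seq_error_rate=0.0, n_replicates=1, seed=9
    )
    truth = simulate_truth(cfg)
    counts = simulate_screen_counts(truth, cfg)
    with tempfile.TemporaryDirectory() as d:
        sheet = simulate_fastq(counts, truth, cfg, d)
        yield truth, counts, sheet


class TestCountScreen:

    def test_round_trip_exact_at_zero_error(self, tiny_screen):
        truth, counts, sheet = tiny_screen
        cm, log = count_screen(sheet, build_index(truth.library))
        pd.testing.assert_frame_equal(
            cm.counts, counts.counts.loc[cm.counts.index, cm.counts.columns]
        )
        for rec in log.values():
            assert rec["assigned"] == rec["total_reads"]

    def test_read_conservation_with_junk_reads(self, tiny_screen, tmp_path):
        truth, _, _ = tiny_screen
        index = build_index(truth.library)
        e = truth.library.elements[0]
        good = [e.protospacer_a + FILLER] * 5
        junk = ["G" * 40, "ACGT", "N" * 40]
        _write_fastq(tmp_path / "r1.fastq", good + junk)
        _write_fastq(tmp_path / "r2.fastq", [e.protospacer_b + FILLER] * 8)
        sheet = pd.DataFrame(
            [
                {
                    "sample_id": "S1",
                    "fastq_r1": str(tmp_path / "r1.fastq"),
                    "fastq_r2": str(tmp_path / "r2.fastq"),
                    "replicate": "R1",
                    "timepoint": "T0",
                }
            ]
        )
        cm, log = count_screen(sheet, index)
        rec = log["S1"]
        assert rec["total_reads"] == 8
        assert rec["assigned"] + sum(rec["unassigned"].values()) == 8
        assert cm.counts["S1"].sum() == rec["assigned"] == 5

    def test_empty_fastq_gives_zero_matrix(self, tiny_screen, tmp_path):
        truth, _, _ = tiny_screen
        (tmp_path / "e1.fastq").write_text("")
        (tmp_path / "e2.fastq").write_text("")
        sheet = pd.DataFrame(
            [
                {
                    "sample_id": "S1",
                    "fastq_r1": str(tmp_path / "e1.fastq"),
                    "fastq_r2": str(tmp_path / "e2.fastq"),
                    "replicate": "R1",
                    "timepoint": "T0",
                }
            ]
        )
        cm, log = count_screen(sheet, build_index(truth.library))
        assert log["S1"]["total_reads"] == 0
        assert (cm.counts["S1"] == 0).all()
        assert len(cm.counts) == len(truth.library.elements)

    def test_counting_is_order_invariant(self, tiny_screen, tmp_path):
        truth, _, sheet = tiny_screen
        index = build_index(truth.library)
        row = sheet.iloc[0]
        records = Path(row["fastq_r1"]).read_text().strip().split("\n")
        recs1 = [records[i : i + 4] for i in range(0, len(records), 4)]
        records2 = Path(row["fastq_r2"]).read_text().strip().split("\n")
        recs2 = [records2[i : i + 4] for i in range(0, len(records2), 4)]
        order = list(range(len(recs1)))
        random.Random(3).shuffle(order)
        (tmp_path / "s1.fastq").write_text(
            "\n".join("\n".join(recs1[i]) for i in order) + "\n"
        )
        (tmp_path / "s2.fastq").write_text(
            "\n".join("\n".join(recs2[i]) for i in order) + "\n"
        )
        base = sheet.iloc[[0]].copy()
        shuf = base.copy()
        shuf["fastq_r1"] = str(tmp_path / "s1.fastq")
        shuf["fastq_r2"] = str(tmp_path / "s2.fastq")
        cm_a, _ = count_screen(base, index)
        cm_b, _ = count_screen(shuf, index)
        pd.testing.assert_frame_equal(cm_a.counts, cm_b.counts)

    def test_desynchronized_files_rejected(self, tiny_screen, tmp_path):
        truth, _, _ = tiny_screen
        e = truth.library.elements[0]
        _write_fastq(tmp_path / "r1.fastq", [e.protospacer_a + FILLER] * 3)
        _write_fastq(tmp_path / "r2.fastq", [e.protospacer_b + FILLER] * 2)
        sheet = pd.DataFrame(
            [
                {
                    "sample_id": "S1",
                    "fastq_r1": str(tmp_path / "r1.fastq"),
                    "fastq_r2": str(tmp_path / "r2.fastq"),
                    "replicate": "R1",
                    "timepoint": "T0",
                }
            ]
        )
        with pytest.raises(ValueError, match="differ"):
            count_screen(sheet, build_index(truth.library))

    def test_rc_read2_flag(self, tiny_screen, tmp_path):
        truth, _, _ = tiny_screen
        e = truth.library.elements[0]
        _write_fastq(tmp_path / "r1.fastq", [e.protospacer_a + FILLER])
        _write_fastq(
            tmp_path / "r2.fastq", [reverse_complement(e.protospacer_b + FILLER)]
        )
        sheet = pd.DataFrame(
            [
                {
                    "sample_id": "S1",
                    "fastq_r1": str(tmp_path / "r1.fastq"),
                    "fastq_r2": str(tmp_path / "r2.fastq"),
                    "replicate": "R1",
                    "timepoint": "T0",
                }
            ]
        )
        index = build_index(truth.library)
        cm_plain, log_plain = count_screen(sheet, index)
        cm_rc, log_rc = count_screen(sheet, index, rc_read2=True)
        assert log_plain["S1"]["assigned"] == 0
        assert log_rc["S1"]["assigned"] == 1
        assert cm_rc.counts.loc[e.element_id, "S1"] == 1

    def test_assignment_decreases_with_error_rate(self):
        fractions = []
        for rate in (0.0, 0.05, 0.2):
            cfg = SimConfig(
                n_genes=4, depth_per_element=30, seq_error_rate=rate,
                n_replicates=1, seed=17,
            )
            truth = simulate_truth(cfg)
            counts = simulate_screen_counts(truth, cfg)
            with tempfile.TemporaryDirectory() as d:
                sheet = simulate_fastq(counts, truth, cfg, d)
                _, log = count_screen(sheet, build_index(truth.library))
            tot = sum(l["total_reads"] for l in log.values())
            asg = sum(l["assigned"] for l in log.values())
            fractions.append(asg / tot)
        assert fractions[0] == 1.0
        assert fractions[0] > fractions[1] > fractions[2]


class TestCoverageQC:
    def _cm(self, values):
        counts = pd.DataFrame(
            {"S1": values}, index=[f"e{i}" for i in range(len(values))]
        )
        counts.index.name = "element_id"
        samples = pd.DataFrame(
            {"replicate": ["R1"], "timepoint": ["T0"]}, index=pd.Index(["S1"], name="sample_id")
        )
        return CountMatrix(counts=counts, samples=samples)

    def test_uniform_counts(self):
        qc = coverage_qc(self._cm([10, 10, 10, 10]))
        assert qc.loc["S1", "mean_per_element"] == 10
        assert qc.loc["S1", "zero_fraction"] == 0

    def test_median_and_zero_fraction(self):
        qc = coverage_qc(self._cm([0, 0, 10, 30]))
        assert qc.loc["S1", "median_per_element"] == 5
        assert qc.loc["S1", "zero_fraction"] == 0.5

    def test_all_zero_sample_flagged(self):
        qc = coverage_qc(self._cm([0, 0, 0]))
        assert bool(qc.loc["S1", "flagged"])
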