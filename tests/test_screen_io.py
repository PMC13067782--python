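"""File formats, strict config validation, and pipeline reproducibility."""

import json

import numpy as np
import pytest

from tilescan.errors import ParseError
from tilescan.guide_design import design_tiling_library
from tilescan.screen_io import (
    RunConfig,
    load_config,
    read_counts,
    read_fasta,
    read_library,
    run_pipeline,
    write_counts,
    write_library,
)
from tilescan.synthetic_screen import (
    Sample,
    ScreenCounts,
    make_itgb1_like_fixture,
)


class TestFasta:
    def test_single_record_roundtrip(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">cds1 test\nATGAAA\nTTTGGG\n")
        (cds,) = read_fasta(p)
        assert cds.id == "cds1"
        assert cds.seq == "ATGAAATTTGGG"

    def test_multi_record_order_preserved(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">b\nATGCCC\n>a\nATGGGG\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["b", "a"]

    def test_crlf_and_trailing_blank_parse_identically(self, tmp_path):
        lf = tmp_path / "lf.fa"
        crlf = tmp_path / "crlf.fa"
        lf.write_bytes(b">x\nATGAAA\nCCCGGG\n")
        crlf.write_bytes(b">x\r\nATGAAA\r\nCCCGGG\r\n\r\n")
        assert read_fasta(lf)[0].seq == read_fasta(crlf)[0].seq

    def test_rna_rejected(self, tmp_path):
        p = tmp_path / "rna.fa"
        p.write_text(">x\nAUGAAA\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_bad_length_reported_with_record_id(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">weird\nATGA\n")
        with pytest.raises(ParseError, match="weird"):
            read_fasta(p)


class TestLibraryTsv:
    def test_roundtrip_with_controls(self, tmp_path):
        fx = make_itgb1_like_fixture(5)
        p = tmp_path / "lib.tsv"
        write_library(fx.library, p)
        back = read_library(p)
        assert back == fx.library

    def test_deterministic_bytes(self, tmp_path):
        fx = make_itgb1_like_fixture(5)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_library(fx.library, a)
        write_library(fx.library, b)
        assert a.read_bytes() == b.read_bytes()


class TestCountsTsv:
    def _counts(self):
        return ScreenCounts(
            ["g1", "g2", "g3"],
            [Sample("ref_1", "reference", 1), Sample("scr_1", "screened", 1)],
            np.array([[5, 1], [10, 2], [0, 12]]),
        )

    def test_write_read_identity(self, tmp_path):
        p = tmp_path / "c.tsv"
        write_counts(self._counts(), p)
        back = read_counts(p)
        assert back.guide_ids == ["g1", "g2", "g3"]
        assert back.samples == self._counts().samples
        assert (back.counts == self._counts().counts).all()
        p2 = tmp_path / "c2.tsv"
        write_counts(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_handwritten_file_parses(self, tmp_path):
        p = tmp_path / "hand.tsv"
        p.write_text(
            "#condition\treference\tscreened\n"
            "#replicate\t1\t1\n"
            "guide_id\tref_1\tscr_1\n"
            "a\t3\t4\n"
            "b\t0\t7\n"
            "c\t9\t1\n"
        )
        counts = read_counts(p)
        assert (counts.counts == np.array([[3, 4], [0, 7], [9, 1]])).all()

    @pytest.mark.parametrize(
        "row,err",
        [
            ("a\t-3\t4\n", "negative"),
            ("a\t3.5\t4\n", "non-integer"),
            ("a\t3\t4\na\t1\t1\n", "duplicated"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, row, err):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#condition\treference\tscreened\n"
            "#replicate\t1\t1\n"
            "guide_id\tref_1\tscr_1\n" + row
        )
        with pytest.raises(ParseError, match=err):
            read_counts(p)

    def test_unknown_condition_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#condition\ttumor\tscreened\n#replicate\t1\t1\n"
            "guide_id\ts1\ts2\na\t1\t2\n"
        )
        with pytest.raises(ParseError, match="condition"):
            read_counts(p)


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = RunConfig()
        assert cfg.sim.coverage >= 1
        assert 0 <= cfg.model.p_frameshift <= 1

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 1\nbogus_knob: 3\n")
        with pytest.raises(ParseError, match="bogus_knob"):
            load_config(p)

    def test_invalid_probability_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("sim:\n  s_scr: 1.7\n")
        with pytest.raises(ParseError):
            load_config(p)

    def test_yaml_values_land_in_config(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "seed: 9\ngene: DEMO\nsim:\n  coverage: 77\n"
            "analysis:\n  bandwidth: 3.5\n"
        )
        cfg = load_config(p)
        assert (cfg.seed, cfg.gene) == (9, "DEMO")
        assert cfg.sim.coverage == 77
        assert cfg.analysis.bandwidth == 3.5


def _small_config(seed=3):
    return RunConfig.model_validate({
        "gene": "MINI",
        "cds_length_nt": 360,
        "n_controls": 30,
        "seed": seed,
        "sim": {"domains": [[40, 60, 1.0]], "coverage": 100,
                "depth": 100_000, "t_pre": 5, "t_scr": 10},
        "analysis": {"permutations": 100},
    })


class TestPipeline:
    def test_pipeline_produces_artifacts_and_manifest(self, tmp_path):
        paths = run_pipeline(_small_config(), tmp_path / "run")
        for key in ("library", "counts", "truth", "scores", "track",
                    "regions", "regions_bed", "metrics", "manifest"):
            assert paths[key].exists(), key
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 3
        assert manifest["stages"][0] == "design"

    def test_deleted_intermediate_is_regenerated_identically(self, tmp_path):
        out = tmp_path / "run"
        paths = run_pipeline(_small_config(), out)
        scores_bytes = paths["scores"].read_bytes()
        paths["scores"].unlink()
        run_pipeline(_small_config(), out)
        assert paths["scores"].read_bytes() == scores_bytes

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        from tilescan.screen_io import write_regions_bed
        from tilescan.domain_scan import RegionCall

        p = tmp_path / "r.bed"
        write_regions_bed([RegionCall(153, 171, -2.0, 0.01, 1)], p, "MINI")
        chrom, s0, e0, name, _ = p.read_text().strip().split("\t")
        assert (chrom, int(s0), int(e0), name) == ("MINI", 152, 171, "region_1")
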