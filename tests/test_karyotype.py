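"""CNV call construction, sex inference, four-way classification and
'seq' nomenclature formatting (including the published call strings)."""

import itertools

import numpy as np
import pytest

from embryoscreen import (
    CnvCall,
    KaryotypeSpec,
    PipelineConfig,
    ReadSimConfig,
    call_cnvs,
    classify,
    expected_cn,
    format_call,
    infer_sex,
    make_synthetic_genome,
    parse_call,
    run_embryo,
    simulate_reads,
)
from embryoscreen.coverage import BinProfile
from embryoscreen.exceptions import AnnotationError
from embryoscreen.segmentation import Segment
from embryoscreen.synthetic import SyntheticGenomeSpec
from embryoscreen.evaluate import reciprocal_overlap
from tests.conftest import HG18_CHR2_LEN, tiny_genome


def seg(chrom, a, b, mean, bin_size=1_000_000, chrom_len=None):
    return Segment(chrom, a, b, a * bin_size,
                   (b * bin_size) if chrom_len is None else min(b * bin_size, chrom_len),
                   mean)


@pytest.fixture
def genome20():
    """Two 20-bin autosomes, no bands needed."""
    spec = SyntheticGenomeSpec(
        autosome_lengths=(20_000_000, 20_000_000), include_sex_chromosomes=False
    )
    return make_synthetic_genome(spec, seed=0)


class TestCallCnvs:
    THRESH = (2.4, 1.6)

    def test_whole_chromosome_gain(self, genome20):
        segs = {"chr1": [seg("chr1", 0, 20, 3.02)], "chr2": [seg("chr2", 0, 20, 2.0)]}
        calls = call_cnvs(segs, self.THRESH, genome20, annotate=False)
        assert len(calls) == 1
        c = calls[0]
        assert (c.chrom, c.copy_number, c.scope) == ("chr1", 3, "whole-chromosome")

    def test_subthreshold_segment_not_called(self, genome20):
        segs = {"chr1": [seg("chr1", 0, 20, 2.2)], "chr2": [seg("chr2", 0, 20, 2.0)]}
        assert call_cnvs(segs, self.THRESH, genome20, annotate=False) == []

    def test_adjacent_same_direction_segments_merge(self, genome20):
        segs = {
            "chr1": [
                seg("chr1", 0, 5, 2.0),
                seg("chr1", 5, 10, 2.9),
                seg("chr1", 10, 15, 3.1),
                seg("chr1", 15, 20, 2.0),
            ],
            "chr2": [seg("chr2", 0, 20, 2.0)],
        }
        calls = call_cnvs(segs, self.THRESH, genome20, annotate=False)
        assert len(calls) == 1
        assert (calls[0].start_bp, calls[0].end_bp) == (5_000_000, 15_000_000)
        assert calls[0].copy_number == 3
        assert calls[0].scope == "segmental"

    def test_short_call_dropped(self, genome20):
        segs = {
            "chr1": [seg("chr1", 0, 20, 2.0)],
            "chr2": [seg("chr2", 0, 20, 2.0)],
        }
        # sub-Mb segment via a custom bin size
        segs["chr1"] = [
            Segment("chr1", 0, 1, 0, 500_000, 3.5),
            Segment("chr1", 1, 20, 500_000, 20_000_000, 2.0),
        ]
        calls = call_cnvs(segs, self.THRESH, genome20, min_cnv_length=1_000_000,
                          annotate=False)
        assert calls == []

    def test_rounded_diploid_inside_thresholds_discarded(self, genome20):
        # passes the gain cut but rounds to 2 -> discarded
        segs = {"chr1": [seg("chr1", 0, 20, 2.45)], "chr2": [seg("chr2", 0, 20, 2.0)]}
        assert call_cnvs(segs, self.THRESH, genome20, annotate=False) == []

    def test_sex_baseline_y_gain(self):
        g = tiny_genome(n_bins=20, bin_size=1_000_000, with_sex=True)
        segs = {
            "c1": [seg("c1", 0, 20, 2.0)],
            "chrX": [seg("chrX", 0, 20, 1.0)],
            "chrY": [seg("chrY", 0, 20, 2.0)],
        }
        calls = call_cnvs(segs, self.THRESH, g, sex="XY", annotate=False)
        assert len(calls) == 1
        assert calls[0].chrom == "chrY" and calls[0].copy_number == 2
        # same segments under undetermined sex: sex chromosomes not called
        assert call_cnvs(segs, self.THRESH, g, sex="undetermined",
                         annotate=False) == []


class TestInferSex:
    def _profile(self, genome, x_level, y_level):
        cn = np.full(genome.n_bins, 2.0)
        cn[genome.chrom_slice("chrX")] = x_level
        cn[genome.chrom_slice("chrY")] = y_level
        return BinProfile("s", np.zeros(genome.n_bins), cn_ratio=cn)

    @pytest.mark.parametrize(
        "x,y,expect",
        [(1.98, 0.02, "XX"), (1.05, 0.97, "XY"), (1.5, 0.5, "undetermined"),
         (2.9, 0.1, "XX"), (1.4, 0.2, "undetermined")],
    )
    def test_cutpoints(self, x, y, expect):
        g = tiny_genome(n_bins=11, bin_size=1_000_000, with_sex=True)
        assert infer_sex(self._profile(g, x, y), g) == expect

    def test_no_sex_chromosomes(self):
        g = tiny_genome(n_bins=11, bin_size=1_000_000)
        prof = BinProfile("s", np.zeros(11), cn_ratio=np.full(11, 2.0))
        assert infer_sex(prof, g) == "undetermined"

    def test_expected_cn_baselines(self):
        assert expected_cn("chr5", "XY") == 2.0
        assert expected_cn("chrX", "XX") == 2.0
        assert expected_cn("chrX", "XY") == 1.0
        assert expected_cn("chrY", "XX") == 0.0
        assert expected_cn("chrY", "XY") == 1.0


def call(chrom="chr1", scope="segmental", cn=3, start=0, end=5_000_000):
    return CnvCall(chrom, start, end, cn, scope)


class TestClassify:
    def test_rules(self):
        assert classify([]) == "euploid"
        assert classify([call(scope="whole-chromosome", chrom="chr16")]) == "numerical"
        assert classify([call()]) == "imbalanced"
        # event set shaped like a whole-Y gain plus two segmental calls
        calls = [
            call(chrom="chrY", scope="whole-chromosome", cn=2),
            call(chrom="chr8", cn=1),
            call(chrom="chr18", cn=3),
        ]
        assert classify(calls) == "numerical+imbalanced"

    def test_permutation_invariance(self):
        calls = [
            call(chrom="chr1", scope="whole-chromosome"),
            call(chrom="chr2"),
            call(chrom="chr3", scope="whole-chromosome", cn=1),
        ]
        expected = classify(calls)
        for perm in itertools.permutations(calls):
            assert classify(list(perm)) == expected


class TestFormatCall:
    def test_published_call_strings(self, hg18_genome):
        c1 = CnvCall("chr2", 182458385, 242690112, 1, "segmental")
        assert (
            format_call(c1, hg18_genome)
            == "seq 2q31.3 → qter(182458386–242690112)×1"
        )
        c2 = CnvCall("chr1", 181509439, 246832193, 3, "segmental")
        assert (
            format_call(c2, hg18_genome)
            == "seq 1q25.3 → qter(181509440–246832193)×3"
        )
        c3 = CnvCall("chr2", 0, 34106490, 3, "segmental")
        assert format_call(c3, hg18_genome) == "seq 2pter → p22.3(1–34106490)×3"

    def test_whole_chromosome_terminal_bands(self, hg18_genome):
        c = CnvCall("chr2", 0, HG18_CHR2_LEN, 3, "whole-chromosome")
        assert (
            format_call(c, hg18_genome)
            == f"seq 2pter → qter(1–{HG18_CHR2_LEN})×3"
        )

    def test_interior_call_single_band(self, hg18_genome):
        c = CnvCall("chr2", 185_000_000, 190_000_000, 1, "segmental")  # in 2q32.1
        s = format_call(c, hg18_genome)
        assert s == "seq 2q32.1 → q32.1(185000001–190000000)×1"

    def test_synthetic_band_names(self, genome20):
        c = CnvCall("chr1", 0, 20_000_000, 3, "whole-chromosome")
        assert format_call(c, genome20) == "seq 1pter → qter(1–20000000)×3"

    def test_call_outside_band_coverage(self, hg18_genome):
        c = CnvCall("chr2", 0, HG18_CHR2_LEN + 5, 3, "whole-chromosome")
        with pytest.raises(AnnotationError):
            format_call(c, hg18_genome)

    @pytest.mark.parametrize(
        "c",
        [
            CnvCall("chr2", 182458385, 242690112, 1, "segmental"),
            CnvCall("chr1", 0, 247_249_719, 3, "whole-chromosome"),
            CnvCall("chr2", 185_000_000, 190_000_000, 4, "segmental"),
        ],
    )
    def test_round_trip(self, c, hg18_genome):
        parsed = parse_call(format_call(c, hg18_genome))
        assert parsed["chrom"] == c.chrom.removeprefix("chr")
        assert parsed["start_bp"] == c.start_bp
        assert parsed["end_bp"] == c.end_bp
        assert parsed["copy_number"] == c.copy_number


class TestEndToEndDeletion:
    def test_five_mb_deletion_recovered(self):
        spec = SyntheticGenomeSpec(
            autosome_lengths=(40_000_000,) * 4, include_sex_chromosomes=False
        )
        g = make_synthetic_genome(spec, seed=5)
        truth = ("chr3", 10_000_000, 15_000_000, 1)
        kar = KaryotypeSpec(events=(truth,))
        reads = simulate_reads(g, kar, ReadSimConfig(seed=17))
        res = run_embryo(reads, g, PipelineConfig(write_plots=False), sample_id="del5")
        assert res.classification == "imbalanced"
        assert len(res.calls) == 1
        c = res.calls[0]
        assert c.chrom == "chr3" and c.copy_number == 1 and c.scope == "segmental"
        assert reciprocal_overlap(truth[1], truth[2], c.start_bp, c.end_bp) >= 0.8
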