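"""Rate-table calibration, class-conditional geometry, count dispersion and
full-study generation."""

import numpy as np
import pandas as pd
import pytest

from spinemorph import (
    StudyConfig,
    calibrate_rate_table,
    classify_spine,
    generate_study,
    sample_geometry,
    sample_segment,
)
from spinemorph.classify import CLASS_LABELS
from spinemorph.synthetic import (
    CalibrationError,
    PRINTED_POOLED,
    PRINTED_TOTALS,
    sample_count,
    segment_to_morphology,
)
from spinemorph.morphology import SPINE_TAG, save_swc, load_swc


class TestCalibration:
    def test_derived_cells_close_the_rows(self, rate_table):
        """The constrained fill reproduces the arithmetic completion."""
        expected = {
            ("glass", "S"): 1.24,
            ("elver", "F"): 0.06,
            ("elver", "S"): 1.03,
            ("elver", "LT"): 1.03,
            ("yellow", "F"): 0.03,
            ("yellow", "LT"): 0.92,
            ("silver", "F"): 0.01,
            ("silver", "LT"): 1.53,
        }
        for (stage, cls), val in expected.items():
            assert rate_table.rate(stage, cls) == pytest.approx(val, abs=1e-9)
            assert rate_table.provenance.loc[stage, cls] == "derived"

    def test_row_sums_match_stage_totals(self, rate_table):
        for stage, total in PRINTED_TOTALS.items():
            assert rate_table.row_total(stage) == pytest.approx(total, abs=0.02)

    def test_pooled_class_means_match(self, rate_table):
        for cls, val in PRINTED_POOLED.items():
            tol = 0.01 if cls == "F" else 0.02
            assert rate_table.pooled_mean(cls) == pytest.approx(val, abs=tol)

    def test_qualitative_equalities(self, rate_table):
        # S and LT statistically indistinguishable in elver and similar in silver
        assert rate_table.rate("elver", "S") == pytest.approx(
            rate_table.rate("elver", "LT")
        )
        assert abs(rate_table.rate("silver", "S") - rate_table.rate("silver", "LT")) < 0.2
        # filopodia fade monotonically across stages
        f = [rate_table.rate(s, "F") for s in ("glass", "elver", "yellow", "silver")]
        assert all(a > b for a, b in zip(f, f[1:]))

    def test_infeasible_printed_values_raise(self):
        bad = {"glass": {"M": 7.0, "LT": 2.60, "F": 0.18}}  # M alone exceeds total
        with pytest.raises(CalibrationError):
            calibrate_rate_table(printed={**bad})

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate_table(phi=0.0)


class TestSampleCount:
    @pytest.mark.parametrize("phi", [0.5, 1.0, 2.0])
    def test_mean_and_dispersion(self, phi, rng):
        mean = 6.67
        draws = np.array([sample_count(mean, phi, rng) for _ in range(20000)])
        se = np.sqrt(phi * mean / draws.size)
        assert draws.mean() == pytest.approx(mean, abs=4 * se)
        assert draws.var() == pytest.approx(phi * mean, rel=0.15)

    def test_zero_rate_never_emits(self, rng):
        assert all(sample_count(0.0, 1.0, rng) == 0 for _ in range(100))


class TestSampleGeometry:
    @pytest.mark.parametrize("cls", CLASS_LABELS)
    def test_round_trip_is_exact(self, cls, rng):
        for _ in range(10_000):
            m = sample_geometry(cls, rng)
            assert classify_spine(m).reported == cls

    def test_stubby_lengths_sub_micron(self, rng):
        lengths = [sample_geometry("S", rng).total_length for _ in range(2000)]
        assert max(lengths) < 1.0

    def test_filopodia_lengths_over_ten_micron(self, rng):
        lengths = [sample_geometry("F", rng).total_length for _ in range(2000)]
        assert min(lengths) > 10.0

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_geometry("X", rng)


class TestSampleSegment:
    def test_total_count_mean_recovered(self, rate_table):
        """Glass-rate segments of exactly 10 µm: empirical mean count within
        3 Poisson standard errors of 6.67 over 10,000 draws."""
        rng = np.random.default_rng(11)
        n = 10_000
        counts = [
            len(sample_segment("glass", rate_table, 10.0, rng, with_geometry=False).spines)
            for _ in range(n)
        ]
        se = np.sqrt(6.67 / n)
        assert np.mean(counts) == pytest.approx(6.67, abs=3 * se)

    def test_zero_rate_table_gives_no_spines(self, rate_table):
        zero = calibrate_rate_table(
            printed={s: {c: 0.0 for c in CLASS_LABELS} for s in PRINTED_TOTALS},
            totals={s: 0.0 for s in PRINTED_TOTALS},
            pooled={c: 0.0 for c in CLASS_LABELS},
            derived_f={},
        )
        rng = np.random.default_rng(12)
        seg = sample_segment("glass", zero, 12.0, rng)
        assert seg.spines == []

    def test_same_seed_identical_segment(self, rate_table):
        a = sample_segment("glass", rate_table, 12.0, np.random.default_rng(13))
        b = sample_segment("glass", rate_table, 12.0, np.random.default_rng(13))
        np.testing.assert_array_equal(a.points, b.points)
        assert a.spines == b.spines

    def test_arc_length_matches_request(self, rate_table):
        seg = sample_segment("glass", rate_table, 12.5, np.random.default_rng(14))
        assert seg.arc_length == pytest.approx(12.5, rel=1e-9)


class TestGenerateStudy:
    def test_default_study_shape(self, small_study):
        assert len(small_study.segments) == 308
        assert len(small_study.animals) == 19
        per_stage = pd.Series([s.stage for s in small_study.segments]).value_counts()
        assert set(per_stage) == {77}
        assert small_study.animals["stage"].value_counts().to_dict() == {
            "glass": 5, "elver": 5, "yellow": 5, "silver": 4,
        }

    def test_segments_reference_existing_animals(self, small_study):
        animals = set(small_study.animals["animal_id"])
        stage_of = dict(
            zip(small_study.animals["animal_id"], small_study.animals["stage"])
        )
        for seg in small_study.segments:
            assert seg.animal_id in animals
            assert stage_of[seg.animal_id] == seg.stage

    def test_biometrics_positive(self, small_study):
        assert (small_study.animals[["TL_cm", "TW_g", "BW_g"]] > 0).all().all()

    def test_same_seed_reproduces_dataset(self):
        a = generate_study(StudyConfig(seed=21, segments_per_stage=5))
        b = generate_study(StudyConfig(seed=21, segments_per_stage=5))
        pd.testing.assert_frame_equal(a.animals, b.animals)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            assert sa.spines == sb.spines
        assert a.provenance["config_hash"] == b.provenance["config_hash"]

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            generate_study(StudyConfig())

    def test_segment_lengths_in_configured_range(self, small_study):
        lengths = [s.arc_length for s in small_study.segments]
        assert min(lengths) >= 10.0
        assert max(lengths) <= 14.0


class TestSwcExport:
    def test_segment_swc_round_trip(self, rate_table, tmp_path):
        seg = sample_segment(
            "glass", rate_table, 12.0, np.random.default_rng(15),
            animal_id="glass-a1", segment_id="glass-s001",
        )
        morph = segment_to_morphology(seg)
        spine_nodes = [n for n in morph.nodes if n.structure_tag == SPINE_TAG]
        assert len(spine_nodes) == len(seg.spines)
        p = tmp_path / "seg.swc"
        save_swc(morph, p)
        again = load_swc(p)
        assert again.metadata["stage"] == "glass"
        assert float(again.metadata["arc_length_um"]) == pytest.approx(seg.arc_length)
        assert len(again.nodes) == len(morph.nodes)
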