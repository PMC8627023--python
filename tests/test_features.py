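"""Window arithmetic, the 25-feature extractor, and table round trips."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mexpred.catalog import DataError, GenomicInterval, MicroexonRecord, MicroindelRecord
from mexpred.features import (
    FEATURE_NAMES,
    ArrayConservationTrack,
    ConstantConservation,
    Preprocessor,
    ResidueAnnotation,
    ResidueMapping,
    conservation_positions,
    conservation_window,
    extract_feature_table,
    extract_features,
    read_feature_table,
    read_residue_annotations,
    residue_window,
    write_feature_table,
    write_residue_annotations,
)


def make_deletion(length, start=100, chrom="chr1"):
    return MicroindelRecord(
        GenomicInterval(chrom, start, start + length), "deletion", length
    )


def make_insertion(start=100, chrom="chr1"):
    return MicroindelRecord(GenomicInterval(chrom, start, start), "insertion", 6)


def make_exon(length, start=100, chrom="chr1"):
    return MicroexonRecord(GenomicInterval(chrom, start, start + length), length)


def make_annotation(pC=0.5, pH=0.3, pE=0.2, disorder=0.4, asa=30.0):
    return ResidueAnnotation(pC, pH, pE, disorder, asa)


class TestConservationWindow:
    @pytest.mark.parametrize("n_del,n_window", [(6, 2), (3, 0), (30, 5)])
    def test_deletion_queries_span_plus_flanks(self, n_del, n_window):
        positions = conservation_positions(make_deletion(n_del), n_window)
        assert len(positions) == n_del + 2 * n_window

    @pytest.mark.parametrize("n_window", [0, 1, 2, 4])
    def test_insertion_queries_flanking_pairs(self, n_window):
        positions = conservation_positions(make_insertion(), n_window)
        assert len(positions) == 2 + 2 * n_window
        assert 99 in positions and 100 in positions  # the two flanking bases

    def test_exon_queries_span_plus_flanks(self):
        assert len(conservation_positions(make_exon(9), 2)) == 9 + 2 * 2

    @given(
        length=st.sampled_from([3, 6, 9, 12, 15, 18, 21, 24, 27, 30]),
        n_window=st.integers(min_value=0, max_value=6),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_size_law(self, length, n_window):
        deletion = make_deletion(length, start=50)
        exon = make_exon(length, start=50)
        insertion = make_insertion(start=50)
        assert len(conservation_positions(deletion, n_window)) == length + 2 * n_window
        assert len(conservation_positions(exon, n_window)) == length + 2 * n_window
        assert len(conservation_positions(insertion, n_window)) == 2 + 2 * n_window

    def test_constant_track(self):
        triple = conservation_window(make_deletion(6), ConstantConservation(0.7))
        assert triple == (0.7, 0.7, 0.7)

    def test_matches_brute_force_on_random_track(self, rng):
        track = ArrayConservationTrack({"chr1": rng.normal(size=2000)})
        for _ in range(50):
            length = int(rng.choice([3, 6, 9, 12]))
            start = int(rng.integers(10, 1900))
            record = make_deletion(length, start=start)
            got = conservation_window(record, track, n_window=2)
            # naive recomputation straight from the raw array
            values = [track.arrays["chr1"][p] for p in range(start - 2, start + length + 2)]
            assert got == pytest.approx((max(values), min(values), sum(values) / len(values)))

    def test_all_missing_yields_nan(self):
        track = ArrayConservationTrack({"chr9": np.array([1.0])})
        triple = conservation_window(make_deletion(6, chrom="chr1"), track)
        assert all(math.isnan(v) for v in triple)

    def test_partial_missing_uses_covered_positions(self):
        arr = np.full(200, np.nan)
        arr[100:106] = 2.0
        track = ArrayConservationTrack({"chr1": arr})
        assert conservation_window(make_deletion(6, start=100), track) == (2.0, 2.0, 2.0)


class TestResidueWindow:
    def test_interior_window(self):
        annotations = [make_annotation(asa=i) for i in range(100)]
        mapping = ResidueMapping("p", 10, 13)  # 3 residues at 10..12
        window = residue_window(mapping, annotations, n_window=2)
        assert [a.asa for a in window] == [8, 9, 10, 11, 12, 13, 14]

    def test_left_boundary_truncated(self):
        annotations = [make_annotation() for _ in range(50)]
        window = residue_window(ResidueMapping("p", 0, 3), annotations, n_window=2)
        assert len(window) == 5  # no left flank available

    def test_insertion_mirrors_dna_rule(self):
        annotations = [make_annotation(asa=i) for i in range(50)]
        window = residue_window(ResidueMapping("p", 20, 20), annotations, n_window=2)
        # two flanking residues (19, 20) plus two more on each side
        assert [a.asa for a in window] == [17, 18, 19, 20, 21, 22]

    def test_mapping_outside_protein_is_fatal(self):
        annotations = [make_annotation() for _ in range(10)]
        with pytest.raises(DataError):
            residue_window(ResidueMapping("p", 8, 15), annotations)


class TestResidueAnnotation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ResidueAnnotation(0.5, 0.5, 0.5, 0.1, 1.0)

    def test_pred_class_defaults_to_argmax(self):
        assert make_annotation(0.2, 0.7, 0.1).pred_class == "H"

    def test_argmax_tie_prefers_first_class(self):
        assert ResidueAnnotation(0.4, 0.4, 0.2, 0.1, 1.0).pred_class == "C"


class TestExtractFeatures:
    def test_dimensionality_and_order(self, toy_tracks):
        record = toy_tracks.microexons[0]
        mapping = toy_tracks.exon_mappings[0]
        vector = extract_features(
            record, mapping, toy_tracks.proteins[mapping.protein_id],
            toy_tracks.conservation,
        )
        assert vector.shape == (25,)
        assert len(FEATURE_NAMES) == 25

    def test_probability_aggregates(self):
        probs_H = [0.1, 0.2, 0.9, 0.8, 0.1]
        annotations = [
            ResidueAnnotation(0.9 - h if h < 0.5 else 0.05, h,
                              round(1 - h - (0.9 - h if h < 0.5 else 0.05), 6),
                              0.5, 10.0)
            for h in probs_H
        ]
        mapping = ResidueMapping("p", 2, 3)
        vector = extract_features(
            make_deletion(3), mapping, annotations, ConstantConservation(0.0),
            n_window=2,
        )
        names = list(FEATURE_NAMES)
        assert vector[names.index("ss_prob_max_H")] == pytest.approx(0.9)
        assert vector[names.index("ss_prob_min_H")] == pytest.approx(0.1)
        assert vector[names.index("ss_prob_mean_H")] == pytest.approx(0.42)

    def test_uniform_class_gives_unit_fraction(self):
        annotations = [make_annotation(0.8, 0.1, 0.1) for _ in range(9)]
        vector = extract_features(
            make_exon(9), ResidueMapping("p", 3, 6), annotations,
            ConstantConservation(1.0),
        )
        names = list(FEATURE_NAMES)
        assert vector[names.index("ss_pred_frac_C")] == 1.0
        assert vector[names.index("ss_pred_frac_H")] == 0.0
        assert vector[names.index("ss_pred_frac_E")] == 0.0

    def test_length_features(self):
        annotations = [make_annotation() for _ in range(100)]
        vector = extract_features(
            make_exon(9), ResidueMapping("p", 10, 13), annotations,
            ConstantConservation(0.0),
        )
        names = list(FEATURE_NAMES)
        assert vector[names.index("record_length")] == 9
        assert vector[names.index("protein_length")] == 100
        assert vector[names.index("dist_to_start")] == 10
        assert vector[names.index("dist_to_end")] == 87  # 100 - 12 - 1

    def test_matches_naive_recomputation_on_synthetic_tracks(self, toy_tracks):
        names = list(FEATURE_NAMES)
        for record, mapping in zip(toy_tracks.microexons, toy_tracks.exon_mappings):
            annotations = toy_tracks.proteins[mapping.protein_id]
            vector = extract_features(
                record, mapping, annotations, toy_tracks.conservation, n_window=2
            )
            # independent straightforward recomputation, plain python
            window = annotations[max(mapping.res_start - 2, 0): mapping.res_end + 2]
            arr = toy_tracks.conservation.arrays[record.interval.chrom]
            cons = [arr[p] for p in range(record.interval.start - 2,
                                          record.interval.end + 2)
                    if 0 <= p < arr.size and not math.isnan(arr[p])]
            disorder = [a.disorder for a in window]
            expected = {
                "record_length": record.exon_length,
                "cons_max": max(cons), "cons_min": min(cons),
                "cons_mean": sum(cons) / len(cons),
                "dis_max": max(disorder), "dis_min": min(disorder),
                "dis_mean": sum(disorder) / len(disorder),
                "ss_pred_frac_H": sum(a.pred_class == "H" for a in window) / len(window),
                "ss_prob_mean_E": sum(a.prob_E for a in window) / len(window),
                "asa_max": max(a.asa for a in window),
                "protein_length": len(annotations),
                "dist_to_start": mapping.res_start,
                "dist_to_end": len(annotations) - mapping.res_end,
            }
            for name, value in expected.items():
                assert vector[names.index(name)] == pytest.approx(value), name

    def test_min_le_mean_le_max_everywhere(self, toy_tracks):
        table = extract_feature_table(
            toy_tracks.microexons + toy_tracks.microindels,
            toy_tracks.exon_mappings + toy_tracks.indel_mappings,
            toy_tracks.proteins,
            toy_tracks.conservation,
        )
        triples = [
            ("cons_max", "cons_min", "cons_mean"),
            ("dis_max", "dis_min", "dis_mean"),
            ("asa_max", "asa_min", "asa_mean"),
        ] + [
            (f"ss_prob_max_{c}", f"ss_prob_min_{c}", f"ss_prob_mean_{c}")
            for c in "CHE"
        ]
        for hi, lo, mid in triples:
            assert (table[lo] <= table[mid] + 1e-12).all()
            assert (table[mid] <= table[hi] + 1e-12).all()

    def test_pred_fractions_sum_to_one(self, toy_tracks):
        table = extract_feature_table(
            toy_tracks.microexons, toy_tracks.exon_mappings,
            toy_tracks.proteins, toy_tracks.conservation,
        )
        sums = table[["ss_pred_frac_C", "ss_pred_frac_H", "ss_pred_frac_E"]].sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestFeatureTableIO:
    def test_round_trip_identity(self, toy_tracks, tmp_path, rng):
        table = extract_feature_table(
            toy_tracks.microexons, toy_tracks.exon_mappings,
            toy_tracks.proteins, toy_tracks.conservation,
        )
        labels = rng.integers(0, 2, size=len(table))
        path = tmp_path / "features.tsv"
        write_feature_table(table, path, labels)
        dataset = read_feature_table(path)
        pd.testing.assert_frame_equal(
            dataset.matrix, table, check_names=False, check_exact=False
        )
        assert (dataset.labels == labels).all()

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        table = pd.DataFrame(np.zeros((2, 24)), columns=list(FEATURE_NAMES[:24]))
        table.to_csv(path, sep="\t", index_label="record_id")
        with pytest.raises(DataError, match="dist_to_end"):
            read_feature_table(path)
        extra = pd.DataFrame(np.zeros((2, 26)), columns=list(FEATURE_NAMES) + ["bogus"])
        extra.to_csv(path, sep="\t", index_label="record_id")
        with pytest.raises(DataError):
            read_feature_table(path)

    def test_missing_values_survive_round_trip(self, tmp_path):
        table = pd.DataFrame(
            np.ones((3, 25)), columns=list(FEATURE_NAMES),
            index=["a", "b", "c"],
        )
        table.iloc[1, 2] = np.nan
        path = tmp_path / "na.tsv"
        write_feature_table(table, path)
        dataset = read_feature_table(path)
        assert math.isnan(dataset.matrix.iloc[1, 2])
        assert dataset.matrix.notna().sum().sum() == 74

    def test_residue_annotation_round_trip(self, toy_tracks, tmp_path):
        path = tmp_path / "residues.tsv"
        write_residue_annotations(toy_tracks.proteins, path)
        back = read_residue_annotations(path)
        assert set(back) == set(toy_tracks.proteins)
        original = toy_tracks.proteins["prot0"][0]
        restored = back["prot0"][0]
        assert restored.prob_H == pytest.approx(original.prob_H, abs=1e-5)
        assert restored.pred_class == original.pred_class


class TestPreprocessor:
    def test_source_medians_impute_both_domains(self):
        source = pd.DataFrame({"a": [1.0, 3.0, np.nan], "b": [0.0, 2.0, 4.0]})
        target = pd.DataFrame({"a": [np.nan], "b": [2.0]})
        prep = Preprocessor()
        out_source = prep.fit_transform(source)
        out_target = prep.transform(target)
        assert out_source.notna().all().all()
        # target NaN filled with the *source* median (2.0) then standardized
        assert out_target.loc[0, "a"] == pytest.approx(out_source["a"].iloc[:2].mean(), abs=1e-9)

    def test_standardization_is_source_anchored(self, rng):
        source = pd.DataFrame(rng.normal(5.0, 2.0, size=(200, 3)), columns=list("abc"))
        target = pd.DataFrame(rng.normal(9.0, 2.0, size=(200, 3)), columns=list("abc"))
        prep = Preprocessor()
        out_source = prep.fit_transform(source)
        out_target = prep.transform(target)
        assert np.allclose(out_source.mean(), 0.0, atol=1e-9)
        assert out_target.mean().mean() > 1.0  # shift survives scaling

    def test_constant_column_passes_through(self):
        source = pd.DataFrame({"a": [2.0, 2.0, 2.0]})
        out = Preprocessor().fit_transform(source)
        assert np.allclose(out["a"], 0.0)
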