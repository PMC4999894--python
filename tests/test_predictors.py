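"""Per-residue track predictors: entropy windows, disorder, SS, binding,
annotation and excision semantics."""

import math

import numpy as np
import pytest

from readthrough.config import PredictorConfig, DISORDER_PROPENSITY
from readthrough.predictors import (
    annotate, binding_sites, binding_track, disorder_track, excise,
    export_scores, import_scores, overlay_track, seg_lowcomplexity,
    ss_track, window_entropies)


class TestWindowEntropy:
    @pytest.mark.parametrize("seq,expected", [
        ("A" * 12, 0.0),                      # single symbol
        ("AAAAAACCCCCC", 1.0),                # two symbols 50/50
        ("ACDEFGHIKLMN", math.log2(12)),      # 12 distinct, uniform
    ])
    def test_known_window_entropies(self, seq, expected):
        k2 = window_entropies(seq, 12)
        assert len(k2) == 1
        assert k2[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_direct_computation_on_random_windows(self, rng):
        """Sliding-window entropies equal a from-scratch recomputation."""
        aas = list("ACDEFGHIKLMNPQRSTVWYX")
        for _ in range(50):
            seq = "".join(rng.choice(aas, int(rng.integers(12, 60))))
            k2 = window_entropies(seq, 12)
            for i, val in enumerate(k2):
                window = [c for c in seq[i:i + 12] if c != "X"]
                if not window:
                    expected = 0.0
                else:
                    expected = 0.0
                    for aa in set(window):
                        p = window.count(aa) / len(window)
                        expected -= p * math.log2(p)
                assert val == pytest.approx(expected, abs=1e-9)

    def test_short_sequence_is_one_window(self):
        assert len(window_entropies("AAAA", 12)) == 1

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            window_entropies("", 12)


class TestSegLowComplexity:
    def test_homopolymer_fully_low_complexity(self, pcfg):
        assert seg_lowcomplexity("A" * 12, pcfg).all()

    def test_two_symbol_window_triggers(self, pcfg):
        # K2 = 1.0 bit <= 2.2 trigger
        assert seg_lowcomplexity("AAAAAACCCCCC", pcfg).all()

    def test_all_distinct_not_low_complexity(self, pcfg):
        assert not seg_lowcomplexity("ACDEFGHIKLMN", pcfg).any()

    def test_extension_windows_require_trigger(self, pcfg):
        """Windows below the extend threshold alone (no trigger) stay clean."""
        # 8 distinct residues -> K2 = 3 bits > 2.5: no region at all
        seq = "ACDEFGHI" * 3
        assert not seg_lowcomplexity(seq, pcfg).any()

    def test_x_excluded_from_composition(self, pcfg):
        """An X inside a homopolymer window does not raise its entropy."""
        with_x = seg_lowcomplexity("AAAAAXAAAAAA", pcfg)
        assert with_x.all()


class TestDisorderTrack:
    def test_max_propensity_homopolymer_scores_disordered(self, pcfg):
        best = max(DISORDER_PROPENSITY, key=DISORDER_PROPENSITY.get)
        assert (disorder_track(best * 30, pcfg) > 0.5).all()

    def test_min_propensity_homopolymer_scores_ordered(self, pcfg):
        worst = min(DISORDER_PROPENSITY, key=DISORDER_PROPENSITY.get)
        assert (disorder_track(worst * 30, pcfg) < 0.5).all()

    def test_length_one_sequence(self, pcfg):
        track = disorder_track("P", pcfg)
        assert track.shape == (1,)
        expected = 1.0 / (1.0 + math.exp(
            -pcfg.disorder_logistic_gain *
            (DISORDER_PROPENSITY["P"] - pcfg.disorder_logistic_center)))
        assert track[0] == pytest.approx(expected)

    def test_unknown_residue_errors(self, pcfg):
        with pytest.raises(ValueError):
            disorder_track("ACDZ", pcfg)

    def test_x_equals_propensity_mean_pseudo_residue(self):
        """Replacing X by a pseudo-residue carrying the mean propensity
        leaves the score track unchanged."""
        cfg = PredictorConfig()
        mean = float(np.mean(list(cfg.disorder_propensity.values())))
        cfg_b = PredictorConfig()
        cfg_b.disorder_propensity = dict(cfg.disorder_propensity, B=mean)
        seq = "ACDEFGHXKLMNP"
        np.testing.assert_allclose(
            disorder_track(seq, cfg),
            disorder_track(seq.replace("X", "B"), cfg_b))

    def test_deterministic(self, pcfg):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        np.testing.assert_array_equal(disorder_track(seq, pcfg),
                                      disorder_track(seq, pcfg))


class TestSSTrack:
    def test_helix_homopolymer(self, pcfg):
        # E: helix 1.51 > 1.0, strand 0.37
        assert (ss_track("E" * 20, pcfg) == "H").all()

    def test_strand_homopolymer(self, pcfg):
        # V: strand 1.70 > helix 1.06
        assert (ss_track("V" * 20, pcfg) == "E").all()

    def test_coil_when_both_below_threshold(self, pcfg):
        # G: helix 0.57, strand 0.75 both < 1.0
        assert (ss_track("G" * 20, pcfg) == "C").all()

    def test_tie_above_threshold_goes_to_helix(self):
        cfg = PredictorConfig()
        cfg.ss_helix_propensity = {aa: 1.5 for aa in cfg.ss_helix_propensity}
        cfg.ss_strand_propensity = {aa: 1.5 for aa in cfg.ss_strand_propensity}
        assert (ss_track("ACDEFG", cfg) == "H").all()


class TestBindingTrack:
    def test_ordered_sequence_has_zero_binding(self, pcfg):
        seq = "W" * 30  # minimal disorder propensity -> gate closed
        dis = disorder_track(seq, pcfg)
        assert (dis < pcfg.theta_elm_disorder).all()
        assert (binding_track(seq, dis, pcfg) == 0.0).all()

    def test_disordered_high_interaction_stretch_is_a_site(self):
        cfg = PredictorConfig()
        cfg.binding_interaction_propensity = {
            aa: 1.0 for aa in cfg.binding_interaction_propensity}
        seq = "P" * 30  # maximally disorder-promoting: gate open
        dis = disorder_track(seq, cfg)
        track = binding_track(seq, dis, cfg)
        assert (track >= cfg.theta_binding).all()
        assert binding_sites(track, cfg.theta_binding) == [(0, 30)]

    def test_disordered_low_interaction_stretch_is_not_a_site(self):
        cfg = PredictorConfig()
        cfg.binding_interaction_propensity = {
            aa: -1.0 for aa in cfg.binding_interaction_propensity}
        seq = "P" * 30
        track = binding_track(seq, disorder_track(seq, cfg), cfg)
        assert (track < cfg.theta_binding).all()

    def test_length_mismatch_errors(self, pcfg):
        with pytest.raises(ValueError):
            binding_track("ACDE", np.zeros(3), pcfg)


class TestAnnotateExcise:
    def test_no_pfam_rows_all_false(self, pcfg):
        ann = annotate("p", "ACDEFGHIKL" * 5, (), pcfg)
        assert not ann.pfam.any()

    def test_pfam_spans_union(self, pcfg):
        ann = annotate("p", "A" * 100, [(0, 50), (40, 60)], pcfg)
        assert ann.pfam[:60].all() and not ann.pfam[60:].any()

    def test_pfam_span_outside_errors(self, pcfg):
        with pytest.raises(ValueError):
            annotate("p", "A" * 10, [(5, 20)], pcfg)

    def test_excise_full_span_is_identity(self, pcfg):
        ann = annotate("p", "MKTAYIAKQRQISFVKSHFSRQ", (), pcfg)
        view = excise(ann, (0, ann.length))
        np.testing.assert_array_equal(view.disorder, ann.disorder)
        np.testing.assert_array_equal(view.ss_class, ann.ss_class)

    def test_excise_idempotent(self, pcfg):
        ann = annotate("p", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", (), pcfg)
        once = excise(ann, (5, 20))
        twice = excise(once, (0, 15))
        np.testing.assert_array_equal(once.disorder, twice.disorder)
        assert once.span == twice.span == (5, 20)

    def test_excised_values_are_stored_not_repredicted(self, pcfg):
        """Segment tracks equal the full-protein values at those positions,
        which differ from predicting on the isolated segment (windows cross
        the junction)."""
        cds = "W" * 40   # order-promoting context
        ext = "P" * 15   # disorder-promoting segment
        ann = annotate("p", cds + ext, (), pcfg)
        view = excise(ann, (40, 55))
        np.testing.assert_array_equal(view.disorder, ann.disorder[40:55])
        isolated = disorder_track(ext, pcfg)
        assert not np.allclose(view.disorder, isolated)

    def test_excise_out_of_range_errors(self, pcfg):
        ann = annotate("p", "ACDEFGHIKL", (), pcfg)
        with pytest.raises(ValueError):
            excise(ann, (5, 11))


class TestImportExport:
    def test_round_trip(self, tmp_path, pcfg):
        anns = [annotate(f"p{i}", "ACDEFGHIKLMNPQRSTVWY", (), pcfg)
                for i in range(3)]
        path = tmp_path / "scores.tsv"
        export_scores(path, anns, "disorder")
        loaded = import_scores(path, "disorder")
        for ann in anns:
            np.testing.assert_allclose(loaded[ann.protein_id], ann.disorder)

    def test_overlay_replaces_single_track(self, pcfg):
        ann = annotate("p", "ACDEFGHIKL", (), pcfg)
        new = overlay_track(ann, "disorder", np.full(10, 0.9))
        assert (new.disorder == 0.9).all()
        np.testing.assert_array_equal(new.ss_class, ann.ss_class)

    def test_non_contiguous_positions_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tposition\tvalue\np\t0\t0.5\np\t2\t0.5\n")
        with pytest.raises(ValueError, match="contiguous"):
            import_scores(path, "disorder")

    def test_duplicate_positions_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tposition\tvalue\np\t0\t0.5\np\t0\t0.6\n")
        with pytest.raises(ValueError, match="duplicate"):
            import_scores(path, "disorder")

    def test_score_out_of_range_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tposition\tvalue\np\t0\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            import_scores(path, "disorder")
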