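"""Synthetic bundle generator: determinism, composition recovery, planted
motifs and planted GO enrichment."""

import filecmp
import os

import numpy as np
import pytest
from scipy import stats as sps

from readthrough.config import AMINO_ACIDS, PredictorConfig
from readthrough.motifscan import scan
from readthrough.predictors import disorder_track
from readthrough.synthetic import (
    SynthConfig, background_composition, default_patterns,
    expected_disorder_fraction, extension_composition, generate_bundle,
    plant_go, plant_motifs, sample_extension, _sample_peptide)


class TestConfigInvariants:
    def test_candidates_cannot_exceed_proteins(self):
        with pytest.raises(ValueError):
            SynthConfig(n_proteins=5, n_candidates=6)

    def test_neutral_regime_forbids_shift_and_bias(self):
        with pytest.raises(ValueError):
            SynthConfig(regime="neutral", disorder_shift=0.1)
        with pytest.raises(ValueError):
            SynthConfig(regime="neutral", composition_bias={"P": 2.0})

    def test_nonpositive_bias_weight_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(regime="fly_like", composition_bias={"P": 0.0})


class TestDeterminism:
    def test_same_seed_byte_identical_bundles(self, tmp_path):
        cfg = SynthConfig(seed=1, n_proteins=40, n_candidates=10,
                          motif_plant_rate=4.0, ortholog_pairs=2,
                          go_enrichment_fold=2.0, regime="fly_like")
        dirs = []
        for name in ("a", "b"):
            d = tmp_path / name
            generate_bundle(cfg).write(d)
            dirs.append(d)
        files = sorted(os.listdir(dirs[0]))
        assert files == sorted(os.listdir(dirs[1]))
        for f in files:
            assert filecmp.cmp(dirs[0] / f, dirs[1] / f, shallow=False), f

    def test_different_seeds_differ(self):
        a = generate_bundle(SynthConfig(seed=1, n_proteins=10, n_candidates=2))
        b = generate_bundle(SynthConfig(seed=2, n_proteins=10, n_candidates=2))
        assert a.proteome_records != b.proteome_records


class TestComposition:
    def test_neutral_frequencies_within_3se(self, rng):
        n = 1_000_000
        cfg = SynthConfig()
        comp = background_composition(cfg)
        pep = _sample_peptide(comp, n, rng)
        counts = np.array([pep.count(aa) for aa in AMINO_ACIDS])
        for k, p in zip(counts, comp):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(k / n - p) < 3 * se + 1e-12

    def test_fly_boost_matches_configured_weights(self, rng):
        n = 100_000
        cfg = SynthConfig(regime="fly_like")
        comp = extension_composition(cfg)
        expect = float(sum(comp[AMINO_ACIDS.index(aa)] for aa in "PQRHS"))
        pep = sample_extension("fly_like", n, rng)
        obs = sum(pep.count(aa) for aa in "PQRHS") / n
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(obs - expect) < 3 * se
        # boosted residues really exceed neutral
        assert expect > 0.25 + 3 * se

    def test_yeast_regime_depletes_and_boosts(self):
        comp = extension_composition(SynthConfig(regime="yeast_like"))
        bg = background_composition(SynthConfig())
        for aa in "YLIFC":
            assert comp[AMINO_ACIDS.index(aa)] > bg[AMINO_ACIDS.index(aa)]
        for aa in "AGDEQ":
            assert comp[AMINO_ACIDS.index(aa)] < bg[AMINO_ACIDS.index(aa)]

    def test_chi_square_goodness_of_fit_recovery(self):
        """Sampled frequencies converge on the configured vector."""
        rejections = 0
        comp = background_composition(SynthConfig())
        for seed in range(20):
            r = np.random.default_rng(seed)
            pep = _sample_peptide(comp, 200_000, r)
            counts = np.array([pep.count(aa) for aa in AMINO_ACIDS])
            _, p = sps.chisquare(counts, comp * counts.sum())
            if p <= 0.01:
                rejections += 1
        assert rejections <= 1  # >= 95% of seeds pass

    def test_single_residue_extension(self, rng):
        assert len(sample_extension("neutral", 1, rng)) == 1

    def test_zero_length_errors(self, rng):
        with pytest.raises(ValueError):
            sample_extension("neutral", 0, rng)


class TestDisorderShift:
    def test_calibrated_expected_fraction(self):
        pcfg = PredictorConfig()
        bg_frac = expected_disorder_fraction(
            background_composition(SynthConfig()), pcfg)
        for shift in (0.05, 0.1, 0.2):
            cfg = SynthConfig(regime="fly_like", disorder_shift=shift)
            frac = expected_disorder_fraction(
                extension_composition(cfg, pcfg), pcfg)
            assert frac - bg_frac == pytest.approx(shift, abs=1e-6)

    def test_monotone_downstream_difference(self, rng):
        """Measured disorder-fraction difference grows with the shift."""
        pcfg = PredictorConfig()
        bg = background_composition(SynthConfig())
        diffs = []
        for shift in (0.0, 0.1, 0.2):
            cfg = SynthConfig(
                regime="fly_like" if shift else "neutral",
                disorder_shift=shift)
            comp = extension_composition(cfg, pcfg)
            fr_e = np.mean([
                (disorder_track(_sample_peptide(comp, 60, rng), pcfg) >= 0.5).mean()
                for _ in range(150)])
            fr_b = np.mean([
                (disorder_track(_sample_peptide(bg, 60, rng), pcfg) >= 0.5).mean()
                for _ in range(150)])
            diffs.append(fr_e - fr_b)
        assert diffs[0] < diffs[1] < diffs[2]


class TestPlantMotifs:
    def _exts(self, n, length, seed=0):
        r = np.random.default_rng(seed)
        comp = background_composition(SynthConfig())
        return {f"E{i:03d}": "X" + _sample_peptide(comp, length - 1, r)
                for i in range(n)}

    def test_rate_zero_is_identity(self, rng):
        exts = self._exts(5, 40)
        out, ledger = plant_motifs(exts, default_patterns("fly"), 0.0, rng)
        assert out == exts and ledger == []

    def test_poisson_count_at_rate(self, rng):
        exts = self._exts(100, 50)  # 5,000 pooled residues
        _, ledger = plant_motifs(exts, default_patterns("fly"), 10.0, rng)
        # expectation 500, 3 SD Poisson window (a few skips tolerated below)
        assert abs(len(ledger) - 500) < 3 * np.sqrt(500) + 25

    def test_ledger_entries_rescan_at_recorded_span(self, rng):
        exts = self._exts(50, 40)
        patterns = default_patterns(None)
        out, ledger = plant_motifs(exts, patterns, 8.0, rng)
        by_id = {p.elm_id: p for p in patterns}
        assert ledger
        for ext_id, elm_id, start, end in ledger:
            m = by_id[elm_id].compiled().match(out[ext_id], start)
            assert m is not None and m.start() == start

    def test_oversized_exemplar_skipped_never_truncated(self, rng):
        exts = {"E1": "XAAA"}
        out, ledger = plant_motifs(exts, [p for p in default_patterns(None)
                                          if len(p.exemplar) >= 4],
                                   200.0, rng)
        assert len(out["E1"]) == 4
        assert ledger == []

    def test_exemplar_must_match_own_pattern(self, rng):
        from readthrough.motifscan import MotifPattern
        bad = MotifPattern("bad", "W.W", 1e-3, frozenset({"fly"}), "AAA")
        with pytest.raises(ValueError, match="bad"):
            plant_motifs({"E1": "XAAAA"}, [bad], 1.0, rng)


class TestPlantGo:
    def test_fold_one_matches_background_rate(self, rng):
        cands = [f"C{i}" for i in range(400)]
        others = [f"P{i}" for i in range(2000)]
        go_map, marked = plant_go(cands, cands + others, 5, 1.0, rng,
                                  background_rate=0.1)
        rate_c = np.mean([marked in go_map[c] for c in cands])
        se = np.sqrt(0.1 * 0.9 / len(cands))
        assert abs(rate_c - 0.1) < 3 * se

    def test_fold_three_binomial_expectation(self, rng):
        cands = [f"C{i}" for i in range(200)]
        go_map, marked = plant_go(cands, cands, 3, 3.0, rng,
                                  background_rate=0.1)
        k = sum(marked in go_map[c] for c in cands)
        assert abs(k - 60) < 3 * np.sqrt(200 * 0.3 * 0.7)

    def test_single_term_map(self, rng):
        go_map, marked = plant_go(["C1"], ["C1", "P1"], 1, 2.0, rng)
        terms = {t for ts in go_map.values() for t in ts}
        assert terms <= {marked} and marked is not None

    def test_fold_below_one_errors(self, rng):
        with pytest.raises(ValueError):
            plant_go(["C1"], ["C1"], 2, 0.5, rng)


class TestBundle:
    def test_every_candidate_resolves_in_proteome(self):
        b = generate_bundle(SynthConfig(seed=3, n_proteins=30,
                                        n_candidates=8))
        ids = {pid for pid, _ in b.proteome_records}
        assert all(c.id in ids for c in b.candidates)
        # candidate CDS equals its proteome record
        seqs = dict(b.proteome_records)
        assert all(c.cds_protein == seqs[c.id] for c in b.candidates)

    def test_no_candidates_still_writes_proteome(self, tmp_path):
        cfg = SynthConfig(seed=1, n_proteins=10, n_candidates=0)
        b = generate_bundle(cfg)
        assert b.candidates == []
        b.write(tmp_path)
        assert (tmp_path / "proteome.fasta").stat().st_size > 0
        assert (tmp_path / "candidates.tsv").exists()

    def test_ledger_spans_exactly_planted_items(self):
        cfg = SynthConfig(seed=4, n_proteins=40, n_candidates=10,
                          motif_plant_rate=6.0)
        b = generate_bundle(cfg)
        exts = {c.id: c.extension for c in b.candidates}
        by_id = {p.elm_id: p for p in b.patterns}
        for ext_id, elm_id, start, end in b.motif_ledger:
            hits = scan(ext_id, exts[ext_id], [by_id[elm_id]])
            assert any(h.span[0] == start for h in hits)

    def test_extension_nt_consistent(self):
        b = generate_bundle(SynthConfig(seed=5, n_proteins=20,
                                        n_candidates=5))
        for c in b.candidates:
            assert len(c.extension_nt) == 3 * len(c.extension)
            assert c.extension_nt.startswith("TGA")
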