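"""Profile construction, scoring, sampling and calibration.

The scoring tests compare the dynamic programming against an independent
brute-force path enumeration oracle (tests/_oracles.py) on small models.
"""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from denitscan.errors import BuildError, CalibrationError, SearchError
from denitscan.profile_hmm import (
    ProfileHMM,
    build_profile,
    calibrate_tc,
    calibrate_tc_from_scores,
    forward,
    read_model,
    sample_sequence,
    score_sequence,
    search_proteome,
    sequence_probability,
    shuffle_residues,
    verify_active_site,
    viterbi,
    write_model,
)
from denitscan.seqio import SequenceRecord

from ._oracles import brute_force_scores
from .conftest import make_alignment, reduced_models, single_gene_registry


class TestBuildProfile:
    def test_identical_rows_forced_emissions(self):
        """4 identical ungapped rows: emission = (count + w/20)/(count + w)."""
        msa = make_alignment(["ACDE"] * 4)
        model = build_profile(msa, pseudocount_weight=1.0)
        assert model.M == 4
        e_a = model.match_emissions[1][model.alphabet.index("A")]
        assert e_a == pytest.approx((4 + 1 / 20) / (4 + 1))
        assert e_a == model.match_emissions[1].max()

    def test_low_occupancy_column_becomes_insert(self):
        msa = make_alignment(["A-DE", "A-DE", "A-DE", "ACDE"])
        model = build_profile(msa, match_occupancy=0.5)
        assert model.M == 3  # the 1/4-occupied column is not a match state

    def test_zero_match_columns_rejected(self):
        msa = make_alignment(["-", "-", "A", "-"])
        with pytest.raises(BuildError, match="occupancy"):
            build_profile(msa, match_occupancy=0.5)

    def test_hand_computed_toy_parameters(self, toy_model):
        """Full parameter table of the 2-row 'AC-E'/'ACDE' alignment at w=1,
        against counts worked out by hand from the implied state paths
        (row 1: M1 M2 D3 M4; row 2: M1 M2 M3 M4)."""
        m = toy_model
        assert m.M == 4
        F = lambda a, b: float(Fraction(a, b))
        # begin: counts B->M1 = 2
        assert m.t_mm[0] == pytest.approx(F(7, 9))
        assert m.t_mi[0] == pytest.approx(F(1, 9))
        assert m.t_md[0] == pytest.approx(F(1, 9))
        # node 2: counts M2->M3 = 1, M2->D3 = 1
        assert m.t_mm[2] == pytest.approx(F(4, 9))
        assert m.t_md[2] == pytest.approx(F(4, 9))
        assert m.t_mi[2] == pytest.approx(F(1, 9))
        # node 3: counts M3->M4 = 1 over 3 legal moves
        assert m.t_mm[3] == pytest.approx(F(2, 3))
        # node 4 (last): two legal moves, counts M4->end = 2
        assert m.t_mm[4] == pytest.approx(F(5, 6))
        assert m.t_mi[4] == pytest.approx(F(1, 6))
        # delete node 3: counts D3->M4 = 1 over 2 legal moves
        assert m.t_dm[3] == pytest.approx(F(3, 4))
        assert m.t_dd[3] == pytest.approx(F(1, 4))
        # unobserved insert transitions fall back to the uniform prior
        assert m.t_ii[1] == pytest.approx(0.5)
        # emissions: M1 saw A twice; M3 saw D once
        a = m.alphabet.index
        assert m.match_emissions[1][a("A")] == pytest.approx(F(41, 60))
        assert m.match_emissions[1][a("C")] == pytest.approx(F(1, 60))
        assert m.match_emissions[3][a("D")] == pytest.approx(F(21, 40))

    def test_distributions_sum_to_one_and_build_is_deterministic(self, registry):
        for entry in registry:
            m = entry.model
            assert np.allclose(m.match_emissions[1:].sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(
                (m.t_mm + m.t_mi + m.t_md), 1.0, atol=1e-9
            )
        # determinism: rebuilding the toy gives identical arrays
        msa = make_alignment(["AC-E", "ACDE"])
        m1, m2 = build_profile(msa), build_profile(msa)
        assert np.array_equal(m1.match_emissions, m2.match_emissions)
        assert np.array_equal(m1.t_mm, m2.t_mm)


class TestScoring:
    def test_consensus_scores_positive(self):
        model = build_profile(make_alignment(["ACDE"] * 4))
        bit, _, span = viterbi(model, "ACDE")
        assert bit > 0
        assert span == (1, 4)

    def test_empty_sequence_rejected(self, toy_model):
        with pytest.raises(SearchError):
            viterbi(toy_model, "")
        with pytest.raises(SearchError):
            forward(toy_model, "")

    def test_forward_at_least_viterbi_on_random_sequences(self, toy_model):
        rng = np.random.default_rng(11)
        letters = np.array(list(toy_model.alphabet))
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=rng.integers(1, 12)))
            v = score_sequence(toy_model, seq, "viterbi")
            f = score_sequence(toy_model, seq, "forward")
            assert f >= v - 1e-12

    def test_fast_score_equals_traceback_score(self):
        rng = np.random.default_rng(3)
        for model in reduced_models():
            letters = np.array(list(model.alphabet))
            for _ in range(25):
                seq = "".join(rng.choice(letters, size=rng.integers(1, 9)))
                assert score_sequence(model, seq) == pytest.approx(
                    viterbi(model, seq)[0], abs=1e-9
                )

    def test_viterbi_and_forward_match_brute_force_small(self):
        """Spot-check against the enumeration oracle (full sweep lives in
        the acceptance tests)."""
        model = reduced_models(max_M=3)[2]
        for seq in ("A", "AB", "ABA", "BBBB"):
            vb, fb = brute_force_scores(model, seq)
            assert score_sequence(model, seq, "viterbi") == pytest.approx(vb, abs=1e-9)
            assert score_sequence(model, seq, "forward") == pytest.approx(fb, abs=1e-9)

    def test_single_path_model_forward_equals_viterbi(self):
        """A fully deterministic model has one path, so max == sum."""
        K = 4
        alphabet = "ACDE"
        M = 3
        e = np.zeros((M + 1, K))
        for j, letter in enumerate("ACD", start=1):
            e[j, alphabet.index(letter)] = 1.0
        ones, zeros = np.ones(M + 1), np.zeros(M + 1)
        model = ProfileHMM(
            name="det", alphabet=alphabet, match_emissions=e,
            insert_emissions=np.full(K, 1 / K), background=np.full(K, 1 / K),
            t_mm=ones.copy(), t_mi=zeros.copy(), t_md=zeros.copy(),
            t_im=ones.copy(), t_ii=zeros.copy(),
            t_dm=ones.copy(), t_dd=zeros.copy(),
        )
        v = score_sequence(model, "ACD", "viterbi")
        f = score_sequence(model, "ACD", "forward")
        assert v == f
        assert sample_sequence(model, 0).residues == "ACD"

    def test_score_ignores_record_identity(self, toy_model):
        assert score_sequence(toy_model, "ACDE") == score_sequence(
            toy_model, "ACDE"
        )

    def test_x_scores_as_background_average(self):
        """On a background-flat match state, X contributes zero log-odds."""
        msa = make_alignment(["ACDE"] * 4)
        model = build_profile(msa)
        s_ref = score_sequence(model, "ACDE")
        s_x = score_sequence(model, "ACXE")
        lo_d = np.log2(
            model.match_emissions[3][model.alphabet.index("D")] * 20
        )
        lo_x = np.log2(
            (model.match_emissions[3] @ model.background)
            / (model.background @ model.background)
        )
        assert s_x == pytest.approx(s_ref - lo_d + lo_x, abs=1e-9)


class TestProbabilityConservation:
    def test_mass_bounded_and_approaching_one(self):
        model = reduced_models(max_M=3)[2]
        totals = []
        running = 0.0
        for L in range(0, 9):
            for seq in itertools.product("AB", repeat=L):
                running += sequence_probability(model, "".join(seq))
            totals.append(running)
        assert all(t <= 1.0 + 1e-9 for t in totals)
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        assert totals[-1] > 0.95


class TestSampling:
    def test_fixed_seed_reproducible(self, registry):
        model = registry["qnor"].model
        s1 = sample_sequence(model, 42).residues
        s2 = sample_sequence(model, 42).residues
        assert s1 == s2

    def test_samples_outscore_their_shuffles(self, registry):
        """Mean Viterbi bit of 200 samples exceeds their shuffled versions."""
        model = registry["nosB"].model
        rng = np.random.default_rng(7)
        samples = [sample_sequence(model, rng) for _ in range(200)]
        shuffles = [shuffle_residues(s, rng) for s in samples]
        mean_s = np.mean([score_sequence(model, s.residues) for s in samples])
        mean_n = np.mean([score_sequence(model, s.residues) for s in shuffles])
        assert mean_s > mean_n


class TestCalibration:
    def test_midpoint_of_clean_margin(self):
        tc = calibrate_tc_from_scores({"p1": 50.0, "p2": 60.0}, {"n1": 10.0})
        assert tc == 30.0

    def test_overlap_raises_listing_offenders(self):
        with pytest.raises(CalibrationError) as exc:
            calibrate_tc_from_scores({"p1": 50.0, "p2": 8.0}, {"n1": 10.0})
        roles = {(role, sid) for role, sid, _ in exc.value.overlaps}
        assert ("positive", "p2") in roles
        assert ("negative", "n1") in roles

    def test_calibrated_tc_separates_fresh_samples(self, registry):
        model = registry["nirK"].model
        rng = np.random.default_rng(123)
        pos = [sample_sequence(model, rng) for _ in range(20)]
        neg = [shuffle_residues(p, rng) for p in pos]
        tc = model.tc_bits
        assert all(score_sequence(model, p.residues) >= tc for p in pos)
        assert all(score_sequence(model, n.residues) < tc for n in neg)

    def test_calibrate_sets_tc_on_model(self):
        model = build_profile(make_alignment(["ACDEFGHIKL"] * 6), name="c")
        rng = np.random.default_rng(5)
        pos = [sample_sequence(model, rng) for _ in range(10)]
        # shuffles of a 10-mer over distinct letters can land close to the
        # consensus; use compositionally disjoint negatives instead
        neg = [
            SequenceRecord(f"n{i}", "".join(
                rng.choice(list("MNPQRSTVWY"), size=10)
            ))
            for i in range(10)
        ]
        tc = calibrate_tc(model, pos, neg)
        assert model.tc_bits == tc


class TestActiveSites:
    def test_conserved_residue_found(self):
        model = build_profile(make_alignment(["ACDE"] * 4))
        report = verify_active_site(model, "ACDE", {2: {"C"}})
        assert report.ok

    def test_deleted_match_state_reported(self, toy_model):
        # 'ACE' optimally deletes match state 3 (the weak 'D' column)
        report = verify_active_site(toy_model, "ACE", {3: {"D"}})
        assert not report.ok
        assert "deleted" in report.violations[0]

    def test_wrong_residue_reported(self):
        model = build_profile(make_alignment(["ACDE"] * 4))
        report = verify_active_site(model, "AADE", {2: {"C"}})
        assert not report.ok and "saw 'A'" in report.violations[0]

    def test_out_of_range_index_rejected(self, toy_model):
        with pytest.raises(ValueError):
            verify_active_site(toy_model, "ACDE", {9: {"C"}})


class TestSearchProteome:
    def test_implanted_sample_found_decoys_rejected(self, registry):
        rng = np.random.default_rng(77)
        implant = sample_sequence(registry["qnor"].model, rng)
        implant = SequenceRecord("p_implant", implant.residues)
        decoys = [
            SequenceRecord(f"d{i}", shuffle_residues(implant, rng).residues)
            for i in range(3)
        ]
        hits = search_proteome(registry, [implant] + decoys)
        passing = [h for h in hits if h.passes_tc]
        assert len(passing) == 1
        assert passing[0].protein_id == "p_implant"
        assert passing[0].model_name == "qnor"
        assert passing[0].primary
        assert passing[0].aligned_span is not None

    def test_empty_proteome(self, registry):
        assert search_proteome(registry, []) == []

    def test_uncalibrated_model_rejected(self, toy_model):
        reg = single_gene_registry(toy_model, "nirK", "NIR")
        with pytest.raises(SearchError, match="trusted cutoff"):
            search_proteome(reg, [SequenceRecord("p", "ACDE")])

    def test_primary_tie_breaks_by_registry_order(self, registry):
        """Two identical models: the earlier registry entry wins the tie."""
        from denitscan.registry import GeneModel, GeneModelRegistry

        model = build_profile(make_alignment(["ACDEFGHIKL"] * 4), name="m")
        model.tc_bits = 0.0
        reg = GeneModelRegistry()
        reg.register(GeneModel(gene="nirK", step="NIR", model=model))
        reg.register(GeneModel(gene="nirS", step="NIR", model=model))
        hits = search_proteome(reg, [SequenceRecord("p", "ACDEFGHIKL")])
        primary = [h for h in hits if h.primary]
        assert len(primary) == 1 and primary[0].model_name == "nirK"


class TestSerialization:
    def test_round_trip_preserves_model(self, tmp_path, registry):
        model = registry["snor"].model
        path = tmp_path / "snor.hmm"
        write_model(model, path)
        back = read_model(path)
        assert back.name == model.name and back.M == model.M
        assert back.tc_bits == pytest.approx(model.tc_bits, rel=1e-15)
        assert np.allclose(
            back.match_emissions, model.match_emissions, rtol=1e-13
        )
        assert np.allclose(back.t_md, model.t_md, rtol=1e-13)
        seq = sample_sequence(model, 1).residues
        assert score_sequence(back, seq) == pytest.approx(
            score_sequence(model, seq), abs=1e-9
        )

    def test_uncalibrated_tc_round_trips_as_none(self, tmp_path, toy_model):
        path = tmp_path / "toy.hmm"
        write_model(toy_model, path)
        assert read_model(path).tc_bits is None
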