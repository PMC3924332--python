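"""Profile HMM construction, scoring, decoding, calibration and search."""

import itertools

import numpy as np
import pytest
from scipy import stats

from famfinder.hmm import (
    AA,
    CalibrationError,
    FamilyAlignment,
    ProfileHMM,
    build_profile,
    calibrate,
    evalue,
    fit_gumbel,
    forward_score,
    gumbel_sf,
    hmmprob_score,
    posterior_decode,
    sample_background,
    search,
)

from oracles import enum_forward_normalized, enum_forward_posterior


class TestBuildProfile:
    def test_gap_free_alignment_uses_every_column(self):
        aln = FamilyAlignment("f", [("a", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")] * 5)
        assert build_profile(aln).M == 30

    def test_majority_gap_column_is_not_match(self):
        aln = FamilyAlignment(
            "f",
            [("a", "AC-D"), ("b", "AC-D"), ("c", "AC-D"), ("d", "ACGD")],
        )
        h = build_profile(aln)
        assert h.M == 3 and h.match_columns == [0, 1, 3]

    def test_all_distributions_normalized(self, tiny_profile):
        h = tiny_profile
        assert np.allclose(h.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(h.insert_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(h.tmm + h.tmi + h.tmd + h.p_exit, 1.0, atol=1e-9)
        assert np.allclose(h.tim + h.tii, 1.0, atol=1e-9)
        assert np.allclose(h.tdm + h.tdd, 1.0, atol=1e-9)

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError, match="match columns"):
            build_profile(FamilyAlignment("f", [("a", "---"), ("b", "---")]))

    def test_json_round_trip(self, calibrated_profile):
        back = ProfileHMM.from_json(calibrated_profile.to_json())
        assert back.M == calibrated_profile.M
        assert np.allclose(back.match_emissions, calibrated_profile.match_emissions)
        assert back.calibration == calibrated_profile.calibration
        s = "".join(AA[i % 20] for i in range(25))
        assert forward_score(back, s) == pytest.approx(
            forward_score(calibrated_profile, s)
        )


@pytest.fixture(scope="module")
def small_profiles():
    alns = [
        FamilyAlignment("p2", [("a", "AC"), ("b", "AD"), ("c", "CC")]),
        FamilyAlignment(
            "p3", [("a", "ACD"), ("b", "A-D"), ("c", "ECD"), ("d", "ACF")]
        ),
        FamilyAlignment(
            "p4",
            [("a", "ACDE"), ("b", "ACDE"), ("c", "AKDE"), ("d", "AC-E")],
        ),
    ]
    return [build_profile(a) for a in alns]


class TestForwardOracle:
    """Forward probability and posteriors against exhaustive enumeration."""

    def test_forward_and_posteriors_match_enumeration(self, small_profiles):
        """All sequences of length <= 5 over a 4-letter reduced alphabet."""
        letters = "ACDE"
        for h in small_profiles:
            for L in range(1, 6):
                for tup in itertools.product(letters, repeat=L):
                    seq = "".join(tup)
                    ref_bits, ref_pm, ref_pi = enum_forward_normalized(h, seq)
                    got = forward_score(h, seq)
                    assert got == pytest.approx(ref_bits, rel=1e-9, abs=1e-9)
                    dec = posterior_decode(h, seq)
                    assert np.allclose(
                        dec.post_match, ref_pm.sum(axis=1), atol=1e-9
                    )
                    assert np.allclose(
                        dec.post_core,
                        ref_pm.sum(axis=1) + ref_pi.sum(axis=1),
                        atol=1e-9,
                    )

    def test_viterbi_never_exceeds_forward(self, small_profiles):
        rng = np.random.default_rng(4)
        for h in small_profiles:
            for _ in range(50):
                seq = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 12)))
                dec = posterior_decode(h, seq)
                assert dec.viterbi_bits <= dec.bit_score + 1e-9

    def test_posteriors_within_unit_interval(self, calibrated_profile):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(AA[i] for i in rng.integers(0, 20, 50))
            dec = posterior_decode(calibrated_profile, seq)
            assert np.all(dec.post_core >= 0) and np.all(dec.post_core <= 1)
            assert np.all(dec.post_match <= dec.post_core + 1e-12)


class TestScoring:
    def test_consensus_beats_reversed_consensus(self, calibrated_profile):
        cons = calibrated_profile.consensus()
        assert forward_score(calibrated_profile, cons) > forward_score(
            calibrated_profile, cons[::-1]
        )

    def test_all_x_scores_at_most_zero(self, calibrated_profile):
        assert forward_score(calibrated_profile, "X" * 30) <= 0.0

    def test_empty_sequence_rejected(self, calibrated_profile):
        with pytest.raises(ValueError):
            forward_score(calibrated_profile, "")

    def test_consensus_mean_posterior_exceeds_random(self, calibrated_profile):
        rng = np.random.default_rng(6)
        cons = calibrated_profile.consensus()
        rand = "".join(AA[i] for i in rng.integers(0, 20, len(cons)))
        pc = posterior_decode(calibrated_profile, cons).post_core.mean()
        pr = posterior_decode(calibrated_profile, rand).post_core.mean()
        assert pc > pr

    def test_hmmprob_bounded_by_length(self, calibrated_profile):
        cons = calibrated_profile.consensus()
        score = hmmprob_score(cons, calibrated_profile)
        assert 0 < score <= len(cons)

    def test_hmmprob_zero_for_unrelated_sequence(self, calibrated_profile):
        assert hmmprob_score("X" * 40, calibrated_profile) == 0.0

    def test_hmmprob_matches_enumeration_on_tiny_profile(self):
        aln = FamilyAlignment(
            "p3", [("a", "WCD"), ("b", "WCD"), ("c", "WCD"), ("d", "WCF")]
        )
        h = build_profile(aln)
        seq = "WCD"
        _, pm, _ = enum_forward_posterior(h, seq)
        dec = posterior_decode(h, seq)
        i0, i1 = dec.target_interval
        assert hmmprob_score(seq, h) == pytest.approx(
            float(pm.sum(axis=1)[i0:i1].sum()), abs=1e-6
        )


class TestCalibration:
    def test_gumbel_ml_recovery(self):
        rng = np.random.default_rng(0)
        draws = stats.gumbel_r.rvs(loc=5.0, scale=1 / 0.7, size=5000, random_state=rng)
        mu, lam = fit_gumbel(draws)
        assert abs(mu - 5.0) / 5.0 < 0.05
        assert abs(lam - 0.7) / 0.7 < 0.05

    def test_same_seed_same_parameters(self, family40):
        h1, h2 = build_profile(family40), build_profile(family40)
        c1 = calibrate(h1, decoy_n=300, decoy_len=30, seed=9)
        c2 = calibrate(h2, decoy_n=300, decoy_len=30, seed=9)
        assert c1 == c2

    def test_more_decoys_shrink_mu_standard_error(self, family40):
        mus = {n: [] for n in (200, 800)}
        for n in mus:
            for rep in range(6):
                h = build_profile(family40)
                cal = calibrate(h, decoy_n=n, decoy_len=30, seed=100 + rep, tail_frac=1.0)
                mus[n].append(cal.mu)
        assert np.std(mus[800]) < np.std(mus[200])

    def test_degenerate_scores_rejected(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.zeros(100), tail_frac=0.25)

    def test_small_decoy_count_rejected(self, tiny_profile):
        with pytest.raises(ValueError):
            calibrate(tiny_profile, decoy_n=10)


class TestSearch:
    def test_uncalibrated_profile_rejected(self, family40):
        h = build_profile(family40)
        with pytest.raises(RuntimeError):
            search(h, [("s", "ACDEF" * 5)])

    def test_planted_consensus_is_top_hit(self, calibrated_profile):
        rng = np.random.default_rng(7)
        db = [(f"d{i}", s) for i, s in enumerate(
            sample_background(rng, 100, 60, calibrated_profile.background)
        )]
        db.append(("planted", calibrated_profile.consensus()))
        hits = search(calibrated_profile, db, e_max=10.0)
        assert hits and hits[0].target_id == "planted"

    def test_database_duplication_doubles_evalues(self, calibrated_profile):
        s = calibrated_profile.consensus()
        score = forward_score(calibrated_profile, s)
        e1 = evalue(calibrated_profile, score, 100)
        e2 = evalue(calibrated_profile, score, 200)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_evalue_monotone_in_score(self, calibrated_profile):
        es = [evalue(calibrated_profile, s, 100) for s in np.linspace(-5, 50, 40)]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_generous_threshold_retains_weak_hits(self, calibrated_profile):
        """The initial scan keeps hits the strict final cutoff would reject."""
        rng = np.random.default_rng(8)
        cons = calibrated_profile.consensus()
        weak = "".join(
            c if rng.random() < 0.3 else AA[rng.integers(0, 20)] for c in cons
        )
        db = [("weak", weak)]
        loose = search(calibrated_profile, db, e_max=10.0)
        strict = search(calibrated_profile, db, e_max=0.001)
        assert [h.target_id for h in loose] == ["weak"]
        assert strict == []

    def test_hit_carries_intervals_and_posteriors(self, calibrated_profile):
        hits = search(calibrated_profile, [("c", calibrated_profile.consensus())])
        h = hits[0]
        i0, i1 = h.target_interval
        assert 0 <= i0 < i1 <= len(calibrated_profile.consensus())
        assert h.profile_interval[1] - h.profile_interval[0] > 40
        assert len(h.posteriors) == i1 - i0
        assert np.all((h.posteriors >= 0) & (h.posteriors <= 1))


@pytest.mark.parametrize("conservation", [0.95])
def test_agreement_with_external_hmmer_engine(conservation):
    """Cross-check hit discrimination against an independent HMMER engine."""
    pyhmmer = pytest.importorskip("pyhmmer")
    from famfinder import make_family

    fam = make_family(n_members=20, length=50, conservation=conservation, seed=21)
    prof = build_profile(fam)
    calibrate(prof, decoy_n=300, decoy_len=30, seed=0)
    rng = np.random.default_rng(22)
    decoys = sample_background(rng, 50, 50, prof.background)
    targets = [("planted", prof.consensus())] + [
        (f"d{i}", s) for i, s in enumerate(decoys)
    ]

    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=b"fam",
        sequences=[
            pyhmmer.easel.TextSequence(name=n.encode(), sequence=s)
            for n, s in fam.members
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), pyhmmer.plan7.Background(alphabet))
    seqs = [
        pyhmmer.easel.TextSequence(name=n.encode(), sequence=s).digitize(alphabet)
        for n, s in targets
    ]
    top_hits = list(pyhmmer.hmmsearch([hmm], seqs))[0]
    if len(top_hits):
        name = top_hits[0].name
        hmmer_best = name.decode() if isinstance(name, bytes) else name
    else:
        hmmer_best = None

    ours = search(prof, targets, e_max=10.0)
    assert ours[0].target_id == "planted"
    assert hmmer_best == "planted"


def test_external_search_engine_seam(calibrated_profile):
    from famfinder import hmm as H

    sentinel = []
    try:
        H.set_search_engine(lambda prof, db, e_max, n_db: sentinel)
        assert search(calibrated_profile, [("s", "ACDEF" * 4)]) is sentinel
    finally:
        H.set_search_engine(None)
    assert isinstance(search(calibrated_profile, [("s", "ACDEF" * 4)]), list)
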