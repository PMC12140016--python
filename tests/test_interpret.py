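"""Attribution stack: perturbation scores, PWM scanning, aggregation."""

import numpy as np
import pandas as pd
import pytest

from tirem import interpret as itp
from tirem.model import logit

MOTIF = "CACCTG"
L = 201


def strip_motif(seq: str, motif: str = MOTIF) -> str:
    """Remove chance occurrences by rewriting one base of each hit."""
    seq = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        j = s.find(motif)
        if j >= 0:
            seq[j] = "T" if seq[j] != "T" else "A"
            changed = True
    return "".join(seq)


@pytest.fixture
def motif_sequence():
    rng = np.random.default_rng(0)
    seq = strip_motif("".join(rng.choice(list("ACGT"), L)))
    return seq[:90] + MOTIF + seq[96:]


def stub_scorer(seqs):
    return np.array([0.9 if MOTIF in s else 0.1 for s in seqs])


class TestHexamerImportance:
    def test_stub_scorer_closed_form(self, motif_sequence):
        track = itp.hexamer_importance(stub_scorer, motif_sequence, C=100,
                                       seed=1)
        expected = logit(0.9) - logit(0.1)  # ~4.394
        overlap = np.arange(85, 96)  # hexamer windows meeting [90, 96)
        np.testing.assert_allclose(track.values[overlap], expected,
                                   atol=1e-9)
        rest = np.setdiff1d(np.arange(196), overlap)
        np.testing.assert_allclose(track.values[rest], 0.0, atol=1e-12)

    def test_low_confidence_sequence_gated_to_zero(self, motif_sequence):
        seq = strip_motif(motif_sequence)
        track = itp.hexamer_importance(stub_scorer, seq, C=20, seed=2)
        assert track.valid == 0
        np.testing.assert_array_equal(track.values, 0.0)

    def test_constant_scorer_gives_zero_everywhere(self, motif_sequence):
        constant = lambda seqs: np.full(len(seqs), 0.8)
        track = itp.hexamer_importance(constant, motif_sequence, C=10, seed=3)
        assert track.valid == 1
        np.testing.assert_allclose(track.values, 0.0, atol=1e-12)

    def test_median_robust_to_perturbation_count(self, motif_sequence):
        t100 = itp.hexamer_importance(stub_scorer, motif_sequence, C=100,
                                      seed=4)
        t1001 = itp.hexamer_importance(stub_scorer, motif_sequence, C=1001,
                                       seed=4)
        np.testing.assert_allclose(t100.values, t1001.values, atol=1e-9)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            itp.hexamer_importance(stub_scorer, "ACGT" * 10, C=5, seed=0)


JASPAR_BRACKETED = """>MA0004.1 Arnt
A  [ 4 19  0  0  0  0 ]
C  [16  0 20  0  0  0 ]
G  [ 0  1  0 20  0 20 ]
T  [ 0  0  0  0 20  0 ]
"""

JASPAR_RAW = """>MA0004.1 Arnt
4 19 0 0 0 0
16 0 20 0 0 0
0 1 0 20 0 20
0 0 0 0 20 0
"""


class TestJaspar:
    def test_both_dialects_parse_identically(self, tmp_path):
        for name, text in (("b.jaspar", JASPAR_BRACKETED),
                           ("r.jaspar", JASPAR_RAW)):
            path = tmp_path / name
            path.write_text(text)
            motifs = itp.read_jaspar(path)
            assert len(motifs) == 1
            m = motifs[0]
            assert (m.tf_id, m.tf_name) == ("MA0004.1", "Arnt")
            np.testing.assert_array_equal(
                m.pfm[0], [4, 19, 0, 0, 0, 0])

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.jaspar"
        path.write_text("")
        assert itp.read_jaspar(path) == []

    def test_round_trip_two_column_toy(self, tmp_path):
        toy = itp.MotifModel(tf_id="T1", tf_name="toy", family="f",
                             tf_class="c",
                             pfm=np.array([[3.0, 0], [1, 2], [0, 1],
                                           [0, 1]]))
        path = tmp_path / "toy.jaspar"
        itp.write_jaspar([toy], path)
        back = itp.read_jaspar(path)
        np.testing.assert_array_equal(back[0].pfm, toy.pfm)

    def test_metadata_join_and_unknown_fallback(self, tmp_path):
        pfm = tmp_path / "m.jaspar"
        pfm.write_text(JASPAR_BRACKETED + "\n>MA0099.1 Other\n"
                       "A [ 1 1 1 1 1 1 ]\nC [ 1 1 1 1 1 1 ]\n"
                       "G [ 1 1 1 1 1 1 ]\nT [ 1 1 1 1 1 1 ]\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text("tf_id\tname\tfamily\tclass\n"
                        "MA0004.1\tArnt\tPAS\tbHLH\n")
        motifs = itp.read_jaspar(pfm, meta)
        assert motifs[0].family == "PAS" and motifs[0].tf_class == "bHLH"
        assert motifs[1].family == "unknown"

    def test_bad_metadata_columns_rejected(self, tmp_path):
        pfm = tmp_path / "m.jaspar"
        pfm.write_text(JASPAR_BRACKETED)
        meta = tmp_path / "meta.tsv"
        meta.write_text("id\tfam\n")
        with pytest.raises(ValueError):
            itp.read_jaspar(pfm, meta)


class TestPfmToPwm:
    def test_hand_column(self):
        ppm, pwm = itp.pfm_to_pwm(np.array([[10.0], [0], [0], [0]]))
        assert ppm[0, 0] == pytest.approx(10.5 / 12)
        assert pwm[0, 0] == pytest.approx(np.log(3.5), abs=1e-9)

    def test_uniform_column_is_zero_log_odds(self):
        ppm, pwm = itp.pfm_to_pwm(np.full((4, 3), 7.0))
        np.testing.assert_allclose(ppm, 0.25)
        np.testing.assert_allclose(pwm, 0.0, atol=1e-12)

    def test_columns_normalize(self):
        rng = np.random.default_rng(6)
        pfm = rng.integers(0, 30, (4, 9)).astype(float)
        ppm, _ = itp.pfm_to_pwm(pfm)
        np.testing.assert_allclose(ppm.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            itp.pfm_to_pwm(np.zeros((4, 2)), alpha=0.0)


def consensus_motif(consensus: str, strength: float = 97.0) -> itp.MotifModel:
    idx = {b: i for i, b in enumerate("ACGT")}
    pfm = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = strength
    return itp.MotifModel(tf_id=f"SYN_{consensus}", tf_name=consensus,
                          family="synthetic", tf_class="synthetic", pfm=pfm)


class TestScan:
    def test_uniform_pwm_never_hits(self):
        m = itp.MotifModel(tf_id="U", tf_name="u", family="f", tf_class="c",
                           pfm=np.full((4, 5), 3.0))
        assert itp.scan(m, "ACGTACGTACGT") == []

    def test_strong_consensus_hits_at_threshold(self):
        # 8 columns, each ln(3.5) for its consensus base: score ~10.02
        pfm = np.zeros((4, 8))
        pfm[0] = 10.0  # consensus AAAAAAAA
        m = itp.MotifModel(tf_id="A8", tf_name="a8", family="f",
                           tf_class="c", pfm=pfm)
        hits = {h.start: h for h in itp.scan(m, "GGAAAAAAAAGG")}
        assert 2 in hits  # the exact consensus window
        assert hits[2].score == pytest.approx(8 * np.log(3.5), abs=1e-9)
        assert hits[2].standardized >= 0.999
        assert 0 not in hits  # two mismatches fall below the cutoff

    def test_matches_bruteforce_all_substrings(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            L_n = int(rng.integers(4, 12))
            pfm = rng.integers(0, 40, (4, L_n)).astype(float)
            m = itp.MotifModel(tf_id="R", tf_name="r", family="f",
                               tf_class="c", pfm=pfm)
            seq = "".join(rng.choice(list("ACGT"), 80))
            idx = {b: i for i, b in enumerate("ACGT")}
            expected = []
            for j in range(80 - L_n + 1):
                score = sum(m.pwm[idx[c], k]
                            for k, c in enumerate(seq[j:j + L_n]))
                if 1 / (1 + np.exp(-score)) >= 0.999:
                    expected.append((j, score))
            hits = itp.scan(m, seq)
            assert [(h.start,) for h in hits] == [(j,) for j, _ in expected]
            for h, (_, sc) in zip(hits, expected):
                assert h.score == pytest.approx(sc, abs=1e-9)

    def test_non_acgt_rejected(self):
        m = consensus_motif("CACCTG")
        with pytest.raises(ValueError):
            itp.scan(m, "ACGNACGT")

    def test_reverse_complement_flag(self):
        m = consensus_motif("CACCTG")
        seq = "TT" + "CAGGTG" + "TTTT"  # revcomp of CACCTG at offset 2
        assert itp.scan(m, seq) == []
        hits = itp.scan(m, seq, reverse_complement=True)
        assert [h.start for h in hits] == [2]


class TestTfImportance:
    def _track(self, values):
        vals = np.zeros(196)
        vals[:len(values)] = values
        return itp.HexamerImportanceTrack(seq_id=0, values=vals, valid=1,
                                          base_probability=0.9)

    def test_hexamer_length_motif_is_single_term(self):
        track = self._track([5.0, 1.0])
        hit = itp.MotifHit(seq_id=0, start=0, tf_id="x", score=9.0,
                           standardized=0.9999)
        assert itp.tf_importance(track, hit, L_n=6) == 5.0

    def test_mean_over_footprint(self):
        track = self._track([1.0, 2.0, 3.0])
        hit = itp.MotifHit(seq_id=0, start=0, tf_id="x", score=9.0,
                           standardized=0.9999)
        assert itp.tf_importance(track, hit, L_n=8) == pytest.approx(2.0)

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError):
            itp.tf_importance(self._track([1.0]), itp.MotifHit(0, 0, "x", 9,
                                                               0.9999), L_n=5)

    def test_invalid_sequence_propagates_zero(self, ):
        rng = np.random.default_rng(8)
        seq = strip_motif("".join(rng.choice(list("ACGT"), 201)))
        seq = seq[:50] + "AAAAAAAA" + seq[58:]
        track = itp.HexamerImportanceTrack(seq_id=0, values=np.zeros(196),
                                           valid=0, base_probability=0.2)
        m = consensus_motif("AAAAAAAA")
        table = itp.hit_table([track], [m], [seq])
        assert (table["valid"] == 0).all()
        assert (table["is_tf"] == 0.0).all()


class TestAggregate:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["seq_id", "j", "tf_id", "family",
                                           "class", "score", "standardized",
                                           "is_tf", "valid"])

    def test_single_hit_passthrough(self):
        t = self._table([(0, 5, "a", "F1", "C1", 9.0, 0.9999, 2.5, 1)])
        tracks = itp.aggregate(t, "family")
        assert tracks[0].group == "F1"
        assert tracks[0].values[5] == 2.5
        assert tracks[0].n_bindings == 1

    def test_two_hits_average(self):
        t = self._table([(0, 5, "a", "F1", "C1", 9.0, 0.9999, 1.0, 1),
                         (1, 5, "b", "F1", "C1", 9.0, 0.9999, 3.0, 1)])
        assert itp.aggregate(t, "family")[0].values[5] == pytest.approx(2.0)

    def test_unbound_positions_missing_not_zero(self):
        t = self._table([(0, 5, "a", "F1", "C1", 9.0, 0.9999, 1.0, 1)])
        values = itp.aggregate(t, "family")[0].values
        assert np.isnan(values[4]) and np.isnan(values[6])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            itp.aggregate(self._table([]), "family")
        with pytest.raises(ValueError):
            itp.aggregate(self._table([(0, 5, "a", "F", "C", 9, 0.9999,
                                        1.0, 1)]), "species")

    def test_selection_filters(self):
        mk = lambda g, vals: itp.AggregateTrack(
            group=g, values=np.array(vals + [np.nan] * (196 - len(vals))),
            n_bindings=len(vals))
        tracks = [mk("hi", [9.0, -1.0]), mk("pos", [1.0, 2.0]),
                  mk("sum", [4.0, 4.0])]
        top = itp.select_tracks(tracks, "top_individual", k=1)
        assert top[0].group == "hi"
        cum = itp.select_tracks(tracks, "cumulative", k=1)
        assert cum[0].group == "hi" or cum[0].group == "sum"
        pos = itp.select_tracks(tracks, "positive_everywhere")
        assert {t.group for t in pos} == {"pos", "sum"}


class TestSmooth:
    def test_constant_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(itp.smooth(x, 10), x, atol=1e-12)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(9).standard_normal(30)
        np.testing.assert_array_equal(itp.smooth(x, 1), x)

    def test_impulse_spreads_triangularly(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = itp.smooth(x, 10)
        assert out[20] == out.max()
        # symmetric, linearly decaying to zero outside the kernel
        np.testing.assert_allclose(out[15:20], out[25:20:-1], atol=1e-12)
        assert out[14] == 0.0 and out[26] == 0.0
        assert np.all(np.diff(out[15:21]) > 0)

    def test_missing_values_excluded_and_preserved(self):
        x = np.array([1.0, np.nan, 1.0, 1.0, 1.0])
        out = itp.smooth(x, 4)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3, 4]], 1.0, atol=1e-12)


class TestComposition:
    def test_mononucleotide_proportions(self):
        rep = itp.composition_features(["AATT"], ["ACGT"])
        mono = rep[1]
        assert mono.loc["A", "prop_a"] == 0.5
        assert mono.loc["T", "prop_a"] == 0.5
        assert mono.loc["G", "prop_a"] == 0.0

    def test_dinucleotide_enumeration(self):
        rep = itp.composition_features(["AATT"], ["ACGT"])
        di = rep[2]
        for kmer in ("AA", "AT", "TT"):
            assert di.loc[kmer, "prop_a"] == pytest.approx(1 / 3)

    def test_identical_sets_have_zero_rank_change(self):
        seqs = ["ACGTACGGTTAC", "GGATCCATG"]
        rep = itp.composition_features(seqs, list(seqs))
        for k in (1, 2, 3):
            assert (rep[k]["rank_change"] == 0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            itp.composition_features([], ["ACGT"])


class TestConsensus:
    def test_dominant_base(self):
        m = itp.MotifModel(tf_id="x", tf_name="x", family="f", tf_class="c",
                           pfm=np.array([[97.0], [1], [1], [1]]))
        assert itp.consensus(m) == "A"

    def test_degenerate_pair(self):
        pfm = np.array([[45.0], [44], [5], [6]])
        m = itp.MotifModel(tf_id="x", tf_name="x", family="f", tf_class="c",
                           pfm=pfm)
        assert itp.consensus(m) == "[A/C]"

    def test_planted_motif_consensus_recovered(self):
        m = consensus_motif(MOTIF)
        assert itp.consensus(m) == MOTIF


def test_tracks_tsv_is_one_based(tmp_path):
    track = itp.HexamerImportanceTrack(seq_id=0, values=np.arange(196.0),
                                       valid=1, base_probability=0.9)
    path = tmp_path / "tracks.tsv"
    itp.tracks_to_tsv([track], path)
    lines = path.read_text().splitlines()
    assert lines[1].split("\t")[1] == "1"
    assert lines[-1].split("\t")[1] == "196"


def test_tracks_tsv_genomic_coordinates(tmp_path):
    track = itp.HexamerImportanceTrack(seq_id=0, values=np.arange(196.0),
                                       valid=1, base_probability=0.9)
    path = tmp_path / "tracks.tsv"
    itp.tracks_to_tsv([track], path, origins=[("contig7", 500)])
    lines = path.read_text().splitlines()
    first = lines[1].split("\t")
    # j=1 is the window starting 100 nt upstream of the centered site
    assert (first[1], first[2], first[3]) == ("1", "contig7", "400")
    last = lines[-1].split("\t")
    assert last[3] == "595"  # j=196 starts 95 nt downstream of the site
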