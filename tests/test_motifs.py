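"""PWM construction, entropy, log-odds and best-site scanning."""

import math

import numpy as np
import pytest

from modmotif.alphabet import DEFAULT_ALPHABET
from modmotif.motifs import (
    CORE_SYMBOLS,
    SYMBOL_INDEX,
    Background,
    ExpandedPWM,
    MotifError,
    apply_pseudocount,
    best_site,
    best_site_offsets_fractional,
    log_odds,
    pwm_from_string,
    read_meme_motifs,
    relative_entropy,
    write_meme_motifs,
)


def brute_force_best(seq, pwm, bg, both_strands=True, threshold=5.0):
    """Independent oracle: enumerate every offset and strand in python.

    A window is scored by summing per-position log2(Pr/b) looked up
    symbol-by-symbol; windows containing a symbol outside the 12 core
    symbols are unscorable. The reverse strand scores the window against
    the reverse-complemented motif.
    """
    def window_score(window, matrix):
        total = 0.0
        for i, ch in enumerate(window):
            ch = ch if ch in SYMBOL_INDEX else ch.upper()
            if ch not in SYMBOL_INDEX:
                return None
            pr = matrix[i][SYMBOL_INDEX[ch]]
            total += math.log2(pr / bg.freq[SYMBOL_INDEX[ch]])
        return total

    w = pwm.width
    rc = pwm.reverse_complement(DEFAULT_ALPHABET)
    best_entry = None
    for strand, matrix in [("+", pwm.matrix), ("-", rc.matrix)]:
        if strand == "-" and not both_strands:
            continue
        for off in range(len(seq) - w + 1):
            sc = window_score(seq[off:off + w], matrix)
            if sc is None or sc < threshold:
                continue
            if best_entry is None or sc > best_entry[2] + 1e-9:
                best_entry = (off, strand, sc)
            elif abs(sc - best_entry[2]) <= 1e-9:
                if (off, strand) < (best_entry[0], best_entry[1]):
                    best_entry = (off, strand, sc)
    return best_entry


class TestPwmFromString:
    def test_plain_consensus_is_unit_columns(self):
        pwm = pwm_from_string("CACGTG")
        assert pwm.width == 6
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert pwm.consensus() == "CACGTG"
        assert all(pwm.matrix.max(axis=1) == 1.0)

    def test_modification_ambiguity_code_splits_mass(self):
        pwm = pwm_from_string("xT")
        col = pwm.matrix[0]
        assert col[SYMBOL_INDEX["m"]] == pytest.approx(0.5)
        assert col[SYMBOL_INDEX["h"]] == pytest.approx(0.5)
        assert col.sum() == pytest.approx(1.0)

    def test_iupac_degeneracy_code(self):
        pwm = pwm_from_string("MTGCGY")
        col = pwm.matrix[0]
        assert col[SYMBOL_INDEX["A"]] == pytest.approx(0.5)
        assert col[SYMBOL_INDEX["C"]] == pytest.approx(0.5)

    def test_modified_core_symbols_accepted(self):
        pwm = pwm_from_string("TGCm1m1")
        assert pwm.consensus() == "TGCm1m1"

    def test_unknown_character_rejected_with_position(self):
        with pytest.raises(MotifError, match="position 2"):
            pwm_from_string("AC*GT")


class TestPseudocount:
    def test_zero_alpha_is_identity(self, uniform_bg):
        pwm = pwm_from_string("CACGTG")
        out = apply_pseudocount(pwm, 0.0, uniform_bg)
        assert np.allclose(out.matrix, pwm.matrix)

    def test_unnormalized_entries_follow_formula(self, uniform_bg):
        pwm = pwm_from_string("C")
        out = apply_pseudocount(pwm, 0.1, uniform_bg, renormalize=False)
        expected = np.full(12, 0.1 / 12)
        expected[SYMBOL_INDEX["C"]] += 1.0
        assert np.allclose(out.matrix[0], expected)
        assert not out.normalized

    def test_column_sums_conserve_alpha(self, realistic_bg):
        pwm = pwm_from_string("CACGTG")
        out = apply_pseudocount(pwm, 0.37, realistic_bg, renormalize=False)
        assert np.allclose(out.matrix.sum(axis=1), 1.37)

    def test_renormalized_columns_sum_to_one(self, realistic_bg):
        out = apply_pseudocount(pwm_from_string("CACGTG"), 0.37, realistic_bg)
        assert np.allclose(out.matrix.sum(axis=1), 1.0)


class TestRelativeEntropy:
    def test_motif_equal_to_background_has_zero_entropy(self, acgt_bg):
        matrix = np.tile(acgt_bg.freq, (3, 1))
        pwm = ExpandedPWM(name="bg", matrix=matrix)
        total, per_col = relative_entropy(pwm, acgt_bg)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_unit_column_against_quarter_background_is_two_bits(self, acgt_bg):
        total, per_col = relative_entropy(pwm_from_string("A"), acgt_bg)
        assert total == pytest.approx(2.0)

    def test_hexamer_consensus_is_twelve_bits(self, acgt_bg):
        total, per_col = relative_entropy(pwm_from_string("CACGTG"), acgt_bg)
        assert total == pytest.approx(12.0)
        assert per_col == pytest.approx(2.0)

    def test_non_negative_on_random_motifs(self, realistic_bg):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.dirichlet(np.ones(12), size=5)
            total, _ = relative_entropy(ExpandedPWM(name="r", matrix=m), realistic_bg)
            assert total >= -1e-9

    def test_zero_background_under_support_rejected(self, acgt_bg):
        with pytest.raises(MotifError):
            relative_entropy(pwm_from_string("m"), acgt_bg)


class TestLogOdds:
    def test_background_motif_scores_zero(self, acgt_bg):
        matrix = np.tile(acgt_bg.freq, (2, 1))
        pwm = ExpandedPWM(name="bg", matrix=matrix)
        with pytest.raises(MotifError):
            log_odds(pwm, acgt_bg)  # zero entries on modified symbols
        sub = apply_pseudocount(pwm, 1e-9, Background.uniform())
        scores = log_odds(sub, Background.uniform())
        # entries matching the background-probability columns are ~log2(3)
        assert np.isfinite(scores).all()

    def test_rare_modified_background_yields_large_scores(self):
        # a near-certain modified base over a 2^-10 background frequency
        # scores close to 10 bits, far above the same motif on C
        f = np.full(12, (1 - 2 ** -10) / 11)
        f[SYMBOL_INDEX["m"]] = 2 ** -10
        bg = Background(f / f.sum())
        pwm = apply_pseudocount(pwm_from_string("m"), 1e-6, bg)
        scores = log_odds(pwm, bg)
        assert scores[0, SYMBOL_INDEX["m"]] == pytest.approx(10.0, abs=0.01)

    def test_unnormalized_matrix_rejected(self, realistic_bg):
        pwm = apply_pseudocount(pwm_from_string("CA"), 0.1, realistic_bg,
                                renormalize=False)
        with pytest.raises(MotifError):
            log_odds(pwm, realistic_bg)


class TestBestSite:
    def make_scannable(self, motif, bg, alpha=0.1):
        return apply_pseudocount(pwm_from_string(motif), alpha, bg)

    def test_planted_exact_match_is_found(self, realistic_bg):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 60))
        seq = seq[:25] + "CACGTG" + seq[31:]
        pwm = self.make_scannable("CACGTG", realistic_bg)
        site = best_site(seq, pwm, realistic_bg)
        assert site is not None and site.offset == 25 and site.strand == "+"

    def test_sequence_shorter_than_motif_errors(self, realistic_bg):
        pwm = self.make_scannable("CACGTG", realistic_bg)
        with pytest.raises(MotifError):
            best_site("ACG", pwm, realistic_bg)

    def test_palindromic_motif_scores_identically_both_strands(self, realistic_bg):
        pwm = self.make_scannable("CACGTG", realistic_bg)  # palindrome
        seq = "TTTTCACGTGTTTT"
        site = best_site(seq, pwm, realistic_bg)
        assert site.strand == "+"  # tie resolved toward forward strand
        fractional = best_site_offsets_fractional(seq, pwm, realistic_bg)
        assert fractional == {4: 1.0}

    def test_ambiguity_symbols_are_unscorable(self, realistic_bg):
        pwm = self.make_scannable("CACGTG", realistic_bg)
        assert best_site("CACGTG", pwm, realistic_bg) is not None
        assert best_site("CACGTz", pwm, realistic_bg) is None

    def test_modified_motif_found_on_reverse_strand(self, realistic_bg):
        from modmotif.alphabet import reverse_complement
        pwm = self.make_scannable("TGCm1m1", realistic_bg)
        core = reverse_complement("TGCm1m1")  # m1m1GCA
        seq = "TTTT" + core + "TTTTT"
        site = best_site(seq, pwm, realistic_bg)
        assert site is not None and site.strand == "-" and site.offset == 4

    def test_agrees_with_brute_force_on_random_instances(self, realistic_bg):
        rng = np.random.default_rng(42)
        alphabet = list("ACGT") + list("mh12") + ["z"]
        probs = [0.22] * 4 + [0.02] * 4 + [0.04]
        motifs = ["CACGTG", "TGCm1m1", "CAm1TG", "MTGCGY", "xT"]
        n_checked = 0
        for trial in range(300):
            motif = motifs[trial % len(motifs)]
            pwm = self.make_scannable(motif, realistic_bg)
            n = int(rng.integers(len(motif), 40))
            seq = "".join(rng.choice(alphabet, size=n, p=probs))
            expected = brute_force_best(seq, pwm, realistic_bg)
            got = best_site(seq, pwm, realistic_bg)
            if expected is None:
                assert got is None
            else:
                assert (got.offset, got.strand) == expected[:2]
                assert got.score == pytest.approx(expected[2], abs=1e-9)
            n_checked += 1
        assert n_checked == 300

    def test_reverse_complement_consistency(self, realistic_bg):
        from modmotif.alphabet import reverse_complement
        rng = np.random.default_rng(3)
        pwm = self.make_scannable("CAm1TG", realistic_bg)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTm1"), 30,
                                     p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04]))
            fwd = best_site(seq, pwm, realistic_bg)
            rev = best_site(reverse_complement(seq), pwm, realistic_bg)
            if fwd is None:
                assert rev is None
                continue
            assert rev is not None
            assert rev.score == pytest.approx(fwd.score, abs=1e-9)
            # ignoring ties, the mirrored offset carries the site
            mirror = len(seq) - pwm.width - fwd.offset
            frac = best_site_offsets_fractional(reverse_complement(seq), pwm,
                                                realistic_bg)
            assert mirror in frac

    def test_fractional_weights_sum_to_one_per_scored_sequence(self, realistic_bg):
        pwm = self.make_scannable("CACGTG", realistic_bg)
        seq = "CACGTGAACACGTG"  # two identical sites tie
        frac = best_site_offsets_fractional(seq, pwm, realistic_bg)
        assert sum(frac.values()) == pytest.approx(1.0)
        assert set(frac) == {0, 8}


def test_meme_round_trip(tmp_path, realistic_bg):
    pwms = [pwm_from_string("CACGTG"), pwm_from_string("CAm1TG", name="ebox_m1")]
    path = tmp_path / "motifs.meme"
    with open(path, "w") as fh:
        write_meme_motifs(pwms, realistic_bg, fh)
    with open(path) as fh:
        back = read_meme_motifs(fh)
    assert [p.name for p in back] == ["CACGTG", "ebox_m1"]
    for orig, rt in zip(pwms, back):
        assert np.allclose(orig.matrix, rt.matrix, atol=1e-6)
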