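import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from promarch import elements as el

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


def iupac_regex(consensus):
    return re.compile(
        "".join("[" + "".join(sorted(el.IUPAC[c])) + "]" for c in consensus)
    )


def oracle_present(seq, spec, seq_start):
    """Regex-expansion oracle for exact (0-mismatch) presence in the window."""
    pat = iupac_regex(spec.consensus)
    k = len(spec.consensus)
    for start in range(spec.window_start, spec.window_end - k + 2):
        i = start - seq_start
        if pat.fullmatch(seq[i : i + k]):
            return True
    return False


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIupacMismatches:
    @pytest.mark.parametrize(
        "consensus,seq,expected",
        [
            ("STATAWAWR", "GTATAAAAG", 0),
            ("STATAWAWR", "TTATAAAAG", 1),  # T not in S={G,C}
            ("TCAKTY", "TCAGTC", 0),
            ("ACGT", "NCGT", 1),  # N in sequence mismatches non-N code
            ("NCGT", "NCGT", 0),
        ],
    )
    def test_counts(self, consensus, seq, expected):
        assert el.iupac_mismatches(consensus, seq) == expected

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            el.iupac_mismatches("ACGT", "ACG")

    def test_invalid_code_error(self):
        with pytest.raises(ValueError):
            el.iupac_mismatches("ACGZ", "ACGT")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seq=DNA)
    def test_self_match_and_n_consensus(self, seq):
        assert el.iupac_mismatches(seq, seq) == 0
        assert el.iupac_mismatches("N" * len(seq), seq) == 0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seq=DNA, data=st.data())
    def test_mismatch_count_bounded_by_length(self, seq, data):
        other = data.draw(
            st.text(alphabet="ACGTN", min_size=len(seq), max_size=len(seq))
        )
        mm = el.iupac_mismatches(seq, other)
        assert 0 <= mm <= len(seq)
        exact = sum(a != b for a, b in zip(seq, other))
        assert mm <= exact  # IUPAC classes only widen acceptance


class TestScanWindow:
    TATA = el.DEFAULT_MOTIFS[0]

    def _seq_with(self, insert, at, lo=-50, hi=10):
        seq = list("A" * (hi - lo + 1))
        i = at - lo
        seq[i : i + len(insert)] = insert
        return "".join(seq), lo

    def test_motif_inside_window_present(self):
        seq, lo = self._seq_with("TATAAATAG", -31)
        assert el.scan_window(seq, self.TATA, lo)

    def test_motif_crossing_window_end_absent(self):
        # placement at -21..-13 ends past the -20 boundary
        seq, lo = self._seq_with("GTATAAAAG", -21)
        seq = seq.replace("A", "C")  # scrub accidental matches elsewhere
        seq2 = list(seq)
        seq2[-21 - lo : -21 - lo + 9] = "GTATAAAAG"
        assert not el.scan_window("".join(seq2), self.TATA, lo)

    def test_uncovered_window_errors(self):
        with pytest.raises(ValueError):
            el.scan_window("ACGT", self.TATA, -2)

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        """Exact scanning equals brute-force regex expansion of the IUPAC codes."""
        for spec in el.DEFAULT_MOTIFS:
            zero = el.MotifSpec(
                spec.name, spec.consensus, spec.window_start, spec.window_end, 0
            )
            lo = spec.window_start - 3
            n = spec.window_end - lo + 4
            for _ in range(300):
                seq = random_seq(rng, n)
                assert bool(el.scan_window(seq, zero, lo)) == oracle_present(
                    seq, zero, lo
                )


class TestClassification:
    def _classify_one(self, planted):
        """Build a 141-mer over [-80, 60] with planted (element, offset) pairs."""
        rng = np.random.default_rng(99)
        specs = {m.name: m for m in el.DEFAULT_MOTIFS}
        instances = {
            "TATA": "CTATAAATA", "DPE": "GGTTA", "DRE": "TATCGATT",
            "INR": "TCAGTC", "TCT": "TTCTTTCT",
        }
        while True:
            seq = random_seq(rng, 141)
            for name, off in planted:
                i = off + 80
                seq = seq[:i] + instances[name] + seq[i + len(instances[name]):]
            present = {
                m.name for m in el.DEFAULT_MOTIFS if el.scan_window(seq, m, -80)
            }
            if present == {name for name, _ in planted}:
                (call,) = el.classify_promoters({"p": seq}, -80)
                return call

    def test_tata_with_dpe_is_tata_only(self):
        call = self._classify_one([("TATA", -31), ("DPE", 28)])
        assert call.labels == frozenset({"TATA"})
        assert call.primary_label == "TATA"

    def test_dre_alone_is_hk(self):
        call = self._classify_one([("DRE", -40)])
        assert call.labels == frozenset({"HK"})

    def test_dpe_plus_dre_unclassified(self):
        call = self._classify_one([("DPE", 28), ("DRE", -40)])
        assert call.labels == frozenset()
        assert call.primary_label == "unclassified"

    def test_planted_types_recovered(self, small_study):
        """Every generated promoter classifies as its planted type."""
        from promarch import simulate

        genome, truth = small_study
        seqs = simulate.truth_window_seqs(genome, truth)
        calls = el.classify_promoters(seqs, -80)
        got = pd.Series({c.promoter_id: c.primary_label for c in calls})
        assert (got == truth.promoters["ptype"]).all()


def fisher_oracle(a, b, c, d):
    """Two-sided exact p as a hypergeometric tail sum."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), N, K, n)
    obs = hypergeom.pmf(a, N, K, n)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


class TestEnrichment:
    def _table(self, k_in, n_in, k_out, n_out):
        ids = [f"p{i}" for i in range(n_in + n_out)]
        clusters = pd.Series([1] * n_in + [2] * n_out, index=ids)
        presence = pd.DataFrame(
            {"TATA": [i < k_in for i in range(n_in)]
             + [i < k_out for i in range(n_out)]},
            index=ids,
        )
        return clusters, presence

    def test_ratio_definition(self):
        clusters, presence = self._table(30, 50, 15, 150)
        out = el.element_enrichment(clusters, presence)
        row = out[(out["cluster"] == 1) & (out["element"] == "TATA")].iloc[0]
        assert row["ratio"] == pytest.approx(6.0)

    def test_fisher_matches_hypergeometric_oracle(self):
        clusters, presence = self._table(30, 50, 15, 150)
        out = el.element_enrichment(clusters, presence)
        row = out[(out["cluster"] == 1) & (out["element"] == "TATA")].iloc[0]
        assert row["p"] == pytest.approx(fisher_oracle(30, 20, 15, 135), abs=1e-10)

    def test_ubiquitous_element_ratio_one_p_one(self):
        clusters, presence = self._table(50, 50, 150, 150)
        out = el.element_enrichment(clusters, presence)
        row = out[(out["cluster"] == 1)].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_bh_q_monotone_in_p(self, rng):
        ids = [f"p{i}" for i in range(120)]
        clusters = pd.Series(rng.integers(1, 5, size=120), index=ids)
        presence = pd.DataFrame(
            rng.random((120, 5)) < 0.3,
            index=ids, columns=["TATA", "DPE", "TCT", "DRE", "INR"],
        )
        out = el.element_enrichment(clusters, presence).dropna(subset=["p"])
        srt = out.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
        assert (srt["q"] >= srt["p"] - 1e-12).all()


class TestPwm:
    def test_identical_sequences_full_information(self):
        pwm = el.build_pwm(["TATA"] * 8, pseudocount=0.0)
        assert np.allclose(pwm["ic"], 2.0)

    def test_uniform_composition_low_information(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(4000)]
        pwm = el.build_pwm(seqs)
        assert pwm["ic"].max() < 0.01

    def test_frequencies_match_direct_tally(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(100)]
        pwm = el.build_pwm(seqs, pseudocount=0.0)
        for j, base in enumerate("ACGT"):
            expect = [
                sum(s[i] == base for s in seqs) / 100 for i in range(5)
            ]
            np.testing.assert_allclose(pwm[base], expect)

    def test_rows_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=7)) for _ in range(30)]
        pwm = el.build_pwm(seqs)
        np.testing.assert_allclose(pwm[["A", "C", "G", "T"]].sum(axis=1), 1.0)
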