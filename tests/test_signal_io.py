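import numpy as np
import pytest

from promarch.signal_io import (
    PromoterRecord,
    StrandedTrack,
    extract_profiles,
    pool_replicates,
    read_stranded_bedgraph,
    rpm_normalize,
    window_signal,
    write_stranded_bedgraph,
)

CONTIGS = {"chr2L": 100}


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestBedgraphIO:
    def test_record_fills_half_open_interval(self, tmp_path):
        plus = _write(tmp_path, "p.bg", ["chr2L\t10\t12\t3.0"])
        minus = _write(tmp_path, "m.bg", [])
        track = read_stranded_bedgraph(plus, minus, CONTIGS)
        assert track.plus["chr2L"][10] == 3.0
        assert track.plus["chr2L"][11] == 3.0
        assert track.plus["chr2L"][12] == 0.0
        assert track.minus["chr2L"].sum() == 0.0

    def test_empty_file_gives_zero_track(self, tmp_path):
        plus = _write(tmp_path, "p.bg", [])
        minus = _write(tmp_path, "m.bg", [])
        track = read_stranded_bedgraph(plus, minus, CONTIGS)
        assert track.total() == 0.0

    @pytest.mark.parametrize(
        "record",
        ["chr2L\t95\t105\t1.0", "chrX\t0\t5\t1.0"],
        ids=["beyond-contig-end", "unknown-contig"],
    )
    def test_bad_records_error(self, tmp_path, record):
        plus = _write(tmp_path, "p.bg", [record])
        minus = _write(tmp_path, "m.bg", [])
        with pytest.raises(ValueError):
            read_stranded_bedgraph(plus, minus, CONTIGS)

    def test_overlapping_intervals_error(self, tmp_path):
        plus = _write(tmp_path, "p.bg", ["chr2L\t10\t20\t1.0", "chr2L\t15\t25\t2.0"])
        minus = _write(tmp_path, "m.bg", [])
        with pytest.raises(ValueError, match="overlap"):
            read_stranded_bedgraph(plus, minus, CONTIGS)

    def test_roundtrip_bit_identical(self, tmp_path, rng):
        track = StrandedTrack.zeros(CONTIGS)
        idx = rng.choice(100, size=30, replace=False)
        track.plus["chr2L"][idx] = rng.integers(1, 50, size=30).astype(float)
        track.minus["chr2L"][idx[:10]] = 2.5
        write_stranded_bedgraph(track, tmp_path / "p.bg", tmp_path / "m.bg")
        back = read_stranded_bedgraph(tmp_path / "p.bg", tmp_path / "m.bg", CONTIGS)
        np.testing.assert_array_equal(back.plus["chr2L"], track.plus["chr2L"])
        np.testing.assert_array_equal(back.minus["chr2L"], track.minus["chr2L"])


class TestRpmAndPooling:
    def _track(self, value, total, **meta):
        t = StrandedTrack.zeros(CONTIGS, total_aligned_reads=total, **meta)
        t.plus["chr2L"][:] = value
        return t

    def test_rpm_scales_by_million_over_total(self):
        out = rpm_normalize(self._track(4.0, 2_000_000))
        assert out.plus["chr2L"][0] == pytest.approx(2.0)

    def test_rpm_identity_at_one_million(self):
        out = rpm_normalize(self._track(7.0, 1_000_000))
        np.testing.assert_array_equal(out.plus["chr2L"], 7.0)

    def test_rpm_total_linearity(self, rng):
        t = StrandedTrack.zeros(CONTIGS, total_aligned_reads=5000)
        t.plus["chr2L"][:] = rng.integers(0, 9, size=100)
        t.minus["chr2L"][:] = rng.integers(0, 9, size=100)
        out = rpm_normalize(t)
        assert out.total() == pytest.approx(1e6 * t.total() / 5000)

    def test_rpm_requires_positive_total(self):
        with pytest.raises(ValueError):
            rpm_normalize(self._track(1.0, 0))

    def test_pool_is_mean_and_permutation_invariant(self):
        meta = {"factor": "TBP", "condition": "control", "normalized": True}
        a = StrandedTrack.zeros(CONTIGS, **meta)
        b = StrandedTrack.zeros(CONTIGS, **meta)
        c = StrandedTrack.zeros(CONTIGS, **meta)
        a.plus["chr2L"][5] = 0.0
        b.plus["chr2L"][5] = 0.0
        c.plus["chr2L"][5] = 6.0
        fwd = pool_replicates([a, b, c])
        rev = pool_replicates([c, a, b])
        assert fwd.plus["chr2L"][5] == pytest.approx(2.0)
        np.testing.assert_array_equal(fwd.plus["chr2L"], rev.plus["chr2L"])

    def test_pool_idempotent_on_identical_replicates(self):
        meta = {"factor": "TBP", "condition": "control", "normalized": True}
        a = StrandedTrack.zeros(CONTIGS, **meta)
        a.plus["chr2L"][3] = 4.0
        pooled = pool_replicates([a, a])
        np.testing.assert_array_equal(pooled.plus["chr2L"], a.plus["chr2L"])

    def test_pool_rejects_mixed_factors(self):
        a = StrandedTrack.zeros(CONTIGS, factor="TBP", condition="c", normalized=True)
        b = StrandedTrack.zeros(CONTIGS, factor="TAF1", condition="c", normalized=True)
        with pytest.raises(ValueError):
            pool_replicates([a, b])


class TestProfiles:
    def _track(self):
        return StrandedTrack.zeros({"chr": 2001})

    def test_plus_strand_offset(self):
        t = self._track()
        t.plus["chr"][1010] = 5.0
        prom = PromoterRecord("p0", "chr", 1000, "+")
        prof = extract_profiles(t, [prom], 50)
        assert prof.sense[0, prof.offset_index(10)] == 5.0

    def test_minus_strand_flip(self):
        t = self._track()
        t.minus["chr"][990] = 5.0
        prom = PromoterRecord("p0", "chr", 1000, "-")
        prof = extract_profiles(t, [prom], 50)
        assert prof.sense[0, prof.offset_index(10)] == 5.0

    def test_mirror_promoter_gives_identical_rows(self, rng):
        """A promoter and its reverse-complement mirror see the same profile."""
        n = 2001
        fwd = StrandedTrack.zeros({"chr": n})
        fwd.plus["chr"][:] = rng.integers(0, 20, size=n)
        fwd.minus["chr"][:] = rng.integers(0, 20, size=n)
        mirror = StrandedTrack.zeros({"chr": n})
        mirror.plus["chr"][:] = fwd.minus["chr"][::-1]
        mirror.minus["chr"][:] = fwd.plus["chr"][::-1]
        tss = 700
        p_fwd = PromoterRecord("p", "chr", tss, "+")
        p_mir = PromoterRecord("p", "chr", n - 1 - tss, "-")
        a = extract_profiles(fwd, [p_fwd], 60)
        b = extract_profiles(mirror, [p_mir], 60)
        np.testing.assert_array_equal(a.sense, b.sense)
        np.testing.assert_array_equal(a.antisense, b.antisense)

    def test_out_of_bounds_promoter_dropped(self):
        t = self._track()
        prof = extract_profiles(
            t, [PromoterRecord("edge", "chr", 10, "+")], 50
        )
        assert prof.promoter_ids == []

    def test_window_signal_sum_mean_zero(self):
        t = self._track()
        t.plus["chr"][:] = 1.0
        t.minus["chr"][:] = 1.0
        prof = extract_profiles(t, [PromoterRecord("p", "chr", 1000, "+")], 60)
        assert window_signal(prof, (-50, 50), "sum")[0] == 202.0
        assert window_signal(prof, (-50, 50), "mean")[0] == 1.0
        empty = extract_profiles(
            self._track(), [PromoterRecord("p", "chr", 1000, "+")], 60
        )
        assert window_signal(empty, (-50, 50), "sum")[0] == 0.0

    def test_window_outside_flank_errors(self):
        t = self._track()
        prof = extract_profiles(t, [PromoterRecord("p", "chr", 1000, "+")], 30)
        with pytest.raises(ValueError):
            window_signal(prof, (-50, 50))
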