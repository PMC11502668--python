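"""Probability codes, per-read calls, stoichiometry, and control subtraction."""

from __future__ import annotations

from array import array

import numpy as np
import pysam
import pytest

from oreo import (
    ConfigError,
    DrsSimConfig,
    InputError,
    UndefinedResultError,
    classify_read,
    classify_site_in_bam,
    decode_probability,
    encode_probability,
    fold_change,
    run_pseucall,
    simulate_drs_reads,
    smallest_code_above,
    subtract_control,
    summarize_site,
)
from oreo.pseucall import ReadClassification, SiteModificationSummary
from conftest import write_bam


class TestProbabilityCodes:
    def test_bin_midpoints(self):
        assert decode_probability(0) == pytest.approx(1 / 512)
        assert decode_probability(255) == pytest.approx(511 / 512)

    def test_round_trip_all_codes(self):
        assert all(encode_probability(decode_probability(c)) == c for c in range(256))

    def test_strictly_monotone(self):
        decoded = [decode_probability(c) for c in range(256)]
        assert all(b > a for a, b in zip(decoded, decoded[1:]))

    def test_smallest_code_above_threshold_brute_force(self):
        brute = min(c for c in range(256) if decode_probability(c) > 0.95)
        assert smallest_code_above(0.95) == brute == 243

    @pytest.mark.parametrize("code", [-1, 256, 1000])
    def test_out_of_range_code(self, code):
        with pytest.raises(ConfigError):
            decode_probability(code)


def _read(seq, start=0, cigar=None, tags=(), header_len=10):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": header_len}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigartuples = cigar or [(0, len(seq))]
    a.query_qualities = array("B", [30] * len(seq))
    for tag, value, vtype in tags:
        a.set_tag(tag, value, vtype)
    return a


def _tags(code, delta=0):
    return [("MM", f"T+17802?,{delta};", "Z"), ("ML", array("B", [code]), None)]


class TestClassifyRead:
    # reference: positions 0..4, site at 2 (ref base T)
    SITE = ("ref", 2)

    def test_mismatch_branch_alone_suffices(self):
        read = _read("AACGA", tags=[])  # C at site, no tag
        c = classify_read(read, self.SITE)
        assert c.u_to_c and c.modified and c.decoded_p is None

    def test_mismatch_with_low_probability_still_modified(self):
        # tag lives on a T elsewhere; site base is C
        read = _read("TACGA", tags=_tags(encode_probability(0.10)))
        c = classify_read(read, self.SITE)
        assert c.observed_base == "C" and c.modified

    def test_probability_branch(self):
        read = _read("AATGA", tags=_tags(encode_probability(0.99)))
        c = classify_read(read, self.SITE)
        assert not c.u_to_c and c.high_conf_call and c.modified
        assert c.decoded_p == pytest.approx(decode_probability(encode_probability(0.99)))

    def test_below_threshold_unmodified(self):
        read = _read("AATGA", tags=_tags(encode_probability(0.50)))
        c = classify_read(read, self.SITE)
        assert not c.modified and c.observed_base == "T"

    def test_threshold_is_strict(self):
        # code 242 decodes to 485/512 ≈ 0.9473 < 0.95; 243 to 487/512 > 0.95
        low = classify_read(_read("AATGA", tags=_tags(242)), self.SITE)
        high = classify_read(_read("AATGA", tags=_tags(243)), self.SITE)
        assert not low.modified and high.modified

    def test_deletion_at_site_excluded(self):
        read = _read("AAGA", cigar=[(0, 2), (2, 1), (0, 2)])
        c = classify_read(read, self.SITE)
        assert c.observed_base == "deletion" and not c.modified and not c.covers_site

    def test_noncovering_read(self):
        read = _read("GA", start=3, cigar=[(0, 2)])
        c = classify_read(read, self.SITE)
        assert c.observed_base == "none" and not c.modified

    def test_non_T_reference_base_rejected(self):
        with pytest.raises(ConfigError):
            classify_read(_read("AATGA"), self.SITE, ref_base="A")


def _cls(observed, u_to_c=False, high_conf=False, p=None):
    return ReadClassification(
        read_id="r",
        ref_name="ref",
        position=2,
        observed_base=observed,
        u_to_c=u_to_c,
        decoded_p=p,
        high_conf_call=high_conf,
        modified=observed not in ("none", "deletion") and (u_to_c or high_conf),
    )


class TestSummarizeSite:
    def test_union_arithmetic(self):
        cls = (
            [_cls("C", u_to_c=True) for _ in range(3)]
            + [_cls("T", high_conf=True, p=0.99) for _ in range(2)]
            + [_cls("T") for _ in range(5)]
        )
        s = summarize_site(cls)
        assert s.n_reads_covering == 10
        assert s.pct_modified_raw == pytest.approx(50.0)
        assert s.pct_u_to_c == pytest.approx(30.0)
        assert s.pct_high_conf_only == pytest.approx(20.0)

    def test_all_modified(self):
        s = summarize_site([_cls("C", u_to_c=True)] * 4)
        assert s.pct_modified_raw == pytest.approx(100.0)

    def test_noncovering_and_deletions_excluded_from_denominator(self):
        cls = [_cls("C", u_to_c=True)] + [_cls("deletion")] * 3 + [_cls("none")] * 2
        s = summarize_site(cls)
        assert s.n_reads_covering == 1
        assert s.pct_modified_raw == pytest.approx(100.0)

    def test_zero_usable_reads_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            summarize_site([_cls("deletion"), _cls("none")])

    def test_union_dominates_components(self):
        rng = np.random.default_rng(5)
        cls = []
        for _ in range(200):
            u2c = rng.random() < 0.3
            hc = rng.random() < 0.4
            cls.append(_cls("C" if u2c else "T", u_to_c=u2c, high_conf=hc, p=0.99 if hc else 0.1))
        s = summarize_site(cls)
        pct_hc = 100 * sum(c.high_conf_call for c in cls) / len(cls)
        assert s.pct_modified_raw >= s.pct_u_to_c
        assert s.pct_modified_raw >= pct_hc


def _summary(pct, ref="ref", pos=2, n=100):
    return SiteModificationSummary(
        sample_label="s", ref_name=ref, position=pos, n_reads_covering=n,
        n_u_to_c=0, n_high_conf_only=0, n_modified=int(n * pct / 100),
        pct_u_to_c=0.0, pct_high_conf_only=0.0, pct_modified_raw=pct,
    )


class TestControlSubtractionAndFoldChange:
    def test_simple_subtraction(self):
        out = subtract_control(_summary(30.0), _summary(4.0))
        assert out.pct_modified_corrected == pytest.approx(26.0)
        assert not out.clamped

    def test_identical_sample_and_control(self):
        out = subtract_control(_summary(12.5), _summary(12.5))
        assert out.pct_modified_corrected == 0.0

    def test_negative_clamps_to_zero_with_flag(self):
        out = subtract_control(_summary(2.0), _summary(4.0))
        assert out.pct_modified_corrected == 0.0 and out.clamped

    def test_site_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            subtract_control(_summary(10.0), _summary(4.0, pos=3))

    def test_fold_change_arithmetic(self):
        tgt = subtract_control(_summary(25.1, ref="mCherry"), _summary(0.0, ref="mCherry"))
        off = subtract_control(_summary(1.0, ref="eGFP"), _summary(0.0, ref="eGFP"))
        # same-site check applies per summary; cross-reference ratio is intended
        fc = fold_change(tgt, off)
        assert fc.fold_change == pytest.approx(25.1)

    def test_equal_percentages_give_unity(self):
        tgt = subtract_control(_summary(5.0), _summary(0.0))
        assert fold_change(tgt, tgt).fold_change == pytest.approx(1.0)

    def test_zero_offtarget_is_undefined(self):
        tgt = subtract_control(_summary(5.0), _summary(0.0))
        off = subtract_control(_summary(0.0), _summary(0.0))
        with pytest.raises(UndefinedResultError):
            fold_change(tgt, off)


class TestRunPseucall:
    def test_parameter_recovery_single_point(self, tiny_ref, tmp_path):
        frac, n = 0.30, 5000
        kwargs = dict(
            p_mismatch_given_mod=1.0, p_mismatch_given_unmod=0.0,
            background_sub_rate=0.0, background_del_rate=0.0,
            prob_dist_mod=(8, 1), prob_dist_unmod=(1, 50),
        )
        sample = simulate_drs_reads(
            tiny_ref, DrsSimConfig(n_reads=n, frac_modified=frac, seed=31, **kwargs),
            tmp_path / "s",
        )
        control = simulate_drs_reads(
            tiny_ref, DrsSimConfig(n_reads=n, frac_modified=0.0, seed=32, **kwargs),
            tmp_path / "c",
        )
        report = run_pseucall(
            sample.bam_path, control.bam_path, tiny_ref, fold_change_pair=None
        )
        got = report[report["sample"] == "sample"]["pct_modified_corrected"].iloc[0]
        se = 100 * np.sqrt(frac * (1 - frac) / n)
        assert abs(got - 100 * frac) <= 3 * se

    def test_self_control_is_zero(self, tiny_ref, tmp_path):
        sim = simulate_drs_reads(
            tiny_ref,
            DrsSimConfig(n_reads=1000, frac_modified=0.5, p_mismatch_given_mod=0.9,
                         p_mismatch_given_unmod=0.05, prob_dist_mod=(8, 1),
                         prob_dist_unmod=(1, 50), seed=33),
            tmp_path,
        )
        report = run_pseucall(sim.bam_path, sim.bam_path, tiny_ref, fold_change_pair=None)
        assert (report["pct_modified_corrected"] == 0.0).all()

    def test_missing_index_fails_before_compute(self, tiny_ref, tmp_path):
        sim = simulate_drs_reads(
            tiny_ref,
            DrsSimConfig(n_reads=10, frac_modified=1.0, p_mismatch_given_mod=1.0,
                         p_mismatch_given_unmod=0.0, prob_dist_mod=(8, 1),
                         prob_dist_unmod=(1, 50), seed=34),
            tmp_path,
        )
        naked = tmp_path / "noindex.bam"
        naked.write_bytes(sim.bam_path.read_bytes())
        with pytest.raises(InputError):
            run_pseucall(naked, sim.bam_path, tiny_ref)

    def test_invalid_threshold_rejected(self, tiny_ref, tmp_path):
        sim = simulate_drs_reads(
            tiny_ref,
            DrsSimConfig(n_reads=10, frac_modified=1.0, p_mismatch_given_mod=1.0,
                         p_mismatch_given_unmod=0.0, prob_dist_mod=(8, 1),
                         prob_dist_unmod=(1, 50), seed=35),
            tmp_path,
        )
        with pytest.raises(ConfigError):
            run_pseucall(sim.bam_path, sim.bam_path, tiny_ref, threshold=1.01)

    def test_threshold_monotonicity(self, tiny_ref, tmp_path):
        """Lowering the probability threshold never decreases percent modified."""
        sim = simulate_drs_reads(
            tiny_ref,
            DrsSimConfig(n_reads=2000, frac_modified=0.5, p_mismatch_given_mod=0.6,
                         p_mismatch_given_unmod=0.02, prob_dist_mod=(4, 1),
                         prob_dist_unmod=(1, 4), seed=36),
            tmp_path,
        )
        site = tiny_ref.target_sites[0]
        pcts = []
        for threshold in (0.995, 0.95, 0.8, 0.5, 0.2, 0.01):
            cls = classify_site_in_bam(sim.bam_path, site, threshold=threshold)
            pcts.append(summarize_site(cls).pct_modified_raw)
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))
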