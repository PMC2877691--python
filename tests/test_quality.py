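"""Quality metrics and threshold filtering."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisclone.alignment import OrientedRead, build_alignment, convert_reference, orient_and_trim
from bisclone.quality import (
    FilterConfig,
    QualityMetrics,
    apply_filters,
    compute_metrics,
    filter_alignment,
)
from bisclone.simulate import SimConfig, bisulfite_convert, simulate_reads, simulate_reference

from conftest import manual_frame


def metrics_for(ref, read_seq):
    _, orientation, aln = orient_and_trim("r", read_seq, ref)
    frame = build_alignment([OrientedRead("r", orientation, aln)], ref, mode="stitched")
    return compute_metrics(frame.rows[0], ref)


# reference with 10 non-CpG cytosines and 2 CpGs
TEN_C_REF = "AACTGT" * 10 + "CGAACG"


class TestComputeMetrics:
    def test_perfect_converted_read(self):
        ref = convert_reference("r", TEN_C_REF)
        assert len(ref.noncpg_c_positions) == 10
        m = metrics_for(ref, ref.converted)
        assert m.identity == 1.0
        assert m.conversion_rate == 1.0
        assert m.gap_fraction == 0.0
        assert m.n_at_cytosine == 0
        assert m.aligned_span == ref.length

    def test_one_unconverted_in_ten(self):
        ref = convert_reference("r", TEN_C_REF)
        read = bisulfite_convert(TEN_C_REF, [True, True], [ref.noncpg_c_positions[0]])
        m = metrics_for(ref, read)
        assert m.conversion_rate == pytest.approx(0.9)
        assert m.unconverted_per_100bp == pytest.approx(100.0 / ref.length)

    def test_n_at_cytosine_excluded_from_conversion(self):
        ref = convert_reference("r", TEN_C_REF)
        read = list(ref.converted)
        read[ref.noncpg_c_positions[2]] = "N"
        m = metrics_for(ref, "".join(read))
        assert m.n_at_cytosine == 1
        assert m.conversion_rate == 1.0  # 9/9, N position out of the denominator

    def test_cpg_t_counts_as_identity_match(self):
        ref = convert_reference("r", TEN_C_REF)
        read = bisulfite_convert(TEN_C_REF, [False, False])  # both CpGs read T
        m = metrics_for(ref, read)
        assert m.identity == 1.0

    def test_gap_fraction_counts_indels(self, small_ref):
        read = small_ref.converted[:6] + small_ref.converted[8:]  # 2 bp deletion
        m = metrics_for(small_ref, read)
        assert m.gap_fraction == pytest.approx(2 / 14)

    def test_padding_columns_from_other_reads_ignored(self):
        # metrics must be invariant to insertion columns other reads open
        ref = convert_reference("r", TEN_C_REF)
        clean = ref.converted
        with_ins = clean[:30] + "AAAA" + clean[30:]
        oriented = []
        for rid, s in (("clean", clean), ("ins", with_ins)):
            _, o, a = orient_and_trim(rid, s, ref)
            oriented.append(OrientedRead(rid, o, a))
        frame = build_alignment(oriented, ref, mode="stitched")
        m_clean = compute_metrics(frame.rows[0], ref)
        assert m_clean.identity == 1.0
        assert m_clean.gap_fraction == 0.0


class TestApplyFilters:
    def make(self, **kw):
        base = dict(
            identity=1.0,
            conversion_rate=1.0,
            unconverted_per_100bp=0.0,
            gap_fraction=0.0,
            n_at_cytosine=0,
            aligned_span=100,
        )
        base.update(kw)
        return QualityMetrics(**base)

    @pytest.mark.parametrize(
        "kw, expect_pass, reason",
        [
            ({"identity": 0.90}, True, None),  # boundary inclusive
            ({"identity": 0.8999}, False, "identity"),
            ({"conversion_rate": 0.95}, True, None),
            ({"conversion_rate": 0.94}, False, "conversion"),
            ({"gap_fraction": 0.20}, True, None),
            ({"gap_fraction": 0.201}, False, "gaps"),
            ({"n_at_cytosine": 3}, True, None),
            ({"n_at_cytosine": 4}, False, "n_sites"),
        ],
    )
    def test_unique_mode_boundaries(self, kw, expect_pass, reason):
        d = apply_filters("r", self.make(**kw), FilterConfig.unique_defaults())
        assert d.passed is expect_pass
        if reason:
            assert d.reasons == (reason,)

    @pytest.mark.parametrize(
        "kw, expect_pass, reason",
        [
            ({"identity": 0.70}, True, None),
            ({"identity": 0.699}, False, "identity"),
            # "3 and more unconverted cytosines in 100 bps are excluded"
            ({"unconverted_per_100bp": 3.0}, False, "conversion"),
            ({"unconverted_per_100bp": 2.0}, True, None),
            ({"conversion_rate": 0.5}, True, None),  # rate criterion replaced
        ],
    )
    def test_repeat_mode_boundaries(self, kw, expect_pass, reason):
        d = apply_filters("r", self.make(**kw), FilterConfig.repeat_defaults())
        assert d.passed is expect_pass
        if reason:
            assert d.reasons == (reason,)

    def test_all_failed_criteria_listed(self):
        m = self.make(identity=0.5, conversion_rate=0.5, gap_fraction=0.5, n_at_cytosine=9)
        d = apply_filters("r", m, FilterConfig.unique_defaults())
        assert set(d.reasons) == {"identity", "conversion", "gaps", "n_sites"}

    def test_undefined_conversion_skips_criterion(self):
        d = apply_filters("r", self.make(conversion_rate=None), FilterConfig.unique_defaults())
        assert d.passed

    @settings(max_examples=200, deadline=None)
    @given(
        identity=st.floats(0, 1),
        conversion=st.floats(0, 1),
        gaps=st.floats(0, 1),
        n_sites=st.integers(0, 10),
        mode=st.sampled_from(["unique", "repeat"]),
    )
    def test_improving_one_metric_never_flips_pass_to_fail(
        self, identity, conversion, gaps, n_sites, mode
    ):
        cfg = (
            FilterConfig.unique_defaults()
            if mode == "unique"
            else FilterConfig.repeat_defaults()
        )
        m = self.make(
            identity=identity,
            conversion_rate=conversion,
            unconverted_per_100bp=(1 - conversion) * 100,
            gap_fraction=gaps,
            n_at_cytosine=n_sites,
        )
        if not apply_filters("r", m, cfg).passed:
            return
        improvements = [
            dataclasses.replace(m, identity=min(1.0, identity + 0.05)),
            dataclasses.replace(m, conversion_rate=min(1.0, conversion + 0.05)),
            dataclasses.replace(m, unconverted_per_100bp=m.unconverted_per_100bp / 2),
            dataclasses.replace(m, gap_fraction=gaps / 2),
            dataclasses.replace(m, n_at_cytosine=max(0, n_sites - 1)),
        ]
        for better in improvements:
            assert apply_filters("r", better, cfg).passed

    def test_pure_function(self):
        m = self.make(identity=0.93)
        cfg = FilterConfig.unique_defaults()
        assert apply_filters("r", m, cfg) == apply_filters("r", m, cfg)


def test_conversion_rate_recovers_simulated_failure_probability():
    """Mean (1 - conversion rate) estimates the planted failure rate q."""
    q = 0.05
    cfg = SimConfig(
        seed=11, ref_length=300, n_cpg=10, n_clones=50, conv_failure=q,
        seq_error=0.0, n_rate=0.0, tstretch_indel=0.0,
    )
    _, seq = simulate_reference(cfg)
    ref = convert_reference("r", seq)
    n_noncpg = len(ref.noncpg_c_positions)
    assert n_noncpg >= 20
    reads, _ = simulate_reads(seq, cfg)
    oriented = []
    for r in reads:
        _, o, a = orient_and_trim(r.read_id, r.sequence, ref)
        oriented.append(OrientedRead(r.read_id, o, a))
    frame = build_alignment(oriented, ref, mode="stitched")
    metrics, _ = filter_alignment(frame, ref, FilterConfig.unique_defaults())
    rates = [1 - m.conversion_rate for m in metrics.values()]
    n_obs = 50 * n_noncpg
    se = np.sqrt(q * (1 - q) / n_obs)
    assert abs(np.mean(rates) - q) < 3 * se
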