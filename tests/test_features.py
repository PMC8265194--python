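"""Feature computations against independent brute-force oracles, plus
standardization and the registry contract."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exonskip.features import (
    CONCENTRATION_FEATURE,
    FeatureDefinition,
    FeatureRegistry,
    NiScoreTable,
    TargetContext,
    acc_last,
    acp,
    compute_features,
    default_registry,
    exon_v_intron_gc,
    gc_count,
    ni_score_per_base,
    pct_gc_blocked,
    standardize_apply,
    standardize_fit,
)
from exonskip.synthetic import random_context
from exonskip.thermo import reverse_complement


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive, independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_gc_count(seq):
    return sum(1 for c in seq.upper().replace("T", "U") if c in "GC")


def oracle_acp(start, end):
    positions = list(range(start, end + 1))
    return positions[(len(positions) - 1) // 2]


def oracle_pct_gc_blocked(exon, start, end):
    remaining = [c for i, c in enumerate(exon, start=1) if i < start or i > end]
    if not remaining:
        return 0.0
    return 100.0 * sum(c in "GC" for c in remaining) / len(remaining)


def oracle_exon_v_intron(exon, upstream, start, end):
    gc_up = 100.0 * sum(c in "GC" for c in upstream) / len(upstream)
    if gc_up == 0:
        return None
    return oracle_pct_gc_blocked(exon, start, end) / gc_up


def oracle_ni(exon, table):
    k = len(next(iter(table)))
    total = sum(table.get(exon[i:i + k], 0.0) for i in range(len(exon) - k + 1))
    return total / len(exon)


def _random_case(rng):
    exon_len = int(rng.integers(20, 80))
    exon = "".join(rng.choice(list("ACGU"), size=exon_len))
    up = "".join(rng.choice(list("ACGU"), size=int(rng.integers(10, 60))))
    down = "".join(rng.choice(list("ACGU"), size=int(rng.integers(10, 60))))
    ctx = TargetContext(exon_seq=exon, upstream_intron=up, downstream_intron=down)
    length = int(rng.integers(5, min(26, exon_len)))
    start = int(rng.integers(1, exon_len - length + 2))
    return ctx, start, start + length - 1


def test_feature_oracles_agree_on_random_inputs(rng):
    table = {"".join(rng.choice(list("ACGU"), size=4)): float(rng.normal())
             for _ in range(30)}
    ni_table = NiScoreTable(dict(table))
    for _ in range(100):
        ctx, s, e = _random_case(rng)
        aso = reverse_complement(ctx.exon_seq[s - 1:e])
        assert gc_count(aso) == oracle_gc_count(aso)
        assert acp(ctx, s, e) == oracle_acp(s, e)
        assert pct_gc_blocked(ctx, s, e) == pytest.approx(
            oracle_pct_gc_blocked(ctx.exon_seq, s, e), abs=1e-12)
        expected_ratio = oracle_exon_v_intron(ctx.exon_seq, ctx.upstream_intron, s, e)
        got = exon_v_intron_gc(ctx, s, e)
        if expected_ratio is None:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected_ratio, abs=1e-12)
        assert ni_score_per_base(ctx, ni_table) == pytest.approx(
            oracle_ni(ctx.exon_seq, table), abs=1e-12)


class TestAcp:
    @pytest.mark.parametrize("start,end,expected", [(1, 15, 8), (11, 40, 25), (1, 1, 1)])
    def test_examples(self, toy_context, start, end, expected):
        assert acp(toy_context, start, end) == expected

    def test_strictly_increasing_in_start_at_fixed_length(self, toy_context):
        values = [acp(toy_context, s, s + 19) for s in range(1, 80)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_site_outside_exon_raises(self, toy_context):
        with pytest.raises(ValueError, match="outside exon"):
            acp(toy_context, 90, 120)


class TestGcFeatures:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 4), ("AUAU", 0), ("GCAUU", 2)])
    def test_gc_count_examples(self, seq, expected):
        assert gc_count(seq) == expected

    def test_blocked_gc_examples(self):
        ctx = TargetContext(exon_seq="GGGGGAAAAA", upstream_intron="GCGC")
        assert pct_gc_blocked(ctx, 1, 5) == 0.0
        assert pct_gc_blocked(ctx, 6, 10) == 100.0
        assert pct_gc_blocked(ctx, 1, 10) == 0.0  # degenerate: whole exon blocked

    def test_empty_site_equals_plain_exon_gc(self):
        # blocking a single terminal base barely moves the value; the
        # complement check: blocking nothing is the exon %GC itself
        ctx = TargetContext(exon_seq="GGAAUUCC")
        assert oracle_pct_gc_blocked(ctx.exon_seq, 0, 0) == pytest.approx(50.0)

    def test_exon_v_intron_examples(self):
        ctx = TargetContext(exon_seq="G" * 10, upstream_intron="G" * 20)
        assert exon_v_intron_gc(ctx, 1, 5) == pytest.approx(1.0)
        gc_free = TargetContext(exon_seq="GGAAUU", upstream_intron="AAAA")
        assert math.isnan(exon_v_intron_gc(gc_free, 1, 2))


class TestNiScore:
    def test_overlapping_hits(self):
        table = NiScoreTable({"AAAAAA": 1.0})
        ctx = TargetContext(exon_seq="AAAAAAA")
        assert ni_score_per_base(ctx, table) == pytest.approx(2 / 7)

    def test_single_exact_hit(self):
        table = NiScoreTable({"AAAAAA": 1.0})
        assert ni_score_per_base(TargetContext(exon_seq="AAAAAA"), table) == pytest.approx(1 / 6)

    def test_no_hits(self):
        table = NiScoreTable({"GGGGGG": 1.0})
        assert ni_score_per_base(TargetContext(exon_seq="AAAAAAA"), table) == 0.0

    def test_kmer_longer_than_exon(self):
        table = NiScoreTable({"AAAAAAAAAA": 1.0})
        assert ni_score_per_base(TargetContext(exon_seq="AAAA"), table) == 0.0

    def test_mixed_kmer_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            NiScoreTable({"AAAA": 1.0, "AAAAA": 2.0})

    def test_tsv_round_trip(self, tmp_path):
        table = NiScoreTable({"ACGUAC": 1.25, "GGGCCC": -0.5})
        path = tmp_path / "ni.tsv"
        table.to_tsv(path)
        assert NiScoreTable.from_tsv(path).scores == table.scores


class TestAccLast:
    def test_unstructured_context_fully_accessible(self):
        ctx = TargetContext(exon_seq="A" * 60, upstream_intron="A" * 40,
                            downstream_intron="A" * 40)
        from exonskip.features import ThermoResources
        res = ThermoResources()
        assert acc_last(ctx, 10, 40, 15, res) == 1.0
        assert acc_last(ctx, 10, 40, 8, res) == 1.0

    def test_value_in_unit_interval_and_suffix_consistency(self, toy_context):
        from exonskip.features import ThermoResources
        res = ThermoResources()
        a15 = acc_last(toy_context, 20, 49, 15, res)
        a8 = acc_last(toy_context, 20, 49, 8, res)
        assert 0.0 <= a15 <= 1.0 and 0.0 <= a8 <= 1.0
        # the 8-base region is the suffix of the 15-base region: both means
        # must be reproducible from the same cached profile
        profile = res.backend.unpaired_profile(toy_context.full_sequence)
        off = toy_context.exon_offset
        assert a15 == pytest.approx(profile[off + 49 - 15: off + 49].mean(), abs=1e-12)
        assert a8 == pytest.approx(profile[off + 49 - 8: off + 49].mean(), abs=1e-12)

    def test_short_site_falls_back_to_whole_site(self, toy_context):
        from exonskip.features import ThermoResources
        res = ThermoResources()
        whole = acc_last(toy_context, 30, 34, 5, res)
        assert acc_last(toy_context, 30, 34, 15, res) == pytest.approx(whole, abs=1e-12)


class TestComputeFeatures:
    def test_full_vector_finite_and_deterministic(self, toy_context):
        registry = default_registry(ni_table=NiScoreTable({"ACGUAC": 1.0}))
        v1 = compute_features(toy_context, 10, 39, reverse_complement(toy_context.exon_seq[9:39]),
                              3.0, registry)
        v2 = compute_features(toy_context, 10, 39, reverse_complement(toy_context.exon_seq[9:39]),
                              3.0, registry)
        assert v1.complete
        assert v1.values == v2.values
        assert all(math.isfinite(x) for x in v1.values.values())
        assert v1[CONCENTRATION_FEATURE] == 3.0

    def test_failing_feature_marks_vector_incomplete(self, toy_context):
        registry = FeatureRegistry([
            FeatureDefinition(CONCENTRATION_FEATURE, "", lambda *a: a[4]),
            FeatureDefinition("broken", "", lambda *a: 1 / 0),
        ])
        vec = compute_features(toy_context, 1, 20,
                               reverse_complement(toy_context.exon_seq[:20]), 3.0, registry)
        assert not vec.complete
        assert "broken" in vec.errors[0]

    def test_duplicate_registration_rejected(self):
        reg = default_registry()
        with pytest.raises(ValueError, match="duplicate"):
            reg.register(FeatureDefinition("ACP", "", lambda *a: 0.0))


class TestStandardization:
    def test_closed_form_column(self):
        scaler = standardize_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        out = standardize_apply(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), scaler)
        assert np.allclose(out["x"], [-1.224744871, 0.0, 1.224744871])

    def test_transformed_moments(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scaler = standardize_fit(X)
        Z = scaler.transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_column_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            scaler = standardize_fit(pd.DataFrame({"c": [5.0, 5.0, 5.0]}))
        assert scaler.scale_[0] == 1.0
        assert "constant" in caplog.text
        out = scaler.transform(pd.DataFrame({"c": [5.0, 5.0]}))
        assert np.allclose(out["c"], 0.0)

    def test_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        scaler = standardize_fit(X)
        back = scaler.inverse_transform(scaler.transform(X))
        assert np.allclose(back, X, atol=1e-12)


@given(st.integers(0, 2**31 - 1))
def test_context_generation_is_pure(seed):
    a = random_context(30, 0.5, seed)
    b = random_context(30, 0.5, seed)
    assert a.exon_seq == b.exon_seq and a.upstream_intron == b.upstream_intron
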