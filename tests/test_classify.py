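import math

import pytest

from aedesid.classify import (
    ConfusionCounts,
    call_record,
    call_sample,
    confusion_for_edna,
    confusion_for_group,
)
from aedesid.qpcr_io import (
    AEGYPTI,
    NO_DETECTION,
    ProbeChannel,
    ReplicateResult,
    SIERRENSIS,
)
from aedesid.simulate import GroupParams, generate_tissue_panel


def _wells(sierr_ct=None, aegy_ct=None, rep=1):
    return [
        ReplicateResult("s", rep, ProbeChannel.SIERR, sierr_ct is not None, sierr_ct),
        ReplicateResult("s", rep, ProbeChannel.AEGYPTI, aegy_ct is not None, aegy_ct),
    ]


class TestCallSample:
    @pytest.mark.parametrize(
        "sierr_ct, aegy_ct, expected_call, expected_ct",
        [
            (28.0, 35.0, SIERRENSIS, 28.0),  # dual amplification: lower Ct wins
            (None, 33.1, AEGYPTI, 33.1),
            (30.0, None, SIERRENSIS, 30.0),
            (None, None, NO_DETECTION, None),
            (36.0, 29.0, AEGYPTI, 29.0),
        ],
    )
    def test_lower_ct_rule(self, sierr_ct, aegy_ct, expected_call, expected_ct):
        call = call_sample(_wells(sierr_ct, aegy_ct))
        assert call.call == expected_call
        assert call.deciding_ct == expected_ct
        assert not call.tie

    def test_equal_ct_tie_goes_to_sierr_with_flag(self):
        call = call_sample(_wells(30.0, 30.0))
        assert call.call == SIERRENSIS
        assert call.tie

    def test_cutoff_suppresses_late_amplification(self):
        call = call_sample(_wells(30.0, 36.0), cutoff_aegy=32.0)
        assert call.call == SIERRENSIS
        call = call_sample(_wells(35.0, 36.0), cutoff_sierr=32.0, cutoff_aegy=32.0)
        assert call.call == NO_DETECTION

    def test_lowering_cutoff_never_adds_positive_channels(self, rng):
        for _ in range(50):
            sierr_ct = float(rng.uniform(10, 40)) if rng.random() < 0.7 else None
            aegy_ct = float(rng.uniform(10, 40)) if rng.random() < 0.7 else None
            wells = _wells(sierr_ct, aegy_ct)
            cut_hi, cut_lo = sorted(rng.uniform(10, 40, 2))[::-1]
            hi = call_sample(wells, cut_hi, cut_hi)
            lo = call_sample(wells, cut_lo, cut_lo)
            if hi.call == NO_DETECTION:
                assert lo.call == NO_DETECTION

    def test_probe_swap_symmetry(self, rng):
        for _ in range(50):
            sierr_ct = round(float(rng.uniform(10, 40)), 3) if rng.random() < 0.7 else None
            aegy_ct = round(float(rng.uniform(10, 40)), 3) if rng.random() < 0.7 else None
            if sierr_ct == aegy_ct:
                continue  # tie-break is deliberately asymmetric
            direct = call_sample(_wells(sierr_ct, aegy_ct))
            swapped = call_sample(_wells(aegy_ct, sierr_ct))
            flip = {SIERRENSIS: AEGYPTI, AEGYPTI: SIERRENSIS, NO_DETECTION: NO_DETECTION}
            assert swapped.call == flip[direct.call]


class TestCallRecord:
    def test_majority_vote_across_replicates(self, edna_record_factory):
        rec = edna_record_factory("e", (30.0, 31.0, None), (29.0, None, None))
        # replicate calls: aegypti (29 < 30), sierrensis, no_detection
        # tie between species broken by lower total deciding Ct: aegypti (29 < 31)
        assert call_record(rec).call == AEGYPTI

    def test_singlicate_reduces_to_call_sample(self, tissue_record_factory):
        rec = tissue_record_factory("t", SIERRENSIS, correct_ct=22.0)
        assert call_record(rec).call == SIERRENSIS


class TestConfusionForGroup:
    def test_perfect_assay(self, tissue_record_factory):
        recs = [tissue_record_factory(f"s{i}", SIERRENSIS, correct_ct=20.0) for i in range(10)]
        assert confusion_for_group(recs) == ConfusionCounts(tp=10, fp=0, tn=10, fn=0)

    def test_mixed_errors_forced_by_definitions(self, tissue_record_factory):
        recs = [
            tissue_record_factory("a1", AEGYPTI, correct_ct=25.0),
            tissue_record_factory("a2", AEGYPTI, correct_ct=25.0),
            tissue_record_factory("a3", AEGYPTI, correct_ct=None),  # false negative
            tissue_record_factory("a4", AEGYPTI, correct_ct=25.0, wrong_ct=36.0),
        ]
        assert confusion_for_group(recs) == ConfusionCounts(tp=3, fp=1, tn=3, fn=1)

    def test_channel_totals_equal_group_size(self):
        gp = GroupParams("g/field/sierrensis", "larva", "field", SIERRENSIS,
                         200, 18.0, 4.0, 0.118, 0.007)
        ds = generate_tissue_panel([gp], seed=6)
        counts = confusion_for_group(ds.records)
        assert counts.tp + counts.fn == 200
        assert counts.fp + counts.tn == 200

    def test_generator_round_trip_at_scale(self):
        n, fn_rate = 10_000, 0.118
        gp = GroupParams("g/field/sierrensis", "larva", "field", SIERRENSIS,
                         n, 18.0, 4.0, fn_rate, 0.0)
        counts = confusion_for_group(generate_tissue_panel([gp], seed=8).records)
        observed = counts.fn / (counts.tp + counts.fn)
        assert abs(observed - fn_rate) <= 3 * math.sqrt(fn_rate * (1 - fn_rate) / n)

    def test_unknown_species_rejected(self, edna_record_factory):
        rec = edna_record_factory("e", (30.0, None, None), (None, None, None))
        with pytest.raises(ValueError, match="proxy"):
            confusion_for_group([rec])

    def test_probe_swap_transposes_counts(self, tissue_record_factory):
        recs = [
            tissue_record_factory("a1", AEGYPTI, correct_ct=25.0),
            tissue_record_factory("a2", AEGYPTI, correct_ct=None, wrong_ct=36.0),
            tissue_record_factory("a3", AEGYPTI, correct_ct=25.0, wrong_ct=36.0),
        ]
        swapped = []
        for rec in recs:
            clone = tissue_record_factory(rec.sample_id, rec.verified_species)
            clone.results = [
                ReplicateResult(r.sample_id, r.replicate, r.probe.other, r.amplified, r.ct)
                for r in rec.results
            ]
            swapped.append(clone)
        before = confusion_for_group(recs)
        after = confusion_for_group(swapped)
        assert (after.tp, after.fn, after.fp, after.tn) == (
            before.fp, before.tn, before.tp, before.fn
        )


class TestConfusionForEdna:
    def test_all_correct_sierrensis_replicates(self, edna_record_factory):
        recs = [
            edna_record_factory(f"e{i}", (30.0, 31.0, 29.0), (None, None, None))
            for i in range(4)
        ]
        truth = {r.sample_id: SIERRENSIS for r in recs}
        counts = confusion_for_edna(recs, truth)[SIERRENSIS]
        assert counts.tp == 12 and counts.fn == 0
        assert counts.tn == 12 and counts.fp == 0

    def test_no_detection_amplification_is_false_positive(self, edna_record_factory):
        rec = edna_record_factory("e0", (34.1, None, None), (None, None, None))
        counts = confusion_for_edna([rec], {"e0": NO_DETECTION})[NO_DETECTION]
        assert counts.fp == 1
        assert counts.tn == 5  # remaining 5 silent wells
        assert counts.tp == 0 and counts.fn == 0

    def test_empty_class_has_zero_counts(self, edna_record_factory):
        rec = edna_record_factory("e0", (30.0, 30.0, 30.0), (None, None, None))
        counts = confusion_for_edna([rec], {"e0": SIERRENSIS})
        assert counts[AEGYPTI] == ConfusionCounts()

    def test_missing_proxy_truth_is_error(self, edna_record_factory):
        rec = edna_record_factory("e0", (30.0, None, None), (None, None, None))
        with pytest.raises(KeyError, match="e0"):
            confusion_for_edna([rec], {})

    def test_cross_probe_amplification_in_species_class(self, edna_record_factory):
        rec = edna_record_factory("e0", (30.0, 30.0, 30.0), (37.0, None, None))
        counts = confusion_for_edna([rec], {"e0": SIERRENSIS})[SIERRENSIS]
        assert counts == ConfusionCounts(tp=3, fp=1, tn=2, fn=0)
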