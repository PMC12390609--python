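"""Species calling and confusion-count tallies for the two-probe assay.

A sample (or one replicate of an eDNA sample) is called by presence/absence
of amplification on the two probe channels, with an optional maximum-Ct
cutoff per channel. When both channels qualify, the lower-Ct channel wins:
a lower cycle threshold reflects higher target-DNA abundance and is taken
to indicate the true species, with dual amplification interpreted as
non-specific cross-amplification rather than co-occurrence.

Confusion counts follow per-channel truth definitions: for a specimen of
verified species S, amplification on the S channel is a true positive (its
absence a false negative) and amplification on the other channel a false
positive (its absence a true negative). Each specimen therefore contributes
one positive-truth and one negative-truth observation. eDNA samples are
evaluated the same way per extraction replicate, against the latent-class
proxy truth; the no-detection class has no correct channel, so both
channels contribute only to its specificity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .qpcr_io import (
    AEGYPTI,
    MAX_CYCLES,
    NO_DETECTION,
    ProbeChannel,
    ReplicateResult,
    SIERRENSIS,
    SpecimenRecord,
    channel_for_species,
)


@dataclass(frozen=True)
class SpeciesCall:
    """Outcome of calling one sample or replicate."""

    call: str  # "sierrensis" | "aegypti" | "no_detection"
    deciding_probe: ProbeChannel | None = None
    deciding_ct: float | None = None
    tie: bool = False

    def __post_init__(self) -> None:
        if (self.call == NO_DETECTION) != (self.deciding_probe is None):
            raise ValueError("deciding_probe must be absent iff call is no_detection")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def call_sample(
    results: Sequence[ReplicateResult],
    cutoff_sierr: float = MAX_CYCLES,
    cutoff_aegy: float = MAX_CYCLES,
) -> SpeciesCall:
    """Call the species for one sample (or one replicate) from its wells.

    A channel is positive iff at least one well amplified with Ct at or
    below that channel's cutoff; its deciding Ct is the minimum qualifying
    Ct. Both channels positive -> the lower-Ct channel's species; an exact
    Ct tie goes to sierr_PRB (canonical channel order) with ``tie=True``.
    """
    cutoffs = {ProbeChannel.SIERR: cutoff_sierr, ProbeChannel.AEGYPTI: cutoff_aegy}
    best: dict[ProbeChannel, float] = {}
    for r in results:
        if r.amplified and r.ct is not None and r.ct <= cutoffs[r.probe]:
            if r.probe not in best or r.ct < best[r.probe]:
                best[r.probe] = r.ct
    if not best:
        return SpeciesCall(call=NO_DETECTION)
    if len(best) == 1:
        probe, ct = next(iter(best.items()))
        return SpeciesCall(call=probe.target_species, deciding_probe=probe, deciding_ct=ct)
    ct_s = best[ProbeChannel.SIERR]
    ct_a = best[ProbeChannel.AEGYPTI]
    if ct_s == ct_a:
        return SpeciesCall(
            call=SIERRENSIS, deciding_probe=ProbeChannel.SIERR, deciding_ct=ct_s, tie=True
        )
    probe = ProbeChannel.SIERR if ct_s < ct_a else ProbeChannel.AEGYPTI
    return SpeciesCall(
        call=probe.target_species, deciding_probe=probe, deciding_ct=min(ct_s, ct_a)
    )


def call_record(
    record: SpecimenRecord,
    cutoff_sierr: float = MAX_CYCLES,
    cutoff_aegy: float = MAX_CYCLES,
) -> SpeciesCall:
    """Sample-level call: per-replicate calls aggregated by majority.

    Ties on the majority vote go to the candidate with the lower total
    deciding Ct (more DNA); singlicate records reduce to one call.
    """
    replicates = sorted({r.replicate for r in record.results})
    calls = [
        call_sample(
            [r for r in record.results if r.replicate == rep], cutoff_sierr, cutoff_aegy
        )
        for rep in replicates
    ]
    if len(calls) == 1:
        return calls[0]
    votes: dict[str, int] = defaultdict(int)
    total_ct: dict[str, float] = defaultdict(float)
    for c in calls:
        votes[c.call] += 1
        if c.deciding_ct is not None:
            total_ct[c.call] += c.deciding_ct
    top = max(votes.values())
    leaders = [k for k, v in votes.items() if v == top]
    if len(leaders) == 1:
        winner = leaders[0]
    else:
        # no_detection carries no Ct; species candidates with lower total Ct win
        species_leaders = [k for k in leaders if k != NO_DETECTION]
        winner = (
            min(species_leaders, key=lambda k: total_ct[k])
            if species_leaders
            else NO_DETECTION
        )
    for c in calls:
        if c.call == winner:
            return c
    raise AssertionError("unreachable: winner has no supporting call")


def replicate_calls(
    record: SpecimenRecord,
    cutoff_sierr: float = MAX_CYCLES,
    cutoff_aegy: float = MAX_CYCLES,
) -> dict[int, SpeciesCall]:
    """Per-replicate calls for one record, keyed by replicate index."""
    return {
        rep: call_sample(
            [r for r in record.results if r.replicate == rep], cutoff_sierr, cutoff_aegy
        )
        for rep in sorted({r.replicate for r in record.results})
    }


def _channel_amplified(record: SpecimenRecord, probe: ProbeChannel) -> bool:
    return any(r.amplified for r in record.results_for(probe))


def confusion_for_group(records: Sequence[SpecimenRecord]) -> ConfusionCounts:
    """Tally per-channel confusion counts for verified tissue specimens.

    Per specimen: the verified-species channel contributes TP if amplified,
    else FN; the other channel contributes FP if amplified, else TN. Hence
    ``tp + fn == fp + tn == len(records)``.
    """
    tp = fp = tn = fn = 0
    for rec in records:
        if rec.verified_species not in (SIERRENSIS, AEGYPTI):
            raise ValueError(
                f"record {rec.sample_id!r} has verified_species="
                f"{rec.verified_species!r}; confusion counting needs a verified "
                "species (use the latent-class proxy truth for eDNA)"
            )
        correct = channel_for_species(rec.verified_species)
        if _channel_amplified(rec, correct):
            tp += 1
        else:
            fn += 1
        if _channel_amplified(rec, correct.other):
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_for_edna(
    records: Sequence[SpecimenRecord],
    proxy_truth: Mapping[str, str],
) -> dict[str, ConfusionCounts]:
    """Per-class confusion counts for eDNA, one unit per extraction replicate.

    For a sample designated to a species class, each replicate's
    correct-probe well contributes TP/FN and its wrong-probe well FP/TN.
    Samples designated no-detection have no correct probe: every amplified
    well is a false positive and every silent well a true negative, so the
    class yields only specificity.
    """
    counts: dict[str, ConfusionCounts] = {
        SIERRENSIS: ConfusionCounts(),
        AEGYPTI: ConfusionCounts(),
        NO_DETECTION: ConfusionCounts(),
    }
    for rec in records:
        if rec.sample_id not in proxy_truth:
            raise KeyError(f"sample {rec.sample_id!r} missing from proxy truth")
        cls = proxy_truth[rec.sample_id]
        if cls not in counts:
            raise ValueError(f"sample {rec.sample_id!r}: unknown class {cls!r}")
        for rep in sorted({r.replicate for r in rec.results}):
            wells = [r for r in rec.results if r.replicate == rep]
            amp = {
                probe: any(r.amplified for r in wells if r.probe is probe)
                for probe in ProbeChannel
            }
            tp = fp = tn = fn = 0
            if cls == NO_DETECTION:
                for probe in ProbeChannel:
                    if amp[probe]:
                        fp += 1
                    else:
                        tn += 1
            else:
                correct = channel_for_species(cls)
                if amp[correct]:
                    tp += 1
                else:
                    fn += 1
                if amp[correct.other]:
                    fp += 1
                else:
                    tn += 1
            counts[cls] = counts[cls] + ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts
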