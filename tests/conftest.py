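import numpy as np
import pytest

from aedesid.qpcr_io import (
    AEGYPTI,
    ProbeChannel,
    ReplicateResult,
    SIERRENSIS,
    SpecimenRecord,
    UNKNOWN,
    channel_for_species,
)


@pytest.fixture
def tissue_record_factory():
    """Build a singlicate two-channel tissue record from optional Ct values."""

    def build(
        sample_id: str,
        species: str = SIERRENSIS,
        correct_ct: float | None = None,
        wrong_ct: float | None = None,
        life_stage: str = "egg",
        source: str = "colony",
    ) -> SpecimenRecord:
        correct = channel_for_species(species)
        results = [
            ReplicateResult(sample_id, 1, correct, correct_ct is not None, correct_ct),
            ReplicateResult(sample_id, 1, correct.other, wrong_ct is not None, wrong_ct),
        ]
        return SpecimenRecord(sample_id, "tissue", life_stage, source, species, results)

    return build


@pytest.fixture
def edna_record_factory():
    """Build a 3x2-well eDNA record from per-well Ct values (None = no amp)."""

    def build(sample_id: str, sierr_cts, aegy_cts) -> SpecimenRecord:
        results = []
        for probe, cts in ((ProbeChannel.SIERR, sierr_cts), (ProbeChannel.AEGYPTI, aegy_cts)):
            for rep, ct in enumerate(cts, start=1):
                results.append(
                    ReplicateResult(sample_id, rep, probe, ct is not None, ct)
                )
        return SpecimenRecord(sample_id, "edna", "none", "field", UNKNOWN, results)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
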