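"""Data model and long-format I/O for multiplex qPCR species-identification results.

The assay interrogates every sample on two fluorescence channels, one per
species-specific hydrolysis probe: ``sierr_PRB`` reports *Aedes sierrensis*
(FAM) and ``aegypti_PRB`` reports *Aedes aegypti* (ABY). A single well
contributes one :class:`ReplicateResult` — the instrument-called
amplification flag plus the cycle threshold (Ct) when amplification
occurred. The run is capped at 40 cycles, so every Ct lies in (0, 40].

Tissue specimens carry a morphologically verified species label and serve
as the gold standard for diagnostic evaluation. eDNA site samples have no
such label; they are assayed in three extraction replicates per probe and
are analysed through their 6-indicator binary amplification pattern
(coded 2 = amplification, 1 = none), the input to the latent-class model.

The canonical on-disk format is a long CSV, one row per well, with header
``sample_id,sample_kind,life_stage,source,verified_species,replicate,probe,amplified,ct``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

MAX_CYCLES = 40.0

#: Species labels used throughout the package.
SIERRENSIS = "sierrensis"
AEGYPTI = "aegypti"
NO_DETECTION = "no_detection"
UNKNOWN = "unknown"

LIFE_STAGES = ("egg", "larva", "adult", "none")
SAMPLE_KINDS = ("tissue", "edna")

#: Number of binary indicators per eDNA pattern row (3 replicates x 2 probes).
N_INDICATORS = 6


class FormatError(ValueError):
    """The file does not conform to the canonical table layout."""


class ValidationError(ValueError):
    """The table parsed but violates a data-model invariant."""


class ProbeChannel(str, Enum):
    """The two fluorescence channels of the multiplex assay."""

    SIERR = "sierr_PRB"
    AEGYPTI = "aegypti_PRB"

    @property
    def target_species(self) -> str:
        return SIERRENSIS if self is ProbeChannel.SIERR else AEGYPTI

    @property
    def other(self) -> "ProbeChannel":
        return ProbeChannel.AEGYPTI if self is ProbeChannel.SIERR else ProbeChannel.SIERR


#: Canonical indicator order for pattern rows: sierr reps 1-3, then aegypti reps 1-3.
PATTERN_ORDER: tuple[tuple[ProbeChannel, int], ...] = tuple(
    (probe, rep) for probe in (ProbeChannel.SIERR, ProbeChannel.AEGYPTI) for rep in (1, 2, 3)
)


def channel_for_species(species: str) -> ProbeChannel:
    """Probe channel whose target is ``species``."""
    if species == SIERRENSIS:
        return ProbeChannel.SIERR
    if species == AEGYPTI:
        return ProbeChannel.AEGYPTI
    raise ValueError(f"no probe channel targets species {species!r}")


@dataclass(frozen=True)
class ReplicateResult:
    """One probe-channel measurement for one qPCR replicate of one sample.

    ``ct`` is present if and only if ``amplified`` is true; an amplified well
    without a Ct cannot feed the lower-Ct species-calling rule, and a Ct on a
    non-amplified well is contradictory instrument output.
    """

    sample_id: str
    replicate: int
    probe: ProbeChannel
    amplified: bool
    ct: float | None = None
    qc_flag: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate index must be >= 1")
        if self.amplified and self.ct is None:
            raise ValidationError(f"{self.sample_id}: amplified well lacks a Ct value")
        if not self.amplified and self.ct is not None:
            raise ValidationError(f"{self.sample_id}: Ct present but amplified=false")
        if self.ct is not None and not (0.0 < self.ct <= MAX_CYCLES):
            raise ValidationError(
                f"{self.sample_id}: ct={self.ct} outside (0, {MAX_CYCLES:g}]"
            )


@dataclass
class SpecimenRecord:
    """One physical specimen (tissue) or one eDNA extraction replicate sample."""

    sample_id: str
    sample_kind: str  # "tissue" | "edna"
    life_stage: str  # "egg" | "larva" | "adult" | "none"
    source: str
    verified_species: str  # "sierrensis" | "aegypti" | "unknown"
    results: list[ReplicateResult] = field(default_factory=list)

    @property
    def group_label(self) -> str:
        return f"{self.life_stage}/{self.source}/{self.verified_species}"

    def results_for(self, probe: ProbeChannel) -> list[ReplicateResult]:
        return [r for r in self.results if r.probe is probe]

    def result_at(self, probe: ProbeChannel, replicate: int) -> ReplicateResult | None:
        for r in self.results:
            if r.probe is probe and r.replicate == replicate:
                return r
        return None


@dataclass(frozen=True)
class PatternRow:
    """6 coded indicators in {1, 2} for one eDNA sample (2 = amplification)."""

    sample_id: str
    indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indicators) != N_INDICATORS:
            raise ValidationError(
                f"{self.sample_id}: pattern has {len(self.indicators)} indicators, "
                f"expected {N_INDICATORS}"
            )
        if any(v not in (1, 2) for v in self.indicators):
            raise ValidationError(f"{self.sample_id}: indicator values must be 1 or 2")


@dataclass
class Dataset:
    """A collection of specimen records plus free-form provenance metadata."""

    records: list[SpecimenRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def tissue_records(self) -> list[SpecimenRecord]:
        return [r for r in self.records if r.sample_kind == "tissue"]

    def edna_records(self) -> list[SpecimenRecord]:
        return [r for r in self.records if r.sample_kind == "edna"]

    def by_id(self) -> dict[str, SpecimenRecord]:
        return {r.sample_id: r for r in self.records}


RESULTS_COLUMNS = (
    "sample_id",
    "sample_kind",
    "life_stage",
    "source",
    "verified_species",
    "replicate",
    "probe",
    "amplified",
    "ct",
)


def _parse_bool(text: str, where: str) -> bool:
    lowered = text.strip().lower()
    if lowered == "true":
        return True
    if lowered == "false":
        return False
    raise FormatError(f"{where}: amplified must be 'true' or 'false', got {text!r}")


def read_results_table(path: str | Path) -> Dataset:
    """Read the canonical long-format results CSV into a validated Dataset.

    Rows are grouped by ``sample_id`` (order of first appearance). Malformed
    rows raise with 1-based line numbers; the header is line 1.
    """
    path = Path(path)
    records: dict[str, SpecimenRecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in RESULTS_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            sample_id = (row["sample_id"] or "").strip()
            if not sample_id:
                raise FormatError(f"{where}: empty sample_id")
            try:
                probe = ProbeChannel(row["probe"].strip())
            except ValueError:
                raise FormatError(
                    f"{where}: unknown probe {row['probe']!r}; expected "
                    f"{ProbeChannel.SIERR.value} or {ProbeChannel.AEGYPTI.value}"
                ) from None
            amplified = _parse_bool(row["amplified"], where)
            ct_text = (row.get("ct") or "").strip()
            ct = None
            if ct_text:
                try:
                    ct = float(ct_text)
                except ValueError:
                    raise FormatError(f"{where}: ct {ct_text!r} is not a number") from None
            try:
                replicate = int(row["replicate"])
            except ValueError:
                raise FormatError(
                    f"{where}: replicate {row['replicate']!r} is not an integer"
                ) from None
            try:
                result = ReplicateResult(
                    sample_id=sample_id,
                    replicate=replicate,
                    probe=probe,
                    amplified=amplified,
                    ct=ct,
                    qc_flag=(row.get("qc_flag") or "").strip() or None,
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from None
            kind = row["sample_kind"].strip()
            if kind not in SAMPLE_KINDS:
                raise FormatError(f"{where}: unknown sample_kind {kind!r}")
            stage = row["life_stage"].strip()
            if stage not in LIFE_STAGES:
                raise FormatError(f"{where}: unknown life_stage {stage!r}")
            species = row["verified_species"].strip()
            if species not in (SIERRENSIS, AEGYPTI, UNKNOWN):
                raise FormatError(f"{where}: unknown verified_species {species!r}")
            rec = records.get(sample_id)
            if rec is None:
                rec = SpecimenRecord(
                    sample_id=sample_id,
                    sample_kind=kind,
                    life_stage=stage,
                    source=row["source"].strip(),
                    verified_species=species,
                )
                records[sample_id] = rec
            elif (rec.sample_kind, rec.life_stage, rec.verified_species) != (
                kind,
                stage,
                species,
            ):
                raise ValidationError(
                    f"{where}: metadata for sample {sample_id!r} disagrees with an "
                    "earlier row"
                )
            rec.results.append(result)
    dataset = Dataset(records=list(records.values()), metadata={"path": str(path)})
    issues = validate_dataset(dataset)
    if issues:
        raise ValidationError(f"{path}: " + "; ".join(issues))
    return dataset


def write_results_table(dataset: Dataset, path: str | Path, ct_decimals: int = 3) -> None:
    """Write a Dataset to the canonical long CSV (one row per well)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_COLUMNS)
        for rec in dataset.records:
            for r in rec.results:
                writer.writerow(
                    [
                        rec.sample_id,
                        rec.sample_kind,
                        rec.life_stage,
                        rec.source,
                        rec.verified_species,
                        r.replicate,
                        r.probe.value,
                        "true" if r.amplified else "false",
                        "" if r.ct is None else f"{r.ct:.{ct_decimals}f}",
                    ]
                )


def validate_dataset(dataset: Dataset) -> list[str]:
    """Return a list of invariant violations (empty when the dataset is valid).

    Never raises and never mutates its input; callers decide severity.
    """
    issues: list[str] = []
    seen: set[str] = set()
    for rec in dataset.records:
        if rec.sample_id in seen:
            issues.append(f"duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        if rec.sample_kind == "tissue":
            if rec.life_stage == "none":
                issues.append(f"tissue record {rec.sample_id!r} has life_stage=none")
        elif rec.sample_kind == "edna":
            if rec.verified_species != UNKNOWN:
                issues.append(
                    f"edna record {rec.sample_id!r} has verified_species="
                    f"{rec.verified_species!r}, expected {UNKNOWN!r}"
                )
            if len(rec.results) != N_INDICATORS:
                issues.append(
                    f"edna record {rec.sample_id!r} has {len(rec.results)} results, "
                    f"expected {N_INDICATORS} (3 replicates x 2 probes)"
                )
        else:
            issues.append(f"record {rec.sample_id!r} has unknown kind {rec.sample_kind!r}")
        keys = [(r.probe, r.replicate) for r in rec.results]
        if len(set(keys)) != len(keys):
            issues.append(f"record {rec.sample_id!r} has duplicate (probe, replicate) wells")
    return issues


def to_patterns(dataset: Dataset) -> list[PatternRow]:
    """Convert eDNA records to 1/2-coded pattern rows in canonical order.

    Indicator order is fixed: sierr_PRB replicates 1-3 then aegypti_PRB
    replicates 1-3. Indicator j is 2 iff the corresponding well amplified.
    """
    patterns: list[PatternRow] = []
    for rec in dataset.edna_records():
        indicators = []
        for probe, rep in PATTERN_ORDER:
            result = rec.result_at(probe, rep)
            if result is None:
                raise ValidationError(
                    f"edna record {rec.sample_id!r} missing well "
                    f"({probe.value}, replicate {rep})"
                )
            indicators.append(2 if result.amplified else 1)
        patterns.append(PatternRow(sample_id=rec.sample_id, indicators=tuple(indicators)))
    return patterns


def patterns_from_indicators(rows: Iterable[tuple[str, Sequence[int]]]) -> list[PatternRow]:
    return [PatternRow(sample_id=sid, indicators=tuple(ind)) for sid, ind in rows]


def write_patterns(patterns: Sequence[PatternRow], path: str | Path) -> None:
    """Export pattern rows as ``sample_id,y1..y6`` CSV (1/2 coding)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id"] + [f"y{j}" for j in range(1, N_INDICATORS + 1)])
        for p in patterns:
            writer.writerow([p.sample_id, *p.indicators])


def read_patterns(path: str | Path) -> list[PatternRow]:
    """Read a ``sample_id,y1..y6`` pattern CSV."""
    path = Path(path)
    expected = ["sample_id"] + [f"y{j}" for j in range(1, N_INDICATORS + 1)]
    patterns: list[PatternRow] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c for c in expected if c not in reader.fieldnames]:
            raise FormatError(f"{path}: expected columns {','.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                indicators = tuple(int(row[f"y{j}"]) for j in range(1, N_INDICATORS + 1))
                patterns.append(PatternRow(row["sample_id"], indicators))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return patterns
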