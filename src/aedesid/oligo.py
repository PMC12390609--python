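"""In-silico specificity scan of the assay's primers and probes.

The assay discriminates two species via fixed SNP differences in the COI
barcode, so hybridisation specificity reduces to substitution (Hamming)
mismatches between each oligo and its best binding window — no indels.
Each oligo is slid over the reference on both strands (minus-strand
binding is detected by matching the oligo's reverse complement against
the plus-strand sequence) and the minimum-mismatch window reported.
IUPAC ambiguity codes in the reference match any compatible base; the
oligos themselves are unambiguous. Fluorophore/quencher annotations and
internal modifications (e.g. ZEN) are metadata and never matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .qpcr_io import AEGYPTI, SIERRENSIS

FORWARD_PRIMER = "forward_primer"
REVERSE_PRIMER = "reverse_primer"
PROBE = "probe"

#: ref base (possibly ambiguous) -> set of concrete bases it can represent
_IUPAC: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


@dataclass(frozen=True)
class Oligo:
    name: str
    sequence: str  # matchable bases only, uppercase A/C/G/T
    role: str
    target_species: str
    label: str | None = None  # fluorophore/quencher annotation, metadata only

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"oligo {self.name!r} contains non-ACGT bases {sorted(bad)}")


@dataclass(frozen=True)
class OligoHit:
    reference_id: str
    start: int  # 0-based, half-open window [start, start + len(oligo))
    strand: str  # "+" | "-" relative to the supplied reference
    mismatches: int


def builtin_oligos() -> list[Oligo]:
    """The six published primers and probes, modification tags stripped."""
    return [
        Oligo("aegypti-F", "TGATTAGCAACTTTACACGGAAC", FORWARD_PRIMER, AEGYPTI),
        Oligo("aegypti-R", "AGCTAATACTACTCCTGTTAAACCT", REVERSE_PRIMER, AEGYPTI),
        Oligo("sierrensis-F", "CCTCCTTCATTAACCCTACTACTTT", FORWARD_PRIMER, SIERRENSIS),
        Oligo("sierrensis-R", "GATGATACTCCAGCTAAATGAAGAG", REVERSE_PRIMER, SIERRENSIS),
        Oligo(
            "aegypti-PRB",
            "TCCAGCCCTTCTATGATCATTAGGATCTGT",
            PROBE,
            AEGYPTI,
            label="ABY/IAbRQSp",
        ),
        Oligo(
            "sierrensis-PRB",
            # internal ZEN quencher sits between the two halves
            "TGGAGCTGGTACAGGATGAACTGT",
            PROBE,
            SIERRENSIS,
            label="FAM/ZEN/IABkFQ",
        ),
    ]


def _base_matches(oligo_base: str, ref_base: str) -> bool:
    allowed = _IUPAC.get(ref_base.upper())
    return oligo_base in allowed if allowed else False


def _hamming(query: str, window: str) -> int:
    return sum(not _base_matches(q, w) for q, w in zip(query, window))


def scan(
    reference: str,
    oligo: Oligo,
    max_mismatches: int | None = None,
    reference_id: str = "ref",
) -> tuple[OligoHit, list[OligoHit]]:
    """Best binding window of an oligo on both strands of a reference.

    Returns ``(best, hits)`` where ``hits`` contains every window with at
    most ``max_mismatches`` mismatches (best-only when None). Ties for
    the best hit prefer the plus strand, then the lowest start.
    """
    ref = reference.upper()
    m = len(oligo.sequence)
    if len(ref) < m:
        raise ValueError(
            f"reference {reference_id!r} (length {len(ref)}) is shorter than "
            f"oligo {oligo.name!r} (length {m})"
        )
    rc = str(Seq(oligo.sequence).reverse_complement())
    hits: list[OligoHit] = []
    for strand, query in (("+", oligo.sequence), ("-", rc)):
        for start in range(len(ref) - m + 1):
            mm = _hamming(query, ref[start : start + m])
            hits.append(OligoHit(reference_id, start, strand, mm))
    best = min(hits, key=lambda h: (h.mismatches, h.strand != "+", h.start))
    if max_mismatches is None:
        kept = [best]
    else:
        kept = [h for h in hits if h.mismatches <= max_mismatches]
    return best, kept


def assay_report(
    references: Sequence[tuple[str, str]],
    oligos: Sequence[Oligo] | None = None,
    ref_species: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Best-hit mismatch matrix (oligo x reference) with cross-reactivity flags.

    A flag is raised when an oligo matches a non-target reference at least
    as well as its target. Reference species are taken from ``ref_species``
    or inferred from 'sierr'/'aegy' substrings in the reference id.
    """
    if not references or (oligos is not None and not oligos):
        raise ValueError("assay_report needs at least one reference and one oligo")
    oligos = list(oligos) if oligos is not None else builtin_oligos()

    def species_of(ref_id: str) -> str | None:
        if ref_species and ref_id in ref_species:
            return ref_species[ref_id]
        low = ref_id.lower()
        if "sierr" in low:
            return SIERRENSIS
        if "aegy" in low:
            return AEGYPTI
        return None

    table = pd.DataFrame(
        {
            ref_id: [scan(seq, o, reference_id=ref_id)[0].mismatches for o in oligos]
            for ref_id, seq in references
        },
        index=[o.name for o in oligos],
    )
    flags: list[str] = []
    for o in oligos:
        target_refs = [rid for rid, _ in references if species_of(rid) == o.target_species]
        other_refs = [
            rid
            for rid, _ in references
            if species_of(rid) not in (None, o.target_species)
        ]
        if not target_refs or not other_refs:
            continue
        best_target = min(table.loc[o.name, rid] for rid in target_refs)
        for rid in other_refs:
            if table.loc[o.name, rid] <= best_target:
                flags.append(
                    f"{o.name}: {table.loc[o.name, rid]} mismatch(es) against "
                    f"non-target {rid} vs {best_target} against its target"
                )
    return table, flags


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_oligo_table(path: str | Path) -> list[Oligo]:
    """Read oligos from TSV with columns name, sequence, role, target_species."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "sequence", "role", "target_species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        Oligo(
            name=row["name"],
            sequence=str(row["sequence"]).upper(),
            role=row["role"],
            target_species=row["target_species"],
        )
        for _, row in df.iterrows()
    ]
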