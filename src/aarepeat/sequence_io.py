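"""Protein/CDS FASTA input, isoform selection and protein–CDS pairing.

Proteome-scale repeat analysis needs one protein per gene and, for the
codon-level statistics, the coding sequence that produced it.  This module
reads the two FASTA files, picks the longest isoform per gene (deterministic
tie-break) and pairs each protein with its CDS, splitting the CDS into one
codon per residue after stripping a terminal stop codon.

Coordinates are 0-based, half-open everywhere in this package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: letters accepted in a validated protein sequence ('X' = unknown residue)
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
NUCLEOTIDES = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: default Ensembl/Biomart-style header: ">PROTID ... gene:GENEID ..."
DEFAULT_HEADER_PATTERN = re.compile(r"gene:(?P<gene_id>\S+)")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class RecordValidationError(ValueError):
    """A FASTA entry violates the protein/CDS record contract."""


class PairingError(ValueError):
    """Protein and CDS cannot be reconciled into a PairedRecord."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    species: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingRecord:
    protein_id: str
    nucleotide_sequence: str

    def __len__(self) -> int:
        return len(self.nucleotide_sequence)


@dataclass(frozen=True)
class PairedRecord:
    """A protein together with its in-frame codon decomposition.

    ``ambiguous`` holds residue positions whose codon cannot be trusted
    (unknown residue 'X', codon containing 'N', or a tolerated translation
    mismatch).  Such positions never contribute to pure-codon runs.
    """

    protein: ProteinRecord
    cds: CodingRecord
    codons: tuple[str, ...]
    ambiguous: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.protein.sequence):
            raise PairingError(
                f"{self.protein.protein_id}: {len(self.codons)} codons for "
                f"{len(self.protein.sequence)} residues"
            )


def _parse_gene_id(description: str, protein_id: str, pattern: re.Pattern) -> str:
    m = pattern.search(description)
    if m:
        return m.group("gene_id")
    # fall back to the protein id so single-isoform inputs still work
    return protein_id


def read_protein_fasta(
    path: str | Path,
    species: str = "",
    header_pattern: re.Pattern | str = DEFAULT_HEADER_PATTERN,
    gene_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[ProteinRecord]:
    """Read a protein FASTA into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    header_pattern
        Regular expression with a named group ``gene_id`` applied to the
        FASTA description; overridden by ``gene_map`` when given.
    gene_map
        Explicit ``protein_id -> gene_id`` mapping (e.g. from a TSV).
    strict
        In strict mode a non-standard letter or an internal stop ``*`` is an
        error naming the offending record; otherwise the record is skipped
        with a warning.
    """
    if isinstance(header_pattern, str):
        header_pattern = re.compile(header_pattern)
    records: list[ProteinRecord] = []
    path = Path(path)
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise RecordValidationError(f"{entry.id}: empty sequence in {path.name}")
        bad = sorted(set(seq) - PROTEIN_ALPHABET)
        if bad:
            msg = f"{entry.id}: illegal letter(s) {','.join(bad)} in {path.name}"
            if strict:
                raise RecordValidationError(msg)
            warnings.warn(msg + " -- record skipped")
            continue
        if gene_map is not None:
            if entry.id not in gene_map:
                raise RecordValidationError(f"{entry.id}: missing from gene map")
            gene_id = gene_map[entry.id]
        else:
            gene_id = _parse_gene_id(entry.description, entry.id, header_pattern)
        records.append(ProteinRecord(entry.id, gene_id, species, seq))
    return records


def read_cds_fasta(path: str | Path, strict: bool = True) -> dict[str, CodingRecord]:
    """Read a CDS FASTA keyed by protein id (first header token)."""
    out: dict[str, CodingRecord] = {}
    path = Path(path)
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise RecordValidationError(f"{entry.id}: empty sequence in {path.name}")
        bad = sorted(set(seq) - NUCLEOTIDES)
        if bad:
            msg = f"{entry.id}: illegal nucleotide(s) {','.join(bad)} in {path.name}"
            if strict:
                raise RecordValidationError(msg)
            warnings.warn(msg + " -- record skipped")
            continue
        out[entry.id] = CodingRecord(entry.id, seq)
    return out


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} gene:{rec.gene_id}\n{rec.sequence}\n")


def write_cds_fasta(records: Iterable[CodingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.nucleotide_sequence}\n")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (protein_id, gene_id)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FastaParseError(f"gene map line {lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def select_longest_isoform(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the longest protein per gene (tie: lexicographically smallest id).

    Output order follows the first appearance of each gene.  Idempotent.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.gene_id not in best:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
            continue
        cur = best[rec.gene_id]
        # longer wins; on equal length the smaller protein_id wins
        if len(rec.sequence) > len(cur.sequence) or (
            len(rec.sequence) == len(cur.sequence)
            and rec.protein_id < cur.protein_id
        ):
            best[rec.gene_id] = rec
    return [best[g] for g in order]


def pair_cds(
    protein: ProteinRecord,
    cds: CodingRecord,
    max_mismatch: int = 0,
) -> PairedRecord:
    """Pair a protein with its CDS, splitting in-frame codons.

    A terminal stop codon is stripped if present.  Each codon is translated
    with the standard code and compared to the protein; up to ``max_mismatch``
    disagreements are tolerated and recorded as ambiguous positions (excluded
    from pure-codon runs), more are a :class:`PairingError`.
    """
    if protein.protein_id != cds.protein_id:
        raise PairingError(
            f"id mismatch: {protein.protein_id} vs {cds.protein_id}"
        )
    nt = cds.nucleotide_sequence
    if len(nt) % 3 == 0 and len(nt) >= 3 and nt[-3:] in STOP_CODONS:
        nt = nt[:-3]
    if len(nt) != 3 * len(protein.sequence):
        raise PairingError(
            f"{protein.protein_id}: CDS length {len(nt)} does not match "
            f"3*{len(protein.sequence)} residues"
        )
    codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
    ambiguous: set[int] = set()
    mismatches: list[int] = []
    for i, (codon, aa) in enumerate(zip(codons, protein.sequence)):
        if aa == "X":
            ambiguous.add(i)
            continue
        if "N" in codon:
            ambiguous.add(i)
            continue
        translated = str(Seq(codon).translate())
        if translated != aa:
            mismatches.append(i)
    if len(mismatches) > max_mismatch:
        i = mismatches[0]
        raise PairingError(
            f"{protein.protein_id}: translation mismatch at residue {i} "
            f"({codons[i]} -> {str(Seq(codons[i]).translate())} != "
            f"{protein.sequence[i]}); {len(mismatches)} total"
        )
    ambiguous.update(mismatches)
    return PairedRecord(protein, cds, codons, frozenset(ambiguous))


def pair_proteome(
    proteins: Sequence[ProteinRecord],
    cds_by_id: Mapping[str, CodingRecord],
    max_mismatch: int = 0,
    skip_missing: bool = False,
) -> dict[str, PairedRecord]:
    """Pair every protein with its CDS; optionally skip proteins without one."""
    out: dict[str, PairedRecord] = {}
    for prot in proteins:
        if prot.protein_id not in cds_by_id:
            if skip_missing:
                continue
            raise PairingError(f"{prot.protein_id}: no CDS record")
        out[prot.protein_id] = pair_cds(
            prot, cds_by_id[prot.protein_id], max_mismatch=max_mismatch
        )
    return out
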