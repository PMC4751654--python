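"""Reciprocal-best-hit orthology from pairwise similarity hit tables.

The pipeline consumes standard 12-column blast-tabular output from an
external search tool; it never runs the search itself.  A pair of proteins
is orthologous when each is the other's best hit (smallest E-value, strictly
below the threshold, default 1e-20) in the two reciprocal searches; the
per-gene rows are anchored on a reference species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_EVALUE_MAX = 1e-20

#: column order of the 12-column blast-tabular dialect
TABULAR_COLUMNS = (
    "query_id",
    "subject_id",
    "identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class HitTableError(ValueError):
    """Malformed similarity hit table."""


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise HitTableError("empty id in hit record")
        if self.evalue < 0:
            raise HitTableError("negative evalue")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file (query, subject, ...,
    evalue, bitscore); only columns 1, 2, 11, 12 are used."""
    hits: list[HitRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise HitTableError(
                    f"{Path(path).name} line {lineno}: expected 12 columns, "
                    f"got {len(row)}"
                )
            try:
                evalue = float(row[10])
                bitscore = float(row[11])
            except ValueError as exc:
                raise HitTableError(
                    f"{Path(path).name} line {lineno}: {exc}"
                ) from None
            hits.append(HitRecord(row[0], row[1], evalue, bitscore))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits back out in the 12-column dialect (unused columns zeroed)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for h in hits:
            writer.writerow(
                [h.query_id, h.subject_id, 0, 0, 0, 0, 0, 0, 0, 0,
                 f"{h.evalue:g}", f"{h.bitscore:g}"]
            )


def best_hits(
    hits: Iterable[HitRecord], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, str]:
    """Best subject per query among hits with evalue strictly below the
    threshold.  Ties on evalue break to larger bitscore, then to the
    lexicographically smallest subject id.  Self-hits are ignored."""
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if not (h.evalue < evalue_max):
            continue
        key = (h.evalue, -h.bitscore, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> set[tuple[str, str]]:
    """(a, b) pairs that are mutual best hits below the threshold."""
    ab = best_hits(hits_ab, evalue_max)
    ba = best_hits(hits_ba, evalue_max)
    return {(a, b) for a, b in ab.items() if ba.get(b) == a}


@dataclass
class OrthologTable:
    """Reference-anchored ortholog table.

    ``rows`` maps each reference protein id to a per-species dict of
    orthologous protein ids (species absent when no RBH)."""

    reference: str
    species: list[str]
    rows: dict[str, dict[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = self.reference
        cols = [s for s in self.species if s != self.reference]
        return df.reindex(columns=cols).sort_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologTable":
        reference = df.index.name or "reference"
        rows = {
            str(idx): {c: v for c, v in row.items() if isinstance(v, str) and v}
            for idx, row in df.iterrows()
        }
        return cls(reference, [reference, *df.columns], rows)


def build_ortholog_table(
    reference: str,
    rbh_by_species: Mapping[str, set[tuple[str, str]]],
    require_complete: bool = True,
) -> OrthologTable:
    """Assemble the per-gene ortholog rows from reference-anchored RBH sets.

    ``rbh_by_species[s]`` holds (reference_protein, s_protein) pairs.  With
    ``require_complete`` (default) only rows filled in every species are
    kept, mirroring a single fully-orthologous data set; otherwise partial
    rows are retained.
    """
    others = [s for s in rbh_by_species if s != reference]
    rows: dict[str, dict[str, str]] = {}
    for sp in others:
        seen_other: set[str] = set()
        for ref_id, other_id in sorted(rbh_by_species[sp]):
            row = rows.setdefault(ref_id, {})
            assert sp not in row, f"duplicate RBH for {ref_id} in {sp}"
            assert other_id not in seen_other, f"{other_id} in two rows"
            seen_other.add(other_id)
            row[sp] = other_id
    if require_complete:
        rows = {r: m for r, m in rows.items() if len(m) == len(others)}
    return OrthologTable(reference, [reference, *others], rows)


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return OrthologTable.from_frame(df)
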