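"""GO-keyword functional grouping and GC-content profiling.

Proteins are assigned to one of four non-redundant functional groups by
case-insensitive keyword matching against their GO term names, in priority
order (a protein matching an earlier group is excluded from the later
ones):

1. ``TF_Development`` -- transcription, development, genesis, differentiation
2. ``Signal`` -- signal transduction, receptor, response, transport, membrane
3. ``Metabolism`` -- metabolic, transferase, catabolic, biosynthetic,
   protein translation, protein modification, protein folding, proteolysis
4. ``Others`` -- everything else, including unannotated proteins

Annotations are keyed on one species (typically the best-annotated one) and
propagated across each ortholog row, on the assumption that orthologous
genes share function.

GC profiling bins coding sequences by GC fraction; for the repeat-containing
protein (RCP) population the codons under every repeat interval are excised
before computing GC, so any GC shift attributable to the repeat-encoding
trinucleotide runs themselves is removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_detection import RepeatCatalog
from .sequence_io import PairedRecord

GROUPS = ("TF_Development", "Signal", "Metabolism", "Others")

#: keyword lists in priority order; first match wins
DEFAULT_KEYWORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "TF_Development",
        ("transcription", "development", "genesis", "differentiation"),
    ),
    (
        "Signal",
        ("signal transduction", "receptor", "response", "transport", "membrane"),
    ),
    (
        "Metabolism",
        (
            "metabolic",
            "transferase",
            "catabolic",
            "biosynthetic",
            "protein translation",
            "protein modification",
            "protein folding",
            "proteolysis",
        ),
    ),
)


def assign_functional_group(
    term_names: Iterable[str],
    keywords: Sequence[tuple[str, Sequence[str]]] = DEFAULT_KEYWORDS,
) -> str:
    """Group of a protein from its GO term names (priority matching)."""
    lowered = [t.lower() for t in term_names]
    for group, phrases in keywords:
        for phrase in phrases:
            if any(phrase in term for term in lowered):
                return group
    return "Others"


def read_go_table(path: str | Path) -> dict[str, list[str]]:
    """Read a GO TSV (protein_id <tab> term_name, one pair per line)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"GO table line {lineno}: expected 2 columns")
            out.setdefault(parts[0], []).append(parts[1])
    return out


def write_go_table(table: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in table:
            for term in table[pid]:
                fh.write(f"{pid}\t{term}\n")


def assign_groups(
    protein_ids: Iterable[str],
    go_table: Mapping[str, Sequence[str]],
    keywords: Sequence[tuple[str, Sequence[str]]] = DEFAULT_KEYWORDS,
) -> dict[str, str]:
    """Partition a protein set into the four groups (missing GO -> Others)."""
    return {
        pid: assign_functional_group(go_table.get(pid, ()), keywords)
        for pid in protein_ids
    }


def repeat_frequency_by_group(
    catalog: RepeatCatalog, assignment: Mapping[str, str]
) -> dict[str, float]:
    """Repeats-per-protein frequency for each functional group.

    The denominator is the number of (orthologous) proteins assigned to the
    group; groups with no proteins are absent from the result.
    """
    group_sizes = Counter(assignment.values())
    repeat_counts: Counter = Counter()
    for ann in catalog:
        group = assignment.get(ann.protein_id)
        if group is not None:
            repeat_counts[group] += 1
    return {
        g: repeat_counts[g] / group_sizes[g]
        for g in GROUPS
        if group_sizes[g] > 0
    }


def gc_content(nucleotides: str) -> float:
    """GC fraction of a nucleotide string; 'N' is excluded from both the
    numerator and the denominator."""
    counts = Counter(nucleotides.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("no unambiguous nucleotides")
    return (counts["G"] + counts["C"]) / total


@dataclass(frozen=True)
class GCProfile:
    population: str  # all_orthologs | rcp_repeats_removed
    bin_edges: tuple[float, ...]  # percent GC
    proportions: tuple[float, ...]
    n: int

    @property
    def peak_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.proportions))
        return (self.bin_edges[i], self.bin_edges[i + 1])


def _excised_cds(paired: PairedRecord, intervals: Sequence[tuple[int, int]]) -> str:
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return "".join(
        codon for i, codon in enumerate(paired.codons) if i not in covered
    )


def gc_profile(
    paired: Mapping[str, PairedRecord],
    catalog: RepeatCatalog,
    population: str = "all_orthologs",
    bin_edges: Sequence[float] | None = None,
) -> GCProfile:
    """GC-content distribution of the coding regions.

    ``all_orthologs``: GC of every paired CDS.  ``rcp_repeats_removed``:
    only repeat-containing proteins, with the codons under every repeat
    interval excised first.  Bins are half-open [lo, hi) percent, last bin
    closed.
    """
    if bin_edges is None:
        bin_edges = tuple(range(0, 101, 10))
    if population == "all_orthologs":
        values = [
            gc_content("".join(rec.codons)) * 100 for rec in paired.values()
        ]
    elif population == "rcp_repeats_removed":
        by_protein = catalog.by_protein
        values = []
        for pid, anns in by_protein.items():
            rec = paired.get(pid)
            if rec is None:
                continue
            remaining = _excised_cds(rec, [(a.start, a.end) for a in anns])
            if remaining and set(remaining) != {"N"}:
                values.append(gc_content(remaining) * 100)
    else:
        raise ValueError(f"unknown population {population!r}")
    if not values:
        raise ValueError("no sequences in population")
    counts, edges = np.histogram(values, bins=np.asarray(bin_edges))
    proportions = counts / counts.sum()
    return GCProfile(
        population, tuple(float(e) for e in edges),
        tuple(float(p) for p in proportions), len(values)
    )


def gc_profile_frame(profiles: Sequence[GCProfile]) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        for i, p in enumerate(prof.proportions):
            rows.append(
                {
                    "population": prof.population,
                    "bin_lo": prof.bin_edges[i],
                    "bin_hi": prof.bin_edges[i + 1],
                    "proportion": p,
                    "n": prof.n,
                }
            )
    return pd.DataFrame(rows)
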