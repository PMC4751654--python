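"""Codon-level and positional characterisation of detected repeats.

The central statistic is PLP, the proportion of the longest consecutive
pure-codon run to the complete repeat size.  A repeat of n residues encoded
throughout by one identical codon has PLP = 1 and is interpreted as a young
tract produced by recent replication slippage; point mutations and codon
turnover erode PLP towards 1/n.

Also provided: per-residue-type summary tables (counts, lengths, cores,
PLP, pure-codon breakdown), repeat length histograms, N/middle/C positional
classification, and the two-sample rank-sum comparison of length
distributions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repeat_detection import RepeatAnnotation, RepeatCatalog
from .sequence_io import PairedRecord


@dataclass(frozen=True)
class CodonProfile:
    """Codon decomposition of one repeat."""

    repeat: RepeatAnnotation
    codons: tuple[str, ...]
    longest_pure_run: int
    pure_codon: str | None

    @property
    def plp(self) -> float:
        return self.longest_pure_run / self.repeat.length


def compute_plp(repeat: RepeatAnnotation, paired: PairedRecord) -> CodonProfile:
    """PLP of a repeat given its protein's codon decomposition.

    The longest run of identical codons that encode the main residue is
    found under the full repeat interval; ambiguous codons (unknown residue,
    'N', tolerated translation mismatch) break runs.  The denominator is the
    complete repeat length in residues.
    """
    if repeat.start < 0 or repeat.end > len(paired.codons):
        raise ValueError(
            f"repeat [{repeat.start},{repeat.end}) outside codon range "
            f"of {paired.protein.protein_id}"
        )
    seq = paired.protein.sequence
    codons = paired.codons[repeat.start : repeat.end]
    longest = run = 0
    prev: str | None = None
    run_codon: str | None = None
    for offset, codon in enumerate(codons):
        pos = repeat.start + offset
        is_main = seq[pos] == repeat.main_residue and pos not in paired.ambiguous
        if is_main and codon == prev:
            run += 1
        elif is_main:
            run = 1
        else:
            run = 0
        prev = codon if is_main else None
        if run > longest:
            longest = run
            run_codon = codon
    pure = run_codon if longest == repeat.length else None
    return CodonProfile(repeat, codons, longest, pure)


def profile_catalog(
    catalog: RepeatCatalog, paired: Mapping[str, PairedRecord]
) -> list[CodonProfile]:
    return [
        compute_plp(ann, paired[ann.protein_id])
        for ann in catalog
        if ann.protein_id in paired
    ]


@dataclass(frozen=True)
class TypeSummary:
    main_residue: str
    count: int
    mean_length: float
    max_length: int
    mean_core: float
    max_core: int
    mean_plp: float | None
    n_plp1: int | None
    prop_plp1: float | None
    codon_breakdown: tuple[tuple[str, int], ...]


def summarize_by_type(
    catalog: RepeatCatalog,
    profiles: Sequence[CodonProfile] | None = None,
) -> list[TypeSummary]:
    """One summary row per main residue present, sorted by count descending.

    ``mean_core`` averages the longest uninterrupted tract of each repeat.
    Without codon profiles the PLP columns are None.
    """
    if len(catalog) == 0:
        raise ValueError("empty repeat catalog")
    by_res: dict[str, list[RepeatAnnotation]] = {}
    for ann in catalog:
        by_res.setdefault(ann.main_residue, []).append(ann)
    plp_by_res: dict[str, list[CodonProfile]] = {}
    if profiles is not None:
        for prof in profiles:
            plp_by_res.setdefault(prof.repeat.main_residue, []).append(prof)
    rows: list[TypeSummary] = []
    for res, anns in by_res.items():
        lengths = [a.length for a in anns]
        cores = [a.longest_core for a in anns]
        profs = plp_by_res.get(res)
        if profiles is None:
            mean_plp = n1 = p1 = None
            breakdown: tuple[tuple[str, int], ...] = ()
        else:
            profs = profs or []
            mean_plp = float(np.mean([p.plp for p in profs])) if profs else 0.0
            pure = Counter(p.pure_codon for p in profs if p.pure_codon)
            n1 = sum(pure.values())
            p1 = n1 / len(anns)
            breakdown = tuple(sorted(pure.items(), key=lambda kv: (-kv[1], kv[0])))
        rows.append(
            TypeSummary(
                res,
                len(anns),
                float(np.mean(lengths)),
                max(lengths),
                float(np.mean(cores)),
                max(cores),
                mean_plp,
                n1,
                p1,
                breakdown,
            )
        )
    rows.sort(key=lambda r: (-r.count, r.main_residue))
    return rows


def summary_frame(rows: Sequence[TypeSummary]) -> pd.DataFrame:
    """Summary rows as a DataFrame (means displayed to one decimal in TSV)."""
    return pd.DataFrame(
        {
            "main_residue": [r.main_residue for r in rows],
            "count": [r.count for r in rows],
            "mean_length": [r.mean_length for r in rows],
            "max_length": [r.max_length for r in rows],
            "mean_core": [r.mean_core for r in rows],
            "max_core": [r.max_core for r in rows],
            "mean_plp": [r.mean_plp for r in rows],
            "n_plp1": [r.n_plp1 for r in rows],
            "prop_plp1": [r.prop_plp1 for r in rows],
            "codon_breakdown": [
                ";".join(f"{c}:{k}" for c, k in r.codon_breakdown) for r in rows
            ],
        }
    )


def positional_class(repeat: RepeatAnnotation, protein_length: int) -> str:
    """Classify a repeat as N-terminal / middle / C-terminal by the tercile
    of its midpoint."""
    if protein_length < repeat.end:
        raise ValueError("protein shorter than repeat end")
    midpoint = (repeat.start + repeat.end) / 2
    if midpoint < protein_length / 3:
        return "N"
    if midpoint >= 2 * protein_length / 3:
        return "C"
    return "M"


def position_profile(
    catalog: RepeatCatalog, protein_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per main residue, the proportion of repeats in N / M / C terciles."""
    counts: dict[str, Counter] = {}
    for ann in catalog:
        cls = positional_class(ann, protein_lengths[ann.protein_id])
        counts.setdefault(ann.main_residue, Counter())[cls] += 1
    rows = []
    for res in sorted(counts):
        total = sum(counts[res].values())
        rows.append(
            {
                "main_residue": res,
                "prop_N": counts[res]["N"] / total,
                "prop_M": counts[res]["M"] / total,
                "prop_C": counts[res]["C"] / total,
                "n": total,
            }
        )
    return pd.DataFrame(rows)


def length_histogram(
    lengths: Iterable[int],
    bin_edges: Sequence[int] | None = None,
    threshold: int = 30,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of repeat lengths plus the proportion shorter than
    ``threshold``.  Returns (counts, edges, proportion)."""
    lengths = np.asarray(list(lengths))
    if lengths.size == 0:
        raise ValueError("empty length collection")
    if bin_edges is None:
        bin_edges = np.arange(5, max(int(lengths.max()) + 6, 35), 5)
    counts, edges = np.histogram(lengths, bins=bin_edges)
    proportion = float(np.mean(lengths < threshold))
    return counts, edges, proportion


def compare_length_distributions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample rank-sum test (normal approximation with tie
    correction).  Returns (z, p); z is antisymmetric under swapping groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (res.statistic - mu) / math.sqrt(sigma2)
    return float(z), float(res.pvalue)
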