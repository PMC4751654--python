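"""Detection of perfect and imperfect tandem amino-acid repeats.

A tandem amino-acid repeat (homopolymeric tract) is an interval of a protein
dominated by one "main" residue.  A repeat must

* contain an uninterrupted core of at least ``min_core_length`` main
  residues (default 5),
* start and end on the main residue,
* contain no internal run of non-main residues longer than
  ``max_nonmain_run`` (default 5), and
* have a main-residue fraction (purity) of at least ``min_main_fraction``
  (default 0.70, inclusive).

A tract with purity 1 is a perfect repeat, anything below is imperfect.

``detect_repeats`` reports, per main residue, the intervals satisfying all
of the above that are maximal under inclusion; overlapping or touching
same-residue intervals are then reduced to one annotation per tract
(longest kept, ties to the left-most).  ``extend_core`` additionally exposes
the classic greedy block-absorption extension of a single core, which
coincides with the maximal interval in all but pathological purity
fail-then-recover flank patterns.

'X' (unknown residue) can never be a main residue and counts as non-main.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .sequence_io import ProteinRecord

#: slack for the inclusive purity comparison (purity >= threshold)
_PURITY_EPS = 1e-9


@dataclass(frozen=True)
class DetectorParams:
    min_core_length: int = 5
    max_nonmain_run: int = 5
    min_main_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.min_core_length < 2:
            raise ValueError("min_core_length must be >= 2")
        if not (0 < self.min_main_fraction <= 1):
            raise ValueError("min_main_fraction must be in (0, 1]")
        if self.max_nonmain_run < 0:
            raise ValueError("max_nonmain_run must be >= 0")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One detected homopolymeric tract (0-based, half-open interval)."""

    protein_id: str
    main_residue: str
    start: int
    end: int
    main_count: int
    longest_core: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def purity(self) -> float:
        return self.main_count / self.length

    @property
    def is_perfect(self) -> bool:
        return self.main_count == self.length

    def sequence_slice(self, sequence: str) -> str:
        return sequence[self.start : self.end]


def _runs(sequence: str) -> list[tuple[str, int, int]]:
    """Maximal single-residue runs as (residue, start, end)."""
    out: list[tuple[str, int, int]] = []
    i, n = 0, len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        out.append((sequence[i], i, j))
        i = j
    return out


def find_cores(
    sequence: str, params: DetectorParams = DetectorParams()
) -> list[tuple[str, tuple[int, int]]]:
    """All maximal runs of one residue with length >= min_core_length.

    Runs of 'X' are never reported (unknown residues cannot seed repeats).
    """
    return [
        (res, (s, e))
        for res, s, e in _runs(sequence)
        if e - s >= params.min_core_length and res != "X" and res != "*"
    ]


def _purity_ok(main: int, length: int, params: DetectorParams) -> bool:
    return main >= params.min_main_fraction * length - _PURITY_EPS


def _annotate(
    protein_id: str,
    sequence: str,
    residue: str,
    start: int,
    end: int,
) -> RepeatAnnotation:
    window = sequence[start:end]
    main = window.count(residue)
    core = best = 0
    for ch in window:
        core = core + 1 if ch == residue else 0
        best = max(best, core)
    return RepeatAnnotation(protein_id, residue, start, end, main, best)


def extend_core(
    sequence: str,
    core: tuple[str, tuple[int, int]],
    params: DetectorParams = DetectorParams(),
    protein_id: str = "",
) -> RepeatAnnotation:
    """Greedy maximal extension of a single core.

    Starting from the core, repeatedly try to absorb -- on alternating sides,
    N-terminal first -- the adjacent block of 1..max_nonmain_run non-main
    residues together with the following maximal main-residue run, accepting
    the absorption only when the extended window keeps purity >=
    min_main_fraction.  Endpoints always land on the main residue.
    """
    residue, (start, end) = core
    n = len(sequence)

    def absorb_left(s: int) -> int | None:
        i = s - 1
        gap = 0
        while i >= 0 and sequence[i] != residue:
            gap += 1
            i -= 1
        if i < 0 or gap == 0 or gap > params.max_nonmain_run:
            return None
        while i >= 0 and sequence[i] == residue:
            i -= 1
        return i + 1

    def absorb_right(e: int) -> int | None:
        i = e
        gap = 0
        while i < n and sequence[i] != residue:
            gap += 1
            i += 1
        if i >= n or gap == 0 or gap > params.max_nonmain_run:
            return None
        while i < n and sequence[i] == residue:
            i += 1
        return i

    sides = ["N", "C"]
    blocked = {"N": False, "C": False}
    turn = 0
    while not all(blocked.values()):
        side = sides[turn % 2]
        turn += 1
        if blocked[side]:
            continue
        if side == "N":
            cand = absorb_left(start)
            if cand is None:
                blocked["N"] = True
                continue
            main = sequence[cand:end].count(residue)
            if _purity_ok(main, end - cand, params):
                start = cand
            else:
                blocked["N"] = True
        else:
            cand = absorb_right(end)
            if cand is None:
                blocked["C"] = True
                continue
            main = sequence[start:cand].count(residue)
            if _purity_ok(main, cand - start, params):
                end = cand
            else:
                blocked["C"] = True
    return _annotate(protein_id, sequence, residue, start, end)


def _maximal_intervals(
    sequence: str, residue: str, params: DetectorParams
) -> list[tuple[int, int]]:
    """Inclusion-maximal valid repeat intervals for one main residue.

    Candidate endpoints are main-residue positions.  Positions are first
    split into blocks separated by non-main gaps longer than
    max_nonmain_run (no valid interval can span such a barrier); within a
    block every endpoint pair is screened for purity and core content, then
    dominated intervals are removed by a sweep.
    """
    pos = [i for i, ch in enumerate(sequence) if ch == residue]
    if not pos:
        return []
    blocks: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - blocks[-1][-1] - 1 > params.max_nonmain_run:
            blocks.append([p])
        else:
            blocks[-1].append(p)
    out: list[tuple[int, int]] = []
    for block in blocks:
        m = len(block)
        if m < params.min_core_length:
            continue
        valid: list[tuple[int, int]] = []
        for a in range(m):
            run = best_run = 1
            for b in range(a, m):
                if b > a:
                    run = run + 1 if block[b] == block[b - 1] + 1 else 1
                    best_run = max(best_run, run)
                if best_run < params.min_core_length:
                    continue
                length = block[b] - block[a] + 1
                if _purity_ok(b - a + 1, length, params):
                    valid.append((block[a], block[b] + 1))
        # inclusion-maximal sweep: sort by (start asc, end desc); an interval
        # is dominated iff an earlier-starting one reaches at least as far
        valid.sort(key=lambda iv: (iv[0], -iv[1]))
        max_end = -1
        for iv in valid:
            if iv[1] > max_end:
                out.append(iv)
                max_end = iv[1]
    return out


def _reduce_overlaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """One annotation per tract: among overlapping or touching same-residue
    intervals keep the longer (tie: left-most), greedily in
    (length desc, start asc) order."""
    kept: list[tuple[int, int]] = []
    for iv in sorted(intervals, key=lambda iv: (-(iv[1] - iv[0]), iv[0])):
        if all(iv[1] < k[0] or iv[0] > k[1] for k in kept):
            kept.append(iv)
    return sorted(kept)


def detect_repeats(
    sequence: str,
    params: DetectorParams = DetectorParams(),
    protein_id: str = "",
) -> list[RepeatAnnotation]:
    """Detect all tandem amino-acid repeats in one protein sequence.

    Per main residue the inclusion-maximal valid intervals are reported,
    reduced to one annotation per tract; annotations of different main
    residues may overlap.  Result is sorted by start, then main residue.
    """
    annotations: list[RepeatAnnotation] = []
    seen: set[str] = set()
    for res, (s, e) in find_cores(sequence, params):
        if res in seen:
            continue
        seen.add(res)
        intervals = _maximal_intervals(sequence, res, params)
        for start, end in _reduce_overlaps(intervals):
            annotations.append(_annotate(protein_id, sequence, res, start, end))
    annotations.sort(key=lambda a: (a.start, a.main_residue))
    return annotations


@dataclass
class RepeatCatalog:
    """All repeat annotations of a proteome plus a per-protein index."""

    params: DetectorParams
    annotations: list[RepeatAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    @property
    def by_protein(self) -> dict[str, list[RepeatAnnotation]]:
        index: dict[str, list[RepeatAnnotation]] = {}
        for ann in self.annotations:
            index.setdefault(ann.protein_id, []).append(ann)
        return index

    def rcp_ids(self) -> set[str]:
        """Identifiers of repeat-containing proteins (RCPs)."""
        return {ann.protein_id for ann in self.annotations}

    def of_residue(self, residue: str) -> list[RepeatAnnotation]:
        return [a for a in self.annotations if a.main_residue == residue]


def detect_proteome(
    records: Iterable[ProteinRecord],
    params: DetectorParams = DetectorParams(),
) -> RepeatCatalog:
    """Scan a one-per-gene protein collection; order-stable catalog."""
    catalog = RepeatCatalog(params=params)
    for rec in sorted(records, key=lambda r: r.protein_id):
        catalog.annotations.extend(
            detect_repeats(rec.sequence, params, protein_id=rec.protein_id)
        )
    return catalog
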