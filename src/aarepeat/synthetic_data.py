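"""Seeded generators for every input the pipeline consumes, with truth.

Real inputs to this kind of analysis are proteome-scale FASTA dumps,
blast-tabular hit files, codon alignments and GO tables.  The generators
here emulate all of them with planted, internally consistent ground truth:
planted repeat coordinates and codon plans, planted reciprocal-best-hit
pairs guarded by decoy hits, planted conservation classes (including
frame-shift decoys where the same nucleotide tract is read as two different
amino acids), planted functional-group labels and planted clade-common
flags.  Every generator is driven by a ``numpy`` Generator or an integer
seed; the same seed reproduces byte-identical output.

Planted tracts are recoverable exactly by construction: the flanking
``max_nonmain_run + 1`` residues on each side never contain the tract's
main residue, so no valid extension can cross them, and background
sequence is kept free of cores (no run reaches ``min_core_length``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .conservation import CodonAlignment
from .orthology import HitRecord
from .repeat_detection import DetectorParams
from .sequence_io import CodingRecord, PairedRecord, ProteinRecord, pair_cds

#: residue -> synonymous codons under the standard code
RESIDUE_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    RESIDUE_CODONS.setdefault(_aa, ())
    RESIDUE_CODONS[_aa] = tuple(sorted((*RESIDUE_CODONS[_aa], _codon)))

AMINO_ACIDS = tuple(sorted(RESIDUE_CODONS))


def _rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _choose_codon(
    rng: np.random.Generator,
    residue: str,
    weights: Mapping[str, float] | None = None,
) -> str:
    codons = RESIDUE_CODONS[residue]
    if weights:
        w = np.array([weights.get(c, 0.0) for c in codons], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"codon weights select nothing for {residue}")
        return codons[rng.choice(len(codons), p=w / w.sum())]
    return codons[rng.integers(len(codons))]


@dataclass(frozen=True)
class RepeatPlan:
    """Blueprint of one planted tract.

    The tract is ``core_len`` main residues followed, per ``insertions``
    entry, by a block of ``gap_len`` non-main residues and another run of
    ``run_len`` main residues.  ``pure`` plants a single codon throughout
    the main residues (PLP = 1 for a perfect tract); ``codon_weights``
    skews the synonymous-codon draw otherwise.
    """

    residue: str
    core_len: int = 5
    insertions: tuple[tuple[int, int], ...] = ()
    codon_weights: Mapping[str, float] | None = None
    pure: bool = False

    def __post_init__(self) -> None:
        if self.residue not in RESIDUE_CODONS:
            raise ValueError(f"not a codeable residue: {self.residue!r}")
        if self.core_len < 1:
            raise ValueError("core_len must be >= 1")
        for gap, run in self.insertions:
            if gap < 1 or run < 1:
                raise ValueError("insertion blocks need gap >= 1 and run >= 1")

    @property
    def length(self) -> int:
        return self.core_len + sum(g + r for g, r in self.insertions)

    @property
    def main_count(self) -> int:
        return self.core_len + sum(r for _, r in self.insertions)

    @property
    def purity(self) -> float:
        return self.main_count / self.length

    @property
    def longest_core(self) -> int:
        return max(self.core_len, *(r for _, r in self.insertions), 0)

    def validate(self, params: DetectorParams) -> None:
        if self.longest_core < params.min_core_length:
            raise ValueError("no run reaches min_core_length")
        if any(g > params.max_nonmain_run for g, _ in self.insertions):
            raise ValueError("insertion gap exceeds max_nonmain_run")
        if self.purity < params.min_main_fraction:
            raise ValueError("planned purity below min_main_fraction")


@dataclass(frozen=True)
class PlantedRepeat:
    """Ground truth for one planted tract."""

    protein_id: str
    residue: str
    start: int
    end: int
    main_count: int
    longest_core: int
    longest_pure_run: int
    pure_codon: str | None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def purity(self) -> float:
        return self.main_count / self.length

    @property
    def plp(self) -> float:
        return self.longest_pure_run / self.length


def _tract_letters_and_codons(
    plan: RepeatPlan, rng: np.random.Generator, forbidden: set[str]
) -> tuple[list[str], list[str]]:
    """Residues and codons of one tract; insertion letters avoid the main
    residue, anything in ``forbidden`` and immediate same-letter runs."""
    letters: list[str] = []
    codons: list[str] = []
    pure_codon = (
        _choose_codon(rng, plan.residue, plan.codon_weights) if plan.pure else None
    )

    def add_main(n: int) -> None:
        for _ in range(n):
            letters.append(plan.residue)
            codons.append(
                pure_codon
                if pure_codon
                else _choose_codon(rng, plan.residue, plan.codon_weights)
            )

    def add_gap(n: int) -> None:
        for _ in range(n):
            pool = [
                aa
                for aa in AMINO_ACIDS
                if aa != plan.residue
                and aa not in forbidden
                and (not letters or aa != letters[-1])
            ]
            aa = pool[rng.integers(len(pool))]
            letters.append(aa)
            codons.append(_choose_codon(rng, aa))

    add_main(plan.core_len)
    for gap, run in plan.insertions:
        add_gap(gap)
        add_main(run)
    return letters, codons


def _planted_truth(
    protein_id: str,
    plan: RepeatPlan,
    start: int,
    letters: Sequence[str],
    codons: Sequence[str],
) -> PlantedRepeat:
    longest = run = 0
    prev: str | None = None
    for aa, codon in zip(letters, codons):
        if aa == plan.residue and codon == prev:
            run += 1
        elif aa == plan.residue:
            run = 1
        else:
            run = 0
        prev = codon if aa == plan.residue else None
        longest = max(longest, run)
    pure = codons[0] if longest == len(letters) else None
    return PlantedRepeat(
        protein_id,
        plan.residue,
        start,
        start + len(letters),
        sum(aa == plan.residue for aa in letters),
        plan.longest_core,
        longest,
        pure,
    )


def _background(
    rng: np.random.Generator,
    n: int,
    min_core: int,
    forbid: Sequence[set[str]] | None = None,
    alphabet: Sequence[str] = AMINO_ACIDS,
) -> list[str]:
    """Repeat-free background: no run of ``min_core``; per-position
    forbidden sets keep planted-tract flanks clean."""
    letters: list[str] = []
    for i in range(n):
        banned = set(forbid[i]) if forbid else set()
        if len(letters) >= min_core - 1 and len(set(letters[-(min_core - 1):])) == 1:
            banned.add(letters[-1])
        pool = [aa for aa in alphabet if aa not in banned]
        letters.append(pool[rng.integers(len(pool))])
    return letters


def generate_paired_record(
    protein_id: str,
    length: int,
    plans: Sequence[RepeatPlan],
    seed: int | np.random.Generator | None = None,
    species: str = "synthetic",
    gene_id: str | None = None,
    params: DetectorParams = DetectorParams(),
    mutation_rate: float = 0.0,
    add_stop: bool = True,
) -> tuple[PairedRecord, list[PlantedRepeat]]:
    """One protein/CDS pair with planted tracts of known truth.

    Tracts are spaced by at least ``max_nonmain_run + 1`` background
    residues free of each tract's main residue.  ``mutation_rate`` applies
    per-residue point substitutions inside planted tracts (truth intervals
    are left as planned, emulating detector stress, not re-derived).
    """
    rng = _rng(seed)
    for plan in plans:
        plan.validate(params)
    margin = params.max_nonmain_run + 1
    total_tract = sum(p.length for p in plans)
    spare = length - total_tract
    n_gaps = len(plans) + 1
    if spare < margin * n_gaps:
        raise ValueError(
            f"{protein_id}: plans need at least "
            f"{total_tract + margin * n_gaps} residues, got {length}"
        )
    gap = spare // n_gaps
    extra = spare - gap * n_gaps
    starts: list[int] = []
    pos = gap + extra
    for plan in plans:
        starts.append(pos)
        pos += plan.length + gap

    forbid: list[set[str]] = [set() for _ in range(length)]
    for plan, start in zip(plans, starts):
        for i in range(max(0, start - margin), start):
            forbid[i].add(plan.residue)
        for i in range(start + plan.length, min(length, start + plan.length + margin)):
            forbid[i].add(plan.residue)

    letters: list[str] = []
    codons: list[str] = []
    truths: list[PlantedRepeat] = []
    cursor = 0
    for plan, start in zip(plans, starts):
        bg = _background(
            rng, start - cursor, params.min_core_length, forbid[cursor:start]
        )
        letters.extend(bg)
        codons.extend(_choose_codon(rng, aa) for aa in bg)
        t_letters, t_codons = _tract_letters_and_codons(plan, rng, set())
        truths.append(_planted_truth(protein_id, plan, start, t_letters, t_codons))
        letters.extend(t_letters)
        codons.extend(t_codons)
        cursor = start + plan.length
    bg = _background(rng, length - cursor, params.min_core_length, forbid[cursor:])
    letters.extend(bg)
    codons.extend(_choose_codon(rng, aa) for aa in bg)

    if mutation_rate > 0:
        for plan, start in zip(plans, starts):
            for i in range(start, start + plan.length):
                if rng.random() < mutation_rate:
                    other = [aa for aa in AMINO_ACIDS if aa != letters[i]]
                    letters[i] = other[rng.integers(len(other))]
                    codons[i] = _choose_codon(rng, letters[i])

    protein = ProteinRecord(
        protein_id, gene_id or protein_id, species, "".join(letters)
    )
    nt = "".join(codons) + ("TAA" if add_stop else "")
    paired = pair_cds(protein, CodingRecord(protein_id, nt))
    return paired, truths


@dataclass
class SyntheticProteome:
    records: list[PairedRecord]
    truth: list[PlantedRepeat]
    seed: int | None = None

    @property
    def proteins(self) -> list[ProteinRecord]:
        return [rec.protein for rec in self.records]

    @property
    def paired(self) -> dict[str, PairedRecord]:
        return {rec.protein.protein_id: rec for rec in self.records}


def generate_proteome(
    n_proteins: int = 30,
    repeat_fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
    params: DetectorParams = DetectorParams(),
    species: str = "synthetic",
) -> SyntheticProteome:
    """A small proteome: ~half the proteins carry 1-2 planted tracts of
    random type, length, imperfection and codon purity."""
    rng = _rng(seed)
    records: list[PairedRecord] = []
    truth: list[PlantedRepeat] = []
    plantable = [aa for aa in AMINO_ACIDS if len(RESIDUE_CODONS[aa]) > 1]
    for i in range(n_proteins):
        pid = f"{species}_P{i:04d}"
        length = int(rng.integers(90, 220))
        plans: list[RepeatPlan] = []
        if rng.random() < repeat_fraction:
            for _ in range(int(rng.integers(1, 3))):
                residue = plantable[rng.integers(len(plantable))]
                core = int(rng.integers(params.min_core_length, 11))
                insertions: tuple[tuple[int, int], ...] = ()
                if rng.random() < 0.5:
                    insertions = ((int(rng.integers(1, 4)), int(rng.integers(2, 6))),)
                plan = RepeatPlan(
                    residue,
                    core,
                    insertions,
                    pure=bool(rng.random() < 0.4),
                )
                if plan.purity >= params.min_main_fraction:
                    plans.append(plan)
        try:
            rec, t = generate_paired_record(
                pid, length, plans, rng, species=species, params=params
            )
        except ValueError:
            rec, t = generate_paired_record(
                pid, length, [], rng, species=species, params=params
            )
        records.append(rec)
        truth.extend(t)
    return SyntheticProteome(records, truth)



# ---------------------------------------------------------------------------
# ortholog families


@dataclass(frozen=True)
class ConservationPlan:
    """One planted tract in an ortholog family.

    The tract (a perfect repeat, single codon) occupies the same alignment
    columns in every species listed in ``present_in``.  ``decoy_residue``
    plants, in every *other* species, a same-column tract of a different
    amino acid whose codon is the main codon read in a shifted frame
    (a frame-shift decoy: same nucleotide repeat, different translation).
    """

    residue: str
    length: int = 6
    present_in: tuple[str, ...] = ()
    decoy_residue: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in RESIDUE_CODONS:
            raise ValueError(f"not a codeable residue: {self.residue!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.decoy_residue == self.residue:
            raise ValueError("decoy residue must differ from the main residue")


#: codon pairs spelling the same repeated nucleotide pattern in two frames,
#: e.g. ...CCGCCGCCG... reads as polyP (CCG) or, shifted, polyA (GCC)
FRAME_SHIFT_CODONS: dict[tuple[str, str], tuple[str, str]] = {
    ("P", "A"): ("CCG", "GCC"),
    ("A", "P"): ("GCC", "CCG"),
    ("G", "A"): ("GGC", "GCG"),
    ("A", "G"): ("GCG", "GGC"),
    ("Q", "S"): ("CAG", "AGC"),
    ("S", "Q"): ("AGC", "CAG"),
}


@dataclass
class FamilyTruth:
    gene: str
    reference: str
    species: list[str]
    plans: list[ConservationPlan]
    planted: dict[str, list[PlantedRepeat]]
    column_ranges: list[tuple[int, int]]  # residue-column interval per plan
    rbh_pairs: set[tuple[str, str]] = field(default_factory=set)

    def expected_class(
        self, plan: ConservationPlan, exclusion: Iterable[str] = ()
    ) -> str:
        """Conservation class the classifier must assign to the reference
        copy of this plan's tract (reference must be in present_in)."""
        others = [sp for sp in self.species if sp != self.reference]
        present = set(plan.present_in)
        excluded = set(exclusion)
        effective = [sp for sp in others if sp in present and sp not in excluded]
        if not effective:
            return "species_only"
        if all(sp in present for sp in others):
            return "conserved_in_all"
        return "conserved_in_k"


@dataclass
class SyntheticFamily:
    gene: str
    records: dict[str, PairedRecord]
    alignment: CodonAlignment
    hit_tables: dict[tuple[str, str], list[HitRecord]]
    truth: FamilyTruth


def _build_family(
    species: Sequence[str],
    plans: Sequence[ConservationPlan],
    gap_plan: Sequence[tuple[str, int, int]],
    rng: np.random.Generator,
    gene: str,
    scaffold_len: int,
    params: DetectorParams,
) -> tuple[dict[str, PairedRecord], CodonAlignment, FamilyTruth]:
    """Column-wise construction of one family alignment.

    Background and fill letters avoid every planted (and decoy) residue, so
    tracts are exactly recoverable; per-species run tracking keeps every
    background stretch free of cores even across tract and gap boundaries.
    """
    from Bio.Seq import Seq

    margin = params.max_nonmain_run + 1
    for plan in plans:
        if plan.length < params.min_core_length:
            raise ValueError(
                f"planted tract of length {plan.length} is undetectable "
                f"(min_core_length={params.min_core_length})"
            )
    reserved = {p.residue for p in plans} | {
        p.decoy_residue for p in plans if p.decoy_residue
    }
    alphabet = [aa for aa in AMINO_ACIDS if aa not in reserved]
    if len(alphabet) < 4:
        raise ValueError("plans reserve too many residues")

    total_tract = sum(p.length for p in plans)
    spare = scaffold_len - total_tract
    n_gaps = len(plans) + 1
    if spare < margin * n_gaps:
        raise ValueError("scaffold too short for the planted tracts")
    gap = spare // n_gaps
    starts: list[int] = []
    pos = gap + (spare - gap * n_gaps)
    for plan in plans:
        starts.append(pos)
        pos += plan.length + gap
    tract_of_col: dict[int, int] = {}
    for i, (plan, s) in enumerate(zip(plans, starts)):
        for c in range(s, s + plan.length):
            tract_of_col[c] = i

    # column descriptors after inserting species-specific codons
    descriptors: list[tuple[str, object]] = [
        ("tract", tract_of_col[c]) if c in tract_of_col else ("bg", None)
        for c in range(scaffold_len)
    ]
    for sp, col, n in sorted(gap_plan, key=lambda g: -g[1]):
        if sp not in species:
            raise ValueError(f"gap plan references unknown species {sp!r}")
        for s, plan in zip(starts, plans):
            if s - margin < col < s + plan.length + margin:
                raise ValueError(
                    f"insertion at column {col} too close to a planted tract"
                )
        descriptors[col:col] = [("ins", sp)] * n

    main_codons: list[str] = []
    decoy_codons: list[str | None] = []
    for plan in plans:
        if plan.decoy_residue is not None:
            key = (plan.residue, plan.decoy_residue)
            if key not in FRAME_SHIFT_CODONS:
                raise ValueError(f"no frame-shift codon pair for {key}")
            mc, dc = FRAME_SHIFT_CODONS[key]
        else:
            mc, dc = _choose_codon(rng, plan.residue), None
        main_codons.append(mc)
        decoy_codons.append(dc)

    last_letter: dict[str, str] = {sp: "" for sp in species}
    run_len: dict[str, int] = {sp: 0 for sp in species}

    def note(sp: str, aa: str) -> None:
        if aa == last_letter[sp]:
            run_len[sp] += 1
        else:
            last_letter[sp] = aa
            run_len[sp] = 1

    def safe_letter(members: Sequence[str]) -> str:
        vetoed = {
            last_letter[sp]
            for sp in members
            if run_len[sp] >= params.min_core_length - 1
        }
        pool = [aa for aa in alphabet if aa not in vetoed]
        return pool[rng.integers(len(pool))]

    columns: list[dict[str, str]] = []
    residue_idx: dict[str, int] = {sp: 0 for sp in species}
    tract_res_start: dict[tuple[int, str], int] = {}
    tract_col_range: dict[int, tuple[int, int]] = {}
    for ci, (kind, info) in enumerate(descriptors):
        col: dict[str, str] = {}
        if kind == "bg":
            aa = safe_letter(species)
            codon = _choose_codon(rng, aa)
            for sp in species:
                col[sp] = codon
                note(sp, aa)
        elif kind == "ins":
            sp = info  # type: ignore[assignment]
            aa = safe_letter([sp])
            col[sp] = _choose_codon(rng, aa)
            note(sp, aa)
        else:
            ti = info  # type: ignore[assignment]
            plan = plans[ti]
            lo, hi = tract_col_range.get(ti, (ci, ci))
            tract_col_range[ti] = (min(lo, ci), ci + 1)
            absent = [
                sp
                for sp in species
                if sp not in plan.present_in and decoy_codons[ti] is None
            ]
            fill_aa = safe_letter(absent) if absent else ""
            fill_codon = _choose_codon(rng, fill_aa) if absent else ""
            for sp in species:
                if sp in plan.present_in:
                    if (ti, sp) not in tract_res_start:
                        tract_res_start[(ti, sp)] = residue_idx[sp]
                    col[sp] = main_codons[ti]
                    note(sp, plan.residue)
                elif decoy_codons[ti] is not None:
                    if (ti, sp) not in tract_res_start:
                        tract_res_start[(ti, sp)] = residue_idx[sp]
                    col[sp] = decoy_codons[ti]
                    note(sp, plan.decoy_residue)
                else:
                    col[sp] = fill_codon
                    note(sp, fill_aa)
        for sp in species:
            if sp in col:
                residue_idx[sp] += 1
        columns.append(col)

    ids = {sp: f"{sp}_{gene}" for sp in species}
    gapped = {
        sp: "".join(col.get(sp, "---") for col in columns) for sp in species
    }
    alignment = CodonAlignment(gapped, dict(ids))

    records: dict[str, PairedRecord] = {}
    for sp in species:
        nt = gapped[sp].replace("-", "")
        protein_seq = "".join(
            str(Seq(nt[i : i + 3]).translate()) for i in range(0, len(nt), 3)
        )
        protein = ProteinRecord(ids[sp], gene, sp, protein_seq)
        records[sp] = pair_cds(protein, CodingRecord(ids[sp], nt + "TAA"))

    planted: dict[str, list[PlantedRepeat]] = {sp: [] for sp in species}
    for ti, plan in enumerate(plans):
        for sp in species:
            if sp in plan.present_in:
                residue, codon = plan.residue, main_codons[ti]
            elif decoy_codons[ti] is not None:
                residue, codon = plan.decoy_residue, decoy_codons[ti]
            else:
                continue
            start = tract_res_start[(ti, sp)]
            planted[sp].append(
                PlantedRepeat(
                    ids[sp], residue, start, start + plan.length,
                    plan.length, plan.length, plan.length, codon,
                )
            )
    truth = FamilyTruth(
        gene,
        species[0],
        list(species),
        list(plans),
        planted,
        [tract_col_range[i] for i in range(len(plans))],
    )
    return records, alignment, truth


def generate_ortholog_family(
    species: Sequence[str],
    plans: Sequence[ConservationPlan],
    gap_plan: Sequence[tuple[str, int, int]] = (),
    seed: int | np.random.Generator | None = None,
    scaffold_len: int = 48,
    gene: str = "fam1",
    params: DetectorParams = DetectorParams(),
    decoy_hits: bool = True,
) -> SyntheticFamily:
    """One ortholog family across ``species`` (reference first) with hit
    tables consistent with the planted RBH truth.

    ``gap_plan`` entries ``(species, residue_column, n_codons)`` insert
    species-specific codons, i.e. gap columns in every other species.
    Planted reference-vs-other pairs get E-values far below the 1e-20
    threshold; ``decoy_hits`` adds above-threshold and non-reciprocal
    decoys that must never survive RBH selection.
    """
    rng = _rng(seed)
    for plan in plans:
        missing = set(plan.present_in) - set(species)
        if missing:
            raise ValueError(f"plan references unknown species {missing}")
    records, alignment, truth = _build_family(
        species, plans, gap_plan, rng, gene, scaffold_len, params
    )
    ids = alignment.protein_ids
    ref = species[0]
    hit_tables: dict[tuple[str, str], list[HitRecord]] = {}
    for sp in species[1:]:
        fwd = [HitRecord(ids[ref], ids[sp], 1e-40, 500.0)]
        rev = [HitRecord(ids[sp], ids[ref], 1e-40, 500.0)]
        if decoy_hits:
            # above-threshold best-looking decoy, and a strong but
            # non-reciprocal one
            fwd.append(HitRecord(ids[ref], f"{sp}_decoy", 1e-19, 80.0))
            rev.append(HitRecord(f"{sp}_decoy", ids[ref], 1e-30, 120.0))
        hit_tables[(ref, sp)] = fwd
        hit_tables[(sp, ref)] = rev
        truth.rbh_pairs.add((ids[ref], ids[sp]))
    return SyntheticFamily(truth.gene, records, alignment, hit_tables, truth)


# ---------------------------------------------------------------------------
# GO tables

_TERM_POOLS: dict[str, tuple[str, ...]] = {
    "TF_Development": (
        "regulation of transcription, dna-templated",
        "embryonic limb development",
        "organ morphogenesis",
        "cell differentiation",
        "neurogenesis",
    ),
    "Signal": (
        "signal transduction",
        "g protein-coupled receptor activity",
        "cellular response to stimulus",
        "ion transport",
        "integral component of membrane",
    ),
    "Metabolism": (
        "lipid metabolic process",
        "acyltransferase activity",
        "protein folding",
        "proteolysis",
        "amino acid biosynthetic process",
        "protein modification process",
    ),
    "Others": (
        "cell adhesion",
        "dna repair",
        "chromosome segregation",
        "rna splicing",
        "cytoskeleton organization",
        "ion homeostasis",
    ),
}

_GROUP_RANK = {"TF_Development": 0, "Signal": 1, "Metabolism": 2, "Others": 3}


def generate_go_table(
    group_plan: Mapping[str, str],
    seed: int | np.random.Generator | None = None,
    adversarial: bool = True,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """A GO term-name table realising planted group labels.

    Each protein receives 1-3 terms containing its group's keywords;
    ``adversarial`` adds extra terms from *lower-priority* groups only, so
    the planted label remains the unique correct assignment under the
    hierarchical-exclusion rule.  ``Others`` proteins get keyword-free
    terms (or none at all).
    """
    rng = _rng(seed)
    table: dict[str, list[str]] = {}
    for pid, group in group_plan.items():
        if group not in _TERM_POOLS:
            raise ValueError(f"unknown group {group!r} for {pid}")
        terms: list[str] = []
        pool = _TERM_POOLS[group]
        if group == "Others" and rng.random() < 0.3:
            table[pid] = []  # unannotated protein
            continue
        n = int(rng.integers(1, 3))
        terms.extend(pool[i] for i in rng.choice(len(pool), n, replace=False))
        if adversarial and group != "Others":
            lower = [
                g for g, r in _GROUP_RANK.items() if r > _GROUP_RANK[group]
            ]
            extra_group = lower[rng.integers(len(lower))]
            extra_pool = _TERM_POOLS[extra_group]
            terms.append(extra_pool[rng.integers(len(extra_pool))])
        rng.shuffle(terms)
        table[pid] = terms
    return table, dict(group_plan)


# ---------------------------------------------------------------------------
# clade gene-family datasets


@dataclass(frozen=True)
class CladeRepeatPlan:
    """One planted tract in one gene of a clade dataset; ``present_in``
    lists the species carrying it (subset of the gene's available
    species)."""

    gene: str
    residue: str
    length: int
    present_in: tuple[str, ...]


@dataclass
class SyntheticCladeDataset:
    records: dict[str, dict[str, PairedRecord]]  # species -> gene -> record
    alignments: dict[str, CodonAlignment]  # per gene
    clades: dict[str, tuple[str, ...]]
    availability: dict[str, tuple[str, ...]]  # gene -> available species
    plans: list[CladeRepeatPlan]

    def expected_clade_common(
        self, plan: CladeRepeatPlan, clade: str
    ) -> bool | None:
        """Truth flag: present in every available clade species; None when
        fewer than two clade species are available for the gene."""
        members = [
            sp
            for sp in self.clades[clade]
            if sp in self.availability[plan.gene]
        ]
        if len(members) < 2:
            return None
        return all(sp in plan.present_in for sp in members)


def generate_clade_dataset(
    clades: Mapping[str, Sequence[str]],
    plans: Sequence[CladeRepeatPlan],
    availability: Mapping[str, Sequence[str]] | None = None,
    seed: int | np.random.Generator | None = None,
    scaffold_len: int = 40,
    params: DetectorParams = DetectorParams(),
) -> SyntheticCladeDataset:
    """Per-species gene fragments for a clade-common analysis.

    ``availability`` maps each gene to the species with a sequence
    (default: every clade member); unavailable species are absent from the
    gene's alignment, emulating fragments that could not be isolated.
    """
    rng = _rng(seed)
    all_species = [sp for members in clades.values() for sp in members]
    genes = sorted({p.gene for p in plans})
    availability = {
        g: tuple(availability[g]) if availability and g in availability
        else tuple(all_species)
        for g in genes
    }
    records: dict[str, dict[str, PairedRecord]] = {sp: {} for sp in all_species}
    alignments: dict[str, CodonAlignment] = {}
    for gene in genes:
        avail = [sp for sp in all_species if sp in availability[gene]]
        gene_plans = [p for p in plans if p.gene == gene]
        for p in gene_plans:
            stray = set(p.present_in) - set(avail)
            if stray:
                raise ValueError(f"{gene}: plan present in unavailable {stray}")
        cplans = [
            ConservationPlan(p.residue, p.length, tuple(p.present_in))
            for p in gene_plans
        ]
        fam_records, alignment, _ = _build_family(
            avail, cplans, (), rng, gene, scaffold_len, params
        )
        alignments[gene] = alignment
        for sp, rec in fam_records.items():
            records[sp][gene] = rec
    return SyntheticCladeDataset(
        records,
        alignments,
        {c: tuple(m) for c, m in clades.items()},
        availability,
        list(plans),
    )
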