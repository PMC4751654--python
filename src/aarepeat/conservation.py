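"""Cross-species repeat conservation on codon-based alignments.

Repeats detected in the proteins of an ortholog family are mapped onto the
family's codon-based nucleotide alignment.  Two repeats in two species are
conserved counterparts when they are formed by the same amino-acid type and
their residue-column intervals share at least one codon column.  A repeated
nucleotide tract read in two different frames in two species (e.g. as polyP
in one and polyA in the other) therefore never counts as conserved: the
translated types differ.

From the pairwise decisions the module derives, per reference repeat, a
conservation class -- species-only (no counterpart in any compared species,
after excluding a designated close relative), conserved-in-k, or
conserved-in-all -- and, for gene families analysed across a clade, the
clade-common / non-clade-common status of each repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

from .repeat_detection import RepeatAnnotation, RepeatCatalog

GAP = "-"


class AlignmentError(ValueError):
    """Codon-alignment invariant violated."""


@dataclass
class CodonAlignment:
    """A codon-based (frame-preserving) nucleotide alignment of one family.

    ``sequences`` maps species to the gapped nucleotide sequence;
    ``protein_ids`` maps species to the aligned protein's identifier.
    Gaps must come in codon-sized chunks: every aligned codon (3-column
    block) of a species is either fully gap or fully nucleotide.
    """

    sequences: dict[str, str]
    protein_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError("aligned sequences differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise AlignmentError("alignment length not a multiple of 3")
        for sp, seq in self.sequences.items():
            for i in range(0, len(seq), 3):
                chunk = seq[i : i + 3]
                if GAP in chunk and chunk != GAP * 3:
                    raise AlignmentError(
                        f"{sp}: partial codon gap at column {i}"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_residue_columns(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3

    def ungapped(self, species: str) -> str:
        return self.sequences[species].replace(GAP, "")

    def gapped_protein(self, species: str) -> str:
        """One symbol per codon column ('-' for a gap codon)."""
        seq = self.sequences[species]
        out = []
        for i in range(0, len(seq), 3):
            chunk = seq[i : i + 3]
            if chunk == GAP * 3:
                out.append(GAP)
            elif "N" in chunk:
                out.append("X")
            else:
                out.append(str(Seq(chunk).translate()))
        return "".join(out)


@dataclass(frozen=True)
class AlignedInterval:
    """A repeat's interval expressed in residue (codon) columns."""

    species: str
    repeat: RepeatAnnotation
    column_start: int
    column_end: int

    @property
    def main_residue(self) -> str:
        return self.repeat.main_residue


def map_repeat_to_alignment(
    repeat: RepeatAnnotation, gapped_protein: str, species: str = ""
) -> AlignedInterval:
    """Map a repeat's residue interval to alignment residue columns.

    ``gapped_protein`` must ungap to the repeat's protein sequence;
    round-trip (column interval -> gap removal) recovers the residue
    interval exactly.
    """
    residue_to_column: list[int] = [
        col for col, ch in enumerate(gapped_protein) if ch != GAP
    ]
    if repeat.end > len(residue_to_column) or repeat.start < 0:
        raise ValueError(
            f"repeat [{repeat.start},{repeat.end}) outside the "
            f"{len(residue_to_column)}-residue aligned sequence"
        )
    return AlignedInterval(
        species,
        repeat,
        residue_to_column[repeat.start],
        residue_to_column[repeat.end - 1] + 1,
    )


def is_conserved_pair(a: AlignedInterval, b: AlignedInterval) -> bool:
    """Same amino-acid type and at least one shared codon column.

    Codon-based alignments fix the reading frame per residue column, so
    same-column overlap of same-type repeats implies identical codon phase;
    a frame-shifted nucleotide repeat surfaces as a different amino acid and
    fails the type test.
    """
    if a.main_residue != b.main_residue:
        return False
    return max(a.column_start, b.column_start) < min(a.column_end, b.column_end)


@dataclass(frozen=True)
class ConservationRecord:
    repeat: RepeatAnnotation
    presence: tuple[tuple[str, bool], ...]  # per compared species
    n_conserved: int
    n_effective: int  # counterparts outside the excluded close relatives
    conservation_class: str  # species_only | conserved_in_k | conserved_in_all

    def present_in(self) -> set[str]:
        return {sp for sp, ok in self.presence if ok}


def _classify(
    presence: dict[str, bool], excluded: set[str]
) -> tuple[int, int, str]:
    n_conserved = sum(presence.values())
    n_effective = sum(ok for sp, ok in presence.items() if sp not in excluded)
    if n_effective == 0:
        cls = "species_only"
    elif n_conserved == len(presence):
        cls = "conserved_in_all"
    else:
        cls = "conserved_in_k"
    return n_conserved, n_effective, cls


def classify_conservation(
    reference: str,
    catalogs: Mapping[str, RepeatCatalog],
    alignments: Mapping[str, CodonAlignment],
    exclusion_map: Mapping[str, Iterable[str]] | None = None,
) -> tuple[list[ConservationRecord], list[str]]:
    """Conservation class of every reference-species repeat.

    ``alignments`` is keyed by the reference protein id of each ortholog
    family.  Reference proteins with repeats but no alignment are collected
    in the returned skip report rather than raising.
    """
    exclusion_map = exclusion_map or {}
    excluded = set(exclusion_map.get(reference, ()))
    index = {sp: cat.by_protein for sp, cat in catalogs.items()}
    records: list[ConservationRecord] = []
    skipped: list[str] = []
    for repeat in catalogs[reference]:
        aln = alignments.get(repeat.protein_id)
        if aln is None:
            skipped.append(repeat.protein_id)
            continue
        ref_interval = map_repeat_to_alignment(
            repeat, aln.gapped_protein(reference), reference
        )
        presence: dict[str, bool] = {}
        for sp in aln.species:
            if sp == reference:
                continue
            other_id = aln.protein_ids.get(sp, "")
            gapped = aln.gapped_protein(sp)
            found = False
            for other in index.get(sp, {}).get(other_id, []):
                other_interval = map_repeat_to_alignment(other, gapped, sp)
                if is_conserved_pair(ref_interval, other_interval):
                    found = True
                    break
            presence[sp] = found
        n_cons, n_eff, cls = _classify(presence, excluded)
        records.append(
            ConservationRecord(
                repeat, tuple(sorted(presence.items())), n_cons, n_eff, cls
            )
        )
    return records, sorted(set(skipped))


def conservation_summary(records: Sequence[ConservationRecord]) -> pd.DataFrame:
    """Counts per conservation class plus the total (partition check)."""
    counts = {"species_only": 0, "conserved_in_k": 0, "conserved_in_all": 0}
    for rec in records:
        counts[rec.conservation_class] += 1
    rows = [{"data_set": "all_repeats", "count": len(records)}]
    rows += [
        {"data_set": k, "count": v} for k, v in counts.items()
    ]
    return pd.DataFrame(rows)


def species_only_proportion_test(
    counts: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    """Two-sided exact tests on every species pair's
    (species-only, not-species-only) 2x2 table."""
    for sp, (only, total) in counts.items():
        if total <= 0:
            raise ValueError(f"{sp}: zero total")
        if not (0 <= only <= total):
            raise ValueError(f"{sp}: species-only count outside [0, total]")
    species = sorted(counts)
    rows = []
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            oa, ta = counts[sa]
            ob, tb = counts[sb]
            _, p = stats.fisher_exact(
                [[oa, ta - oa], [ob, tb - ob]], alternative="two-sided"
            )
            rows.append(
                {"species_a": sa, "species_b": sb, "p_value": float(p)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clade-common analysis of gene families


@dataclass
class CladeRepeatFlag:
    gene: str
    clade: str
    main_residue: str
    column_start: int
    column_end: int
    clade_common: bool | None  # None when the clade has one available species


@dataclass
class CladeRepeatMatrix:
    """Gene x species repeat counts with clade-common flags."""

    counts: pd.DataFrame  # genes x species, -1 marks unavailable (N/A)
    flags: list[CladeRepeatFlag]

    def totals(self) -> pd.Series:
        """Total repeats per species over available genes."""
        return self.counts.where(self.counts >= 0, 0).sum(axis=0).astype(int)

    def repeat_gene_counts(self) -> pd.Series:
        """Number of repeat-containing genes per species."""
        return (self.counts > 0).sum(axis=0).astype(int)

    def clade_totals(self) -> pd.DataFrame:
        rows = []
        for clade in sorted({f.clade for f in self.flags}):
            fl = [f for f in self.flags if f.clade == clade]
            defined = [f for f in fl if f.clade_common is not None]
            rows.append(
                {
                    "clade": clade,
                    "clade_common": sum(f.clade_common for f in defined),
                    "non_clade_common": sum(
                        not f.clade_common for f in defined
                    ),
                    "undefined": len(fl) - len(defined),
                }
            )
        return pd.DataFrame(rows)


def classify_clade_common(
    catalogs: Mapping[str, RepeatCatalog],
    alignments: Mapping[str, CodonAlignment],
    clades: Mapping[str, Sequence[str]],
    species_order: Sequence[str] | None = None,
) -> CladeRepeatMatrix:
    """Clade-common status of gene-family repeats.

    ``alignments`` is keyed by gene; a species missing from a gene's
    alignment is unavailable (N/A) for that gene and is skipped, not counted
    as absent.  Presence is chained pairwise against an anchor species (the
    clade member available for the most genes); a repeat is clade-common iff
    a same-type overlapping repeat exists in every available clade species.
    Clades with a single available species for a gene yield an undefined
    flag.
    """
    index = {sp: cat.by_protein for sp, cat in catalogs.items()}
    genes = sorted(alignments)
    all_species = list(species_order) if species_order else sorted(
        {sp for aln in alignments.values() for sp in aln.species}
    )
    counts = pd.DataFrame(-1, index=genes, columns=all_species)

    def repeats_on(gene: str, sp: str) -> list[AlignedInterval]:
        aln = alignments[gene]
        pid = aln.protein_ids.get(sp, "")
        gapped = aln.gapped_protein(sp)
        return [
            map_repeat_to_alignment(r, gapped, sp)
            for r in index.get(sp, {}).get(pid, [])
        ]

    cache: dict[tuple[str, str], list[AlignedInterval]] = {}
    for gene in genes:
        for sp in alignments[gene].species:
            if sp in counts.columns:
                cache[(gene, sp)] = repeats_on(gene, sp)
                counts.loc[gene, sp] = len(cache[(gene, sp)])

    flags: list[CladeRepeatFlag] = []
    for clade, members in clades.items():
        availability = {
            sp: sum(sp in alignments[g].species for g in genes) for sp in members
        }
        ranked = sorted(members, key=lambda sp: (-availability[sp], sp))
        for gene in genes:
            available = [sp for sp in members if sp in alignments[gene].species]
            if not available:
                continue
            anchor = next(sp for sp in ranked if sp in available)
            # cluster repeats across the clade: anchor repeats seed clusters,
            # non-anchor repeats join the first same-type overlapping cluster
            # or seed an anchorless one (necessarily non-clade-common)
            clusters: list[tuple[AlignedInterval, set[str], bool]] = [
                (iv, {anchor}, True) for iv in cache[(gene, anchor)]
            ]
            for sp in available:
                if sp == anchor:
                    continue
                for iv in cache[(gene, sp)]:
                    for rep, seen, _ in clusters:
                        if is_conserved_pair(iv, rep):
                            seen.add(sp)
                            break
                    else:
                        clusters.append((iv, {sp}, False))
            for rep, seen, anchored in clusters:
                if len(available) == 1:
                    common: bool | None = None
                elif anchored:
                    common = seen == set(available)
                else:
                    common = False
                flags.append(
                    CladeRepeatFlag(
                        gene,
                        clade,
                        rep.main_residue,
                        rep.column_start,
                        rep.column_end,
                        common,
                    )
                )
    return CladeRepeatMatrix(counts, flags)


# ---------------------------------------------------------------------------
# gapped-FASTA ingestion


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    """Read a gapped FASTA codon alignment; headers are 'species|protein_id'."""
    sequences: dict[str, str] = {}
    protein_ids: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if "|" in entry.id:
            species, pid = entry.id.split("|", 1)
        else:
            species, pid = entry.id, entry.id
        sequences[species] = str(entry.seq).upper()
        protein_ids[species] = pid
    return CodonAlignment(sequences, protein_ids)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp, seq in aln.sequences.items():
            pid = aln.protein_ids.get(sp, sp)
            fh.write(f">{sp}|{pid}\n{seq}\n")


def validate_against_cds(aln: CodonAlignment, cds: Mapping[str, str]) -> None:
    """Check that ungapping each aligned sequence recovers its CDS
    (terminal stop codons on the CDS side are tolerated)."""
    for sp, seq in aln.sequences.items():
        raw = cds.get(aln.protein_ids.get(sp, sp))
        if raw is None:
            continue
        ungapped = seq.replace(GAP, "")
        if raw != ungapped and raw[:-3] != ungapped:
            raise AlignmentError(f"{sp}: alignment does not ungap to its CDS")
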