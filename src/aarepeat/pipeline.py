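"""Orchestration of the three analyses from a single declarative config.

Stages
------
``run_proteome_scan``
    Whole-proteome repeat scan: detection, per-type summary, length
    histogram, positional profile (and PLP when a CDS file is supplied).
``run_ortholog_comparison``
    Multi-species comparison over an RBH ortholog set: ortholog table,
    per-repeat conservation classes with close-relative exclusion, a
    conservation-class summary, functional-group repeat frequencies and
    GC profiles with repeat excision.
``run_clade_analysis``
    Gene-family comparison across clades from codon alignments: gene x
    species repeat-count matrix with clade-common flags and totals.

All stages are deterministic; randomness exists only in the synthetic-data
presets, which are seed-controlled.  Every stage writes a MANIFEST listing
output files and their SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as synth
from .conservation import (
    classify_clade_common,
    classify_conservation,
    conservation_summary,
    read_codon_alignment,
)
from .functional_profiles import (
    assign_functional_group,
    gc_profile,
    gc_profile_frame,
    read_go_table,
    write_go_table,
)
from .orthology import (
    build_ortholog_table,
    read_hit_table,
    reciprocal_best_hits,
    write_hit_table,
    write_ortholog_table,
)
from .repeat_detection import DetectorParams, RepeatCatalog, detect_proteome
from .repeat_statistics import (
    length_histogram,
    position_profile,
    profile_catalog,
    summarize_by_type,
    summary_frame,
)
from .sequence_io import (
    PairedRecord,
    pair_proteome,
    read_cds_fasta,
    read_gene_map,
    read_protein_fasta,
    select_longest_isoform,
    write_cds_fasta,
    write_protein_fasta,
)


@dataclass
class PipelineConfig:
    """Declarative configuration of all stages (see the preset writers for
    a complete example)."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    scan: dict[str, Any] = field(default_factory=dict)
    compare: dict[str, Any] = field(default_factory=dict)
    clade: dict[str, Any] = field(default_factory=dict)
    out_dir: Path = Path("out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = raw.get("detector", {})
        params = DetectorParams(
            min_core_length=int(det.get("min_core", 5)),
            max_nonmain_run=int(det.get("max_insert", 5)),
            min_main_fraction=float(det.get("min_purity", 0.70)),
        )
        base = Path(path).parent
        cfg = cls(
            detector=params,
            scan=raw.get("scan", {}),
            compare=raw.get("compare", {}),
            clade=raw.get("clade", {}),
            out_dir=base / raw.get("out_dir", "out"),
            seed=int(raw.get("seed", 0)),
        )
        cfg._base = base  # type: ignore[attr-defined]
        return cfg

    def resolve(self, p: str | Path) -> Path:
        base = getattr(self, "_base", Path("."))
        p = Path(p)
        return p if p.is_absolute() else base / p


def _write_manifest(out_dir: Path, files: list[Path]) -> None:
    lines = []
    for f in sorted(files):
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        lines.append(f"{digest}  {f.name}")
    (out_dir / "MANIFEST").write_text("\n".join(lines) + "\n")


def catalog_frame(
    catalog: RepeatCatalog,
    species: str,
    gene_ids: Mapping[str, str],
    sequences: Mapping[str, str],
    plp: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Repeat annotations as the documented TSV layout."""
    rows = []
    for i, ann in enumerate(catalog):
        rows.append(
            {
                "species": species,
                "protein_id": ann.protein_id,
                "gene_id": gene_ids.get(ann.protein_id, ""),
                "main_residue": ann.main_residue,
                "start": ann.start,
                "end": ann.end,
                "length": ann.length,
                "main_count": ann.main_count,
                "purity": round(ann.purity, 6),
                "longest_core": ann.longest_core,
                "is_perfect": int(ann.is_perfect),
                "plp": round(plp[i], 6) if plp and i in plp else "",
                "repeat_sequence": ann.sequence_slice(
                    sequences[ann.protein_id]
                ),
            }
        )
    columns = [
        "species", "protein_id", "gene_id", "main_residue", "start", "end",
        "length", "main_count", "purity", "longest_core", "is_perfect",
        "plp", "repeat_sequence",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_proteome_scan(config: PipelineConfig) -> Path:
    """Scan one proteome; returns the stage output directory."""
    scan = config.scan
    out = config.out_dir / "scan"
    out.mkdir(parents=True, exist_ok=True)
    species = scan.get("species", "unknown")
    gene_map = (
        read_gene_map(config.resolve(scan["gene_map"]))
        if "gene_map" in scan
        else None
    )
    proteins = read_protein_fasta(
        config.resolve(scan["proteins"]), species=species, gene_map=gene_map
    )
    proteins = select_longest_isoform(proteins)
    catalog = detect_proteome(proteins, config.detector)
    sequences = {p.protein_id: p.sequence for p in proteins}
    gene_ids = {p.protein_id: p.gene_id for p in proteins}

    plp_by_row: dict[int, float] | None = None
    profiles = None
    if "cds" in scan:
        cds = read_cds_fasta(config.resolve(scan["cds"]))
        paired = pair_proteome(proteins, cds, skip_missing=True)
        profiles = profile_catalog(catalog, paired)
        plp_by_row = {}
        by_key = {
            (p.repeat.protein_id, p.repeat.start, p.repeat.end): p.plp
            for p in profiles
        }
        for i, ann in enumerate(catalog):
            key = (ann.protein_id, ann.start, ann.end)
            if key in by_key:
                plp_by_row[i] = by_key[key]

    files = []
    repeats = catalog_frame(catalog, species, gene_ids, sequences, plp_by_row)
    repeats.to_csv(out / "repeats.tsv", sep="\t", index=False)
    files.append(out / "repeats.tsv")
    if len(catalog) > 0:
        rows = summarize_by_type(catalog, profiles)
        summary_frame(rows).to_csv(
            out / "summary.tsv", sep="\t", index=False, float_format="%.4f"
        )
        counts, edges, prop = length_histogram(a.length for a in catalog)
        pd.DataFrame(
            {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
        ).to_csv(out / "length_histogram.tsv", sep="\t", index=False)
        position_profile(
            catalog, {p.protein_id: len(p.sequence) for p in proteins}
        ).to_csv(out / "positions.tsv", sep="\t", index=False, float_format="%.6f")
        files += [
            out / "summary.tsv",
            out / "length_histogram.tsv",
            out / "positions.tsv",
        ]
    else:
        # empty proteome or no repeats: headers only, still a valid run
        summary_frame([]).to_csv(out / "summary.tsv", sep="\t", index=False)
        files.append(out / "summary.tsv")
    _write_manifest(out, files)
    return out


def _load_species_proteome(
    config: PipelineConfig, species: str, entry: Mapping[str, Any]
) -> tuple[list, dict[str, PairedRecord]]:
    gene_map = (
        read_gene_map(config.resolve(entry["gene_map"]))
        if "gene_map" in entry
        else None
    )
    proteins = select_longest_isoform(
        read_protein_fasta(
            config.resolve(entry["proteins"]), species=species, gene_map=gene_map
        )
    )
    paired: dict[str, PairedRecord] = {}
    if "cds" in entry:
        cds = read_cds_fasta(config.resolve(entry["cds"]))
        paired = pair_proteome(proteins, cds, skip_missing=True)
    return proteins, paired


def run_ortholog_comparison(config: PipelineConfig) -> Path:
    cmp_cfg = config.compare
    out = config.out_dir / "compare"
    out.mkdir(parents=True, exist_ok=True)
    reference: str = cmp_cfg["reference"]
    species: list[str] = list(cmp_cfg["species"])
    evalue_max = float(cmp_cfg.get("evalue_max", 1e-20))
    exclusion = {
        sp: list(v) for sp, v in (cmp_cfg.get("exclusion") or {}).items()
    }

    proteomes: dict[str, list] = {}
    paired: dict[str, dict[str, PairedRecord]] = {}
    for sp in species:
        proteomes[sp], paired[sp] = _load_species_proteome(
            config, sp, cmp_cfg["proteomes"][sp]
        )

    rbh_by_species = {}
    for sp in species:
        if sp == reference:
            continue
        fwd_path, rev_path = cmp_cfg["hits"][sp]
        rbh_by_species[sp] = reciprocal_best_hits(
            read_hit_table(config.resolve(fwd_path)),
            read_hit_table(config.resolve(rev_path)),
            evalue_max,
        )
    table = build_ortholog_table(
        reference, rbh_by_species, require_complete=True
    )
    write_ortholog_table(table, out / "orthologs.tsv")

    # repeat detection restricted to the orthologous protein set
    member_ids: dict[str, set[str]] = {reference: set(table.rows)}
    for sp in species:
        if sp == reference:
            continue
        member_ids[sp] = {row[sp] for row in table.rows.values() if sp in row}
    catalogs: dict[str, RepeatCatalog] = {}
    for sp in species:
        members = [p for p in proteomes[sp] if p.protein_id in member_ids[sp]]
        catalogs[sp] = detect_proteome(members, config.detector)

    aln_dir = config.resolve(cmp_cfg["alignments_dir"])
    alignments = {}
    for ref_id in table.rows:
        path = aln_dir / f"{ref_id}.fasta"
        if path.exists():
            alignments[ref_id] = read_codon_alignment(path)
    records, skipped = classify_conservation(
        reference, catalogs, alignments, exclusion
    )
    cons = pd.DataFrame(
        [
            {
                "protein_id": r.repeat.protein_id,
                "main_residue": r.repeat.main_residue,
                "start": r.repeat.start,
                "end": r.repeat.end,
                "length": r.repeat.length,
                "n_conserved": r.n_conserved,
                "n_effective": r.n_effective,
                "conservation_class": r.conservation_class,
                "present_in": ",".join(sorted(r.present_in())),
            }
            for r in records
        ],
        columns=[
            "protein_id", "main_residue", "start", "end", "length",
            "n_conserved", "n_effective", "conservation_class", "present_in",
        ],
    )
    cons.to_csv(out / "conservation.tsv", sep="\t", index=False)
    (out / "skip_report.txt").write_text("\n".join(skipped) + "\n" if skipped else "")

    # Table-3-shaped summary with PLP per conservation class
    plp_map: dict[tuple[str, int, int], float] = {}
    if paired[reference]:
        for prof in profile_catalog(catalogs[reference], paired[reference]):
            r = prof.repeat
            plp_map[(r.protein_id, r.start, r.end)] = prof.plp
    summary_rows = []
    groups = {
        "all_repeats": records,
        "species_only": [r for r in records if r.conservation_class == "species_only"],
        "conserved_in_all": [
            r for r in records if r.conservation_class == "conserved_in_all"
        ],
        "conserved_in_k": [
            r for r in records if r.conservation_class == "conserved_in_k"
        ],
    }
    for name, recs in groups.items():
        if not recs:
            summary_rows.append({"data_set": name, "count": 0})
            continue
        lengths = [r.repeat.length for r in recs]
        cores = [r.repeat.longest_core for r in recs]
        plps = [
            plp_map[(r.repeat.protein_id, r.repeat.start, r.repeat.end)]
            for r in recs
            if (r.repeat.protein_id, r.repeat.start, r.repeat.end) in plp_map
        ]
        summary_rows.append(
            {
                "data_set": name,
                "count": len(recs),
                "mean_length": round(float(np.mean(lengths)), 4),
                "max_length": max(lengths),
                "mean_core": round(float(np.mean(cores)), 4),
                "max_core": max(cores),
                "mean_plp": round(float(np.mean(plps)), 4) if plps else "",
                "n_plp1": sum(p == 1 for p in plps) if plps else "",
            }
        )
    pd.DataFrame(summary_rows).to_csv(
        out / "conservation_summary.tsv", sep="\t", index=False
    )

    # functional groups keyed on the annotation species, propagated per row
    files = [
        out / "orthologs.tsv", out / "conservation.tsv",
        out / "conservation_summary.tsv", out / "skip_report.txt",
    ]
    if "go_table" in cmp_cfg:
        go = read_go_table(config.resolve(cmp_cfg["go_table"]))
        go_species = cmp_cfg.get("go_species", reference)
        assignment = {}
        for ref_id, row in table.rows.items():
            anno_id = ref_id if go_species == reference else row.get(go_species)
            assignment[ref_id] = assign_functional_group(
                go.get(anno_id, []) if anno_id else []
            )
        freq_rows = []
        from .functional_profiles import repeat_frequency_by_group

        freqs = repeat_frequency_by_group(catalogs[reference], assignment)
        sizes = pd.Series(list(assignment.values())).value_counts()
        for group, freq in freqs.items():
            freq_rows.append(
                {
                    "group": group,
                    "n_proteins": int(sizes.get(group, 0)),
                    "frequency": round(freq, 6),
                }
            )
        pd.DataFrame(freq_rows).to_csv(
            out / "group_frequencies.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(assignment.items()), columns=["protein_id", "group"]
        ).to_csv(out / "group_assignment.tsv", sep="\t", index=False)
        files += [out / "group_frequencies.tsv", out / "group_assignment.tsv"]

    # GC profiles per species (orthologous members only)
    gc_rows = []
    for sp in species:
        if not paired[sp]:
            continue
        members = {
            pid: rec for pid, rec in paired[sp].items() if pid in member_ids[sp]
        }
        profs = [gc_profile(members, catalogs[sp], "all_orthologs")]
        if catalogs[sp].rcp_ids():
            profs.append(gc_profile(members, catalogs[sp], "rcp_repeats_removed"))
        df = gc_profile_frame(profs)
        df.insert(0, "species", sp)
        gc_rows.append(df)
    if gc_rows:
        pd.concat(gc_rows).to_csv(
            out / "gc_profiles.tsv", sep="\t", index=False, float_format="%.6f"
        )
        files.append(out / "gc_profiles.tsv")

    _write_manifest(out, files)
    return out


def run_clade_analysis(config: PipelineConfig) -> Path:
    clade_cfg = config.clade
    out = config.out_dir / "clade"
    out.mkdir(parents=True, exist_ok=True)
    clades = {c: list(m) for c, m in clade_cfg["clades"].items()}
    aln_dir = config.resolve(clade_cfg["alignments_dir"])
    alignments = {
        p.stem: read_codon_alignment(p) for p in sorted(aln_dir.glob("*.fasta"))
    }

    # detect repeats on the (translated) ungapped member sequences
    from .sequence_io import ProteinRecord

    catalogs: dict[str, RepeatCatalog] = {}
    per_species: dict[str, list[ProteinRecord]] = {}
    for gene, aln in alignments.items():
        for sp in aln.species:
            pid = aln.protein_ids.get(sp, sp)
            protein = ProteinRecord(pid, gene, sp, aln.gapped_protein(sp).replace("-", ""))
            per_species.setdefault(sp, []).append(protein)
    for sp, prots in per_species.items():
        catalogs[sp] = detect_proteome(prots, config.detector)

    species_order = [sp for members in clades.values() for sp in members]
    matrix = classify_clade_common(catalogs, alignments, clades, species_order)

    counts = matrix.counts.astype(object)
    counts[matrix.counts < 0] = "N/A"
    counts.index.name = "gene"
    counts.to_csv(out / "clade_matrix.tsv", sep="\t")
    pd.DataFrame(
        {
            "total_repeats": matrix.totals(),
            "repeat_containing_genes": matrix.repeat_gene_counts(),
        }
    ).rename_axis("species").to_csv(out / "clade_species_totals.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "gene": f.gene,
                "clade": f.clade,
                "main_residue": f.main_residue,
                "column_start": f.column_start,
                "column_end": f.column_end,
                "clade_common": "" if f.clade_common is None else int(f.clade_common),
            }
            for f in matrix.flags
        ]
    ).to_csv(out / "clade_flags.tsv", sep="\t", index=False)
    matrix.clade_totals().to_csv(out / "clade_totals.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        [
            out / "clade_matrix.tsv",
            out / "clade_species_totals.tsv",
            out / "clade_flags.tsv",
            out / "clade_totals.tsv",
        ],
    )
    return out


# ---------------------------------------------------------------------------
# synthetic presets: write pipeline-ready input trees with ground truth

SPECIES_SIX = ("anole", "frog", "turtle", "zebrafinch", "mouse", "human")

#: close-relative exclusion used for species-only counting
DEFAULT_EXCLUSION = {
    "human": ["mouse"],
    "mouse": ["human"],
    "zebrafinch": ["turtle"],
    "turtle": ["zebrafinch"],
}


def write_proteome_preset(out_dir: str | Path, seed: int = 0) -> Path:
    """Synthetic proteome preset: protein+CDS FASTA, config and truth."""
    out_dir = Path(out_dir)
    (out_dir / "inputs").mkdir(parents=True, exist_ok=True)
    proteome = synth.generate_proteome(n_proteins=40, seed=seed, species="anole")
    write_protein_fasta(proteome.proteins, out_dir / "inputs" / "proteins.fasta")
    write_cds_fasta(
        [rec.cds for rec in proteome.records], out_dir / "inputs" / "cds.fasta"
    )
    truth = {
        "planted_repeats": [
            {
                "protein_id": t.protein_id,
                "residue": t.residue,
                "start": t.start,
                "end": t.end,
                "purity": t.purity,
                "longest_core": t.longest_core,
                "longest_pure_run": t.longest_pure_run,
                "plp": t.plp,
            }
            for t in proteome.truth
        ]
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    config = {
        "seed": seed,
        "out_dir": "out",
        "scan": {
            "species": "anole",
            "proteins": "inputs/proteins.fasta",
            "cds": "inputs/cds.fasta",
        },
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config))
    return out_dir / "config.yaml"


def _family_plans() -> dict[str, list[synth.ConservationPlan]]:
    """Fixed family structure of the preset (seed varies sequence/codons)."""
    S = SPECIES_SIX
    return {
        "g01": [synth.ConservationPlan("E", 7, present_in=S)],
        "g02": [synth.ConservationPlan("A", 6, present_in=("anole",))],
        "g03": [
            synth.ConservationPlan("Q", 8, present_in=("anole", "mouse", "human"))
        ],
        "g04": [
            synth.ConservationPlan(
                "P", 6, present_in=("anole",), decoy_residue="A"
            )
        ],
        "g05": [synth.ConservationPlan("S", 6, present_in=("frog", "turtle"))],
        "g06": [synth.ConservationPlan("G", 7, present_in=("anole", "frog"))],
        "g07": [],
        "g08": [
            synth.ConservationPlan("K", 6, present_in=("anole",)),
            synth.ConservationPlan("D", 6, present_in=S),
        ],
    }


_FAMILY_GROUPS = {
    "g01": "TF_Development",
    "g02": "Signal",
    "g03": "TF_Development",
    "g04": "Metabolism",
    "g05": "Others",
    "g06": "Signal",
    "g07": "Others",
    "g08": "TF_Development",
}


def _reference_repeat_truth(families) -> list[dict[str, Any]]:
    """Expected reference-species repeats with their conservation class.

    Planted entries per species follow plan order, one entry per plan in
    which the species carries either the main tract or a frame-shift decoy;
    walk both lists in lockstep to pair plans with their reference tract.
    """
    out = []
    for fam in families:
        entries = iter(fam.truth.planted["anole"])
        for plan in fam.truth.plans:
            if "anole" in plan.present_in:
                rep = next(entries)
                out.append(
                    {
                        "protein_id": rep.protein_id,
                        "residue": rep.residue,
                        "start": rep.start,
                        "end": rep.end,
                        "plp": rep.plp,
                        "class": fam.truth.expected_class(plan),
                    }
                )
            elif plan.decoy_residue is not None:
                next(entries)  # anole carries the decoy, not the tract
    return out


def write_family_preset(out_dir: str | Path, seed: int = 0) -> Path:
    """Six-species ortholog-comparison preset: proteomes, hit tables, codon
    alignments, GO table, config and truth."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    inputs = out_dir / "inputs"
    (inputs / "hits").mkdir(parents=True, exist_ok=True)
    (inputs / "alignments").mkdir(parents=True, exist_ok=True)

    plan_by_gene = _family_plans()
    families = []
    for gene, plans in plan_by_gene.items():
        gap_plan = [("frog", 6, 2)] if gene == "g06" else []
        families.append(
            synth.generate_ortholog_family(
                SPECIES_SIX,
                plans,
                gap_plan=gap_plan,
                seed=rng,
                scaffold_len=60,
                gene=gene,
            )
        )

    # per-species FASTA
    for sp in SPECIES_SIX:
        prots = [fam.records[sp].protein for fam in families]
        cds = [fam.records[sp].cds for fam in families]
        write_protein_fasta(prots, inputs / f"{sp}_proteins.fasta")
        write_cds_fasta(cds, inputs / f"{sp}_cds.fasta")

    # hit tables concatenated over families
    hits_cfg = {}
    for sp in SPECIES_SIX[1:]:
        fwd, rev = [], []
        for fam in families:
            fwd.extend(fam.hit_tables[("anole", sp)])
            rev.extend(fam.hit_tables[(sp, "anole")])
        fwd_path = inputs / "hits" / f"anole_vs_{sp}.tsv"
        rev_path = inputs / "hits" / f"{sp}_vs_anole.tsv"
        write_hit_table(fwd, fwd_path)
        write_hit_table(rev, rev_path)
        hits_cfg[sp] = [
            str(fwd_path.relative_to(out_dir)),
            str(rev_path.relative_to(out_dir)),
        ]

    # codon alignments keyed by reference protein id
    from .conservation import write_codon_alignment

    for fam in families:
        ref_id = fam.alignment.protein_ids["anole"]
        write_codon_alignment(
            fam.alignment, inputs / "alignments" / f"{ref_id}.fasta"
        )

    # GO table keyed on human protein ids
    group_plan = {
        fam.alignment.protein_ids["human"]: _FAMILY_GROUPS[fam.gene]
        for fam in families
    }
    go_table, go_truth = synth.generate_go_table(group_plan, seed=rng)
    write_go_table(go_table, inputs / "go.tsv")

    truth = {
        "rbh_pairs": sorted(
            [a, b] for fam in families for a, b in fam.truth.rbh_pairs
        ),
        "reference_repeats": _reference_repeat_truth(families),
        "planted_counts": {
            sp: sum(len(fam.truth.planted[sp]) for fam in families)
            for sp in SPECIES_SIX
        },
        "groups": {
            fam.alignment.protein_ids["anole"]: _FAMILY_GROUPS[fam.gene]
            for fam in families
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))

    config = {
        "seed": seed,
        "out_dir": "out",
        "compare": {
            "reference": "anole",
            "species": list(SPECIES_SIX),
            "evalue_max": 1e-20,
            "exclusion": DEFAULT_EXCLUSION,
            "proteomes": {
                sp: {
                    "proteins": f"inputs/{sp}_proteins.fasta",
                    "cds": f"inputs/{sp}_cds.fasta",
                }
                for sp in SPECIES_SIX
            },
            "hits": hits_cfg,
            "alignments_dir": "inputs/alignments",
            "go_table": "inputs/go.tsv",
            "go_species": "human",
        },
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config))
    return out_dir / "config.yaml"


CLADES_PRESET = {
    "squamates": ("anole", "gecko", "skink", "snake"),
    "mammals": ("human", "mouse", "dog"),
    "turtles": ("softshell",),
}


def _clade_plans() -> tuple[list[synth.CladeRepeatPlan], dict[str, tuple[str, ...]]]:
    sq = CLADES_PRESET["squamates"]
    mam = CLADES_PRESET["mammals"]
    plans = [
        synth.CladeRepeatPlan("hoxa13", "A", 7, (*sq, *mam, "softshell")),
        synth.CladeRepeatPlan("hoxd13", "S", 6, (*sq, "human")),
        synth.CladeRepeatPlan("hoxc4", "P", 6, ("anole", "gecko", "snake")),
        synth.CladeRepeatPlan("hoxb2", "G", 6, ("human", "mouse", "softshell")),
    ]
    availability = {
        "hoxa13": (*sq, *mam, "softshell"),
        "hoxd13": (*sq, *mam, "softshell"),
        "hoxc4": ("anole", "gecko", "snake", *mam, "softshell"),  # skink N/A
        "hoxb2": (*sq, *mam, "softshell"),
    }
    return plans, availability


def write_clade_preset(out_dir: str | Path, seed: int = 0) -> Path:
    """Gene-family clade preset: per-gene codon alignments, config, truth."""
    out_dir = Path(out_dir)
    inputs = out_dir / "inputs" / "alignments"
    inputs.mkdir(parents=True, exist_ok=True)
    plans, availability = _clade_plans()
    dataset = synth.generate_clade_dataset(
        CLADES_PRESET, plans, availability, seed=seed, scaffold_len=44
    )
    from .conservation import write_codon_alignment

    for gene, aln in dataset.alignments.items():
        write_codon_alignment(aln, inputs / f"{gene}.fasta")

    truth_flags = []
    for plan in plans:
        for clade in CLADES_PRESET:
            present_members = [
                sp for sp in CLADES_PRESET[clade] if sp in plan.present_in
            ]
            if not present_members:
                continue
            expected = dataset.expected_clade_common(plan, clade)
            truth_flags.append(
                {
                    "gene": plan.gene,
                    "clade": clade,
                    "residue": plan.residue,
                    "clade_common": expected,
                }
            )
    counts = {
        sp: {
            gene: (
                sum(
                    p.gene == gene and sp in p.present_in for p in plans
                )
                if sp in dataset.availability[gene]
                else None
            )
            for gene in dataset.alignments
        }
        for sp in [m for c in CLADES_PRESET.values() for m in c]
    }
    (out_dir / "truth.json").write_text(
        json.dumps({"flags": truth_flags, "counts": counts}, indent=1)
    )
    config = {
        "seed": seed,
        "out_dir": "out",
        "clade": {
            "alignments_dir": "inputs/alignments",
            "clades": {c: list(m) for c, m in CLADES_PRESET.items()},
        },
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config))
    return out_dir / "config.yaml"


def write_preset(preset: str, out_dir: str | Path, seed: int = 0) -> Path:
    writers = {
        "proteome": write_proteome_preset,
        "family": write_family_preset,
        "clade": write_clade_preset,
    }
    if preset not in writers:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(writers)}")
    return writers[preset](out_dir, seed)
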