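# aarepeat

Detection and comparative analysis of **tandem amino-acid repeats**
(homopolymeric tracts) in proteomes.

Tandem amino-acid repeats — runs of a protein dominated by one residue,
such as the polyglutamine tract of FoxP2 — are translated from
trinucleotide repeats that expand and contract by replication slippage at
rates far above the point-mutation rate. They concentrate in transcription
factors and developmental regulators and are a candidate source of rapid
phenotypic variability. Comparing repeat inventories across species
requires a chain of careful steps: detecting imperfect tracts with a
principled definition, characterising their codon structure to separate
young from old repeats, building an orthologous protein set, deciding when
two repeats in two species are *the same* repeat, and profiling the genes
that carry them. `aarepeat` implements that chain as a tested, scriptable
pipeline for anyone studying low-complexity coding sequence — plus a
seeded synthetic-data generator so every stage is verifiable offline
against planted ground truth.

## The model in brief

A repeat is an interval of a protein with main residue *r* such that

* it contains a core of ≥ 5 consecutive *r*,
* it starts and ends on *r*,
* no internal run of non-*r* residues exceeds 5, and
* purity (fraction of *r*) ≥ 70 %.

Purity = 1 is a perfect repeat. Reported intervals are maximal under
inclusion, one annotation per tract. For a repeat of length *n* with
codons available, **PLP** = (longest run of identical codons encoding
*r*) / *n*; PLP = 1 marks a tract encoded by a single repeated codon,
i.e. a young repeat. Orthology is reciprocal-best-hit (E < 10⁻²⁰, strict);
two repeats in orthologs are *conserved counterparts* iff they have the
same main residue and overlap by at least one codon column of the
codon-based alignment — so a repeated DNA tract read in two frames
(polyP vs polyA) never counts. A repeat with no counterpart in any
compared species (after excluding a designated close relative) is
*species-only*; in gene-family clade analyses a repeat found in every
available species of a clade is *clade-common*.

See `docs/methods.md` for the full treatment.

## Worked example

```python
from aarepeat import detect_repeats, compute_plp, pair_cds, ProteinRecord, CodingRecord

seq = "MEEEEEEKEEDLLPKAAAAAGTRSQQAQQPQQQQQLS"
cds = ("ATG" + "GAA"*6 + "AAA" + "GAA"*2 + "GAT" + "CTG"*2 + "CCG" + "AAA"
       + "GCT"*5 + "GGT" + "ACC" + "CGT" + "AGC" + "CAA"*2 + "GCA" + "CAA"*2
       + "CCG" + "CAG"*5 + "CTG" + "AGC" + "TAA")
protein = ProteinRecord("prot1", "gene1", "anole", seq)
paired = pair_cds(protein, CodingRecord("prot1", cds))
for ann in detect_repeats(seq, protein_id="prot1"):
    prof = compute_plp(ann, paired)
    print(f"{ann.main_residue}  [{ann.start},{ann.end})  len={ann.length}  "
          f"purity={ann.purity:.2f}  core={ann.longest_core}  "
          f"perfect={ann.is_perfect}  PLP={prof.plp:.2f}")
```

prints

```
E  [1,10)  len=9  purity=0.89  core=6  perfect=False  PLP=0.67
A  [15,20)  len=5  purity=1.00  core=5  perfect=True  PLP=1.00
Q  [24,35)  len=11  purity=0.82  core=5  perfect=False  PLP=0.45
```

Three tracts: an imperfect polyE (9 residues, one lysine insertion, its
longest pure-codon run GAA×6 giving PLP 6/9), a perfect single-codon polyA
(PLP = 1, a "young" repeat), and an imperfect polyQ whose mixed CAA/CAG
encoding caps PLP at 5/11 despite containing a 5-residue core.

## Command line

```sh
aarepeat synth --preset family --seed 1 --out demo      # synthetic inputs + truth
aarepeat run --config demo/config.yaml --stage compare  # ortholog comparison
aarepeat detect --proteins proteins.fasta --cds cds.fasta --species anole --out repeats.tsv
aarepeat summarize --repeats repeats.tsv --out summary.tsv
aarepeat orthologs --ref anole --species frog --hits a_vs_f.tsv f_vs_a.tsv --out orthologs.tsv
```

`aarepeat run` drives the three stages (proteome scan, six-species
ortholog comparison, clade gene-family analysis) from one YAML config and
writes TSV reports plus a MANIFEST of digests; re-runs are byte-identical.

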