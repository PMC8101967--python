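# merlintools

Curation toolkit for **Merlin-superfamily DNA transposons** — the Class II
(cut-and-paste) elements related to the bacterial IS*1595* family that have
recently been found far beyond animals, in red algae, metamonads,
kinetoplastids and alveolates.

Annotating these elements in a new genome assembly is a multi-step curation
problem that is usually done by hand: find transposase-like regions, verify
the catalytic domain, work out where each copy actually starts and ends,
confirm that copies are true transposition products rather than segmental
duplications or bacterial contamination, group them into families, and
prepare clean matrices for phylogenetics. `merlintools` turns every one of
those steps into a tested, scriptable operation — and ships a synthetic
genome generator with full ground truth, so the whole pipeline can be
validated end to end without touching external databases.

## The biology encoded in the defaults

A canonical Merlin element is

```
5'-[TSD] GG····TIR····  transposase ORF  ····TIR····CC [TSD]-3'
```

* **TIRs** (terminal inverted repeats): 24–462 bp, starting with `GG`, and
  sometimes remarkably imperfect — up to 12 mismatches in the first 26
  positions of an active family. Detection therefore extends inward under
  a cumulative-mismatch budget (≤ 50%) with a stop rule of 4 consecutive
  mismatches, rather than requiring perfection.
* **TSDs** (target site duplications): 8 or 9 bp, identical on the two
  flanks of one copy but *different between copies* — the signature that
  distinguishes transposition from segmental duplication.
* **Transposase**: carries the DDE_Tnp_IS1595 catalytic domain (~130 aa),
  scanned here as three conserved residue blocks anchored on the D-D-E
  triad, with a 40–120 aa linker between the aspartate blocks (typical
  span 50–70 aa) and a short block-2→3 spacer. The scan is a
  position-weight-matrix dynamic program with deterministic tie-breaking.
* **Degeneration states**: intact ORF, frameshifted pseudogene, remnant
  fragment — all classified per copy; conserved coding copies with *no*
  TIR/TSD evidence are reported as groups (G1, G2, …), candidate
  domesticates, while TIR+TSD-supported copies form families (F1, F2, …).
* **Contamination rule**: a protein with > 80 % identity (strict) to a
  bacterial reference is a possible contaminant; 40–80 % becomes suspect
  only when neighboring ORFs on the contig look bacterial too.

Copy divergence is measured as the p-distance (mismatch fraction over
compared sites, pairwise deletion), clustering trees are neighbor joining
with column-resampling bootstrap, and family consensus sequences use IUPAC
degenerate codes (`R`, `Y`, `S`, `W`, `K`, `M`, …) where copies disagree.

## Worked example

Simulate a genome with two planted families, then curate it blind:

```bash
cat > families.yaml <<'EOF'
background_length: 40000
contaminant_count: 1
families:
  - family_id: famA
    tir_length: 30
    tsd_length: 8
    n_copies: 3
    orf_length: 300
    per_copy_divergence: 0.01
  - family_id: famB
    tir_length: 39
    tir_mismatches: 3
    tsd_length: 9
    n_copies: 2
    orf_length: 260
    per_copy_divergence: 0.005
EOF

merlintools simulate --spec families.yaml --seed 11 --out sim/
merlintools curate --genome sim/genome.fasta --queries sim/queries.faa --out curated/
merlintools report --indir curated/
```

which prints

```
wrote genome (49237 bp, 5 planted copies) to sim
5 copies, 2 families, 0 groups -> curated/
copies: 5
classification
family_candidate    5
families/groups: 2
family_id  n_members                 members  tir_length  modal_tsd_length  mean_pdistance activity
       F1          3 chr1_+0,chr1_+1,chr1_-3          30                 8        0.012508   recent
       F2          2         chr1_+2,chr1_-4          39                 9        0.007261   recent
```

Reading the output: all five planted copies were recovered as
`family_candidate` (GG-terminal TIR **and** exact TSD found), the two
families were separated with their planted TIR lengths (30 and 39 bp) and
TSD sizes (8 and 9 bp), mean within-family p-distance matches the planted
~1 % / 0.5 % divergence, and both families are dated `recent` (near-identical
copies with distinct TSDs — the signature of ongoing transposition).
`curated/` also contains `elements.gff3` (elements with TIR/TSD child
features), `elements.fasta`, per-family degenerate consensus sequences and
a `provenance.json` with the config hash.

The same operations are importable as a library (`merlintools.simgenome`,
`orf_domain`, `copyfinder`, `boundaries`, `families`, `repeats`,
`contamination`, `phyloprep`, `pipeline`), and `merlintools phyloprep`
applies the domain-matrix filter chain (size > 115 aa → 70 % identity
clustering → alignment → 0.4 gap-threshold column trimming → drop rows
< 110 aa) and exports relaxed PHYLIP or NEXUS for external Bayesian/ML
tree inference.

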