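# neuromine

Mining assembled transcriptomes for neuropeptides and protein hormones.

Crustacean (and more broadly arthropod) neuropeptides are translated as
prepro-peptide precursors: a signal peptide followed by one or more peptide
cargoes separated by basic prohormone-convertase sites. Identifying them in
a de novo CNS transcriptome means calling precursor ORFs, removing the
signal peptide, cutting at dibasic sites (KR/RK/KK/RR), trimming the exposed
basics, flagging C-terminal amidation (a glycine donor) and N-terminal
pyroglutamate, grouping the products into hormone families by conserved
motifs (YXFGL-amide allatostatins, W-X₆-W-amide allatostatins, NFDEID
orcokinins, ...) or cysteine scaffolds (the 6-cysteine CHH/MIH domains,
12-cysteine neuroparsins, ...), quantifying conservation, and contrasting
expression between tissues as RPKM. `neuromine` implements that pipeline as
a tested library plus a CLI, for researchers curating neuropeptidomes from
non-model species where the raw evidence is an assembly, a BLAST annotation
table and per-library read counts.

The package ships hand-transcribed reference tables from a published spiny
lobster CNS neuropeptidome (37 precursor transcripts in 21 hormone
families, their printed mature peptides, and per-library RPKM values) used
as ground truth throughout the test suite, and a synthetic-data generator
that builds precursors, transcripts and negative-binomial count matrices
with known truth for every stage.

## Worked example

Reassemble the A-type allatostatin precursor from its 22 printed mature
peptides and run the maturation cascade:

```python
from neuromine.sequence_io import load_paper_fixtures
from neuromine.synthetic_data import PrecursorSpec, build_precursor_protein
from neuromine.maturation import process_precursor, SignalPrediction

rows = [(r.peptide, r.amidated) for r in load_paper_fixtures("table2")
        if r.family == "Allatostatin A"]
spec = PrecursorSpec(family="Allatostatin A", peptides=tuple(rows),
                     signal_length=27)
protein, truth = build_precursor_protein(spec)     # 277-aa precursor
model, mature = process_precursor(protein, SignalPrediction(27, "external", 1.0))
print("mature peptides:", len(mature))
for m in mature[:3]:
    print(f"  {m.start_aa:>3}-{m.end_aa:<3} {m.sequence}{'a' if m.amidated else ''}")
```

prints

```
mature peptides: 22
   28-35  HNNYAFGLa
   39-46  TPDYAFGLa
   50-57  EGMYSFGLa
```

— the 22 peptides come back exactly as printed, in precursor order, with
coordinates on the full protein and the trailing `a` marking amidation
(the glycine donor was stripped, the KR site trimmed). Conservation of the
two pigment-dispersing-hormone peptides:

```python
from neuromine.conservation import global_align
aln = global_align("NAELINSILGLPKVMNDA", "NAELINSLLGIPKVMSDA")
print(aln.identical_positions, "/", len(aln.seq_a_aligned))   # 15 / 18
```

From the shell, the same stages run as `neuromine orfs`, `neuromine
peptides`, `neuromine classify`, `neuromine conserve`, `neuromine quant`,
`neuromine simulate ...`, or end-to-end as `neuromine run --config
pipeline.yaml` (deterministic outputs plus a manifest of input checksums).

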