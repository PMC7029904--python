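# ppiipred

Polyproline II helix (PPIIH) tooling: assignment of PPIIH residues from
protein 3D structures by backbone dihedral-angle filtering, and
per-residue prediction of PPIIH propensity from sequence with a
bidirectional recurrent neural network (BRNN), plus a proline-window
baseline and a full evaluation suite.

## What is in the box

| module | purpose |
| --- | --- |
| `ppiipred.structgeom` | PDB backbone I/O, phi/psi/omega and CA pseudo-torsion computation, internal-to-Cartesian backbone construction |
| `ppiipred.ppii_label` | strict / non-strict PPIIH residue labelling (trans, dihedral and regularity filters; >= 3-residue segments) |
| `ppiipred.features`   | per-residue input encoding: one-hot, length, charge, optional MSA profile + gap frequency, optional disorder tracks (width 24 or 45) |
| `ppiipred.brnn`       | the BRNN (forward/backward hidden chains, three two-layer subnets), exact backprop, SGD training with lr-halving on validation stall, ensembling |
| `ppiipred.pipeline`   | every-10th test split, fivefold cross-validation, proline-window baseline, high-scoring-region extraction |
| `ppiipred.evalmetrics`| confusion counts, Sens / precision / MCC / accuracy, ROC/AUC, TP-vs-log10(FP) |
| `ppiipred.synthetic`  | seed-deterministic fixtures: backbone chains with planted PPII/alpha/beta segments and labelled corpora with a planted learnable rule |
| `ppiipred.io_cli`, `ppiipred.cli` | FASTA/TSV/YAML readers and writers and the `ppiipred` command-line tool |

Conventions: coordinates in Angstrom, angles in degrees in (-180, 180]
(IUPAC torsion signs, trans = 180), residue positions 1-based except the
BED-like segment output (0-based half-open). Amino-acid alphabet order is
`ACDEFGHIKLMNPQRSTVWY`.

## Command line

```sh
ppiipred simulate --kind structure --out-prefix demo   # synthetic PDB
ppiipred label demo.pdb --mode strict                  # PPIIH labels + segments

ppiipred simulate --kind corpus --n 200 --seed 1 --out-prefix corpus
ppiipred train corpus.fasta corpus.labels.tsv --epochs 100 --out model.json
ppiipred crossval corpus.fasta corpus.labels.tsv --epochs 50
ppiipred predict corpus.fasta --model model.json --out predictions.tsv
ppiipred baseline corpus.fasta --halfwidth 2
ppiipred regions predictions.tsv --cutoff 0.5
ppiipred evaluate predictions.tsv corpus.labels.tsv
```

Multi-FASTA input is supported throughout; predictions are per-residue
TSV (`id`, 1-based `position`, `residue`, `score`). Models are portable
JSON files that refuse to load on feature-layout mismatch.

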