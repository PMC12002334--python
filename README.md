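# pepfill

Chemistry-aware generative design of peptides by masked-position infilling.

`pepfill` is for peptide drug-discovery work where part of a sequence is
fixed — a binding motif, a pharmacophore, cyclization anchors — and the
remaining positions are open to redesign with **any** alpha-amino acid,
natural or non-natural, rather than a fixed 20-letter alphabet. A
sequence-to-sequence model reads a peptide with `?` at the open positions and
generates complete amino acids for exactly those slots, at the atomic level;
a REINVENT-style reinforcement-learning loop then steers generation toward
peptide-level objectives such as macrocyclic topology, solubility and
membrane permeability.

## Representation

Peptides are written in the CHUCKLES convention: each residue is a SMILES
fragment in N-to-C order (amino nitrogen, alpha carbon, sidechain, carbonyl),
joined with `|`. Concatenating the residues and completing the C-terminus
yields the molecule's SMILES:

```
N[C@@H](C)C(=O) | NCC(=O) | N[C@@H](CO)C(=O)   ->   N[C@@H](C)C(=O)NCC(=O)N[C@@H](CO)C(=O)O
      Ala            Gly         Ser                      Ala-Gly-Ser
```

Macrocycles (head-to-tail, sidechain-to-tail, disulfide) carry a paired
`%nn` ring-closure label on the two attachment atoms. A head-to-tail cycle of
L alpha-residues has exactly 3L atoms in its main ring.

The infilling task masks residues with `?`; the model is trained on
source-target pairs where the target holds the masked residues in order:

```
source  N[C@@H](C)C(=O)|?|N[C@@H](CO)C(=O)      target  NCC(=O)
```

## What is in the box

- `pepfill.chuckles` — residues, peptides, masking, assembly, N-methylation,
  stereo flips, cyclization annotation, validity and canonicalization
  (RDKit-backed).
- `pepfill.building_blocks` — the 20 natural amino acids as verified
  L-templates, a loader for external SMILES libraries, and a seeded fragment
  grammar generating synthetic non-natural alpha-amino acids so everything
  runs offline.
- `pepfill.datagen` — the semi-synthetic corpus: four topologies
  (40/20/20/20), lengths 6-18, up to 30% non-natural content, stereo/N-methyl
  modifications, stratified 90/5/5 splits, masked training pairs, held-out
  evaluation sets.
- `pepfill.model` / `pepfill.training` — a recurrent encoder-decoder with
  attention (pure NumPy, in-package autodiff), multinomial sampling and beam
  search.
- `pepfill.scoring` — score transforms (sigmoid / reverse / double sigmoid),
  largest-ring-size, custom SMARTS alerts, solubility and permeability
  surrogates, weighted/geometric aggregation, Murcko-scaffold diversity
  filter.
- `pepfill.rl` — the augmented-likelihood RL loop plus drivers for the two
  study scenarios (ring-size steering; multi-parameter optimization of the
  cyclized Rev-binding peptide).
- `pepfill.metrics` — task completion, validity, peptide- and three-level
  amino-acid uniqueness, novelty profiling, topology-context validity.
- `pepfill` CLI — `datagen`, `train`, `sample`, `evaluate`, `rl`,
  `chuckles-to-smiles`, `smiles-report`, driven by validated JSON configs.

## Worked example

```python
import numpy as np
from pepfill import Peptide, Residue, Topology, annotate_cyclization
from pepfill import assemble_smiles, largest_ring_size, mask

ala = Residue("N[C@@H](C)C(=O)")
cyc = annotate_cyclization(Peptide(residues=(ala,) * 9), Topology.HEAD_TO_TAIL)
smiles = assemble_smiles(cyc)
print(largest_ring_size(smiles))
# 27        <- 9 residues x 3 backbone atoms: the macrolactam main ring

masked, target = mask(cyc, [1, 4])
print(masked.source)
# N%10[C@@H](C)C(=O)|?|N[C@@H](C)C(=O)|N[C@@H](C)C(=O)|?|...|N[C@@H](C)C%10(=O)
print(target)
# N[C@@H](C)C(=O)|N[C@@H](C)C(=O)
```

The printed `27` is the ring-size reward used by the topology RL scenario;
the masked string is exactly what the generator consumes. End-to-end from a
shell:

```bash
pepfill datagen --n 2000 --seed 1 --out run/data
pepfill train --pairs run/data/pairs_train.tsv --epochs 20 --out run/model
pepfill sample --checkpoint run/model/checkpoint \
    --source 'N[C@@H](C)C(=O)|?|NCC(=O)' --n 100 --seed 1 --out run/samples
pepfill evaluate --samples run/samples/samples.csv \
    --sources run/data/peptides.tsv --out run/eval
```

`run/eval/summary.json` reports, per topology and overall, the task-failure
rate, validity %, peptide uniqueness %, the three amino-acid uniqueness
levels (raw string >= isomeric >= canonical), the natural / non-natural /
novel split of proposed residues, and the fold-expansion over the 20 natural
amino acids.

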