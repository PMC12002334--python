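# Methods

## The design problem

A peptide lead is rarely redesigned from scratch. More often a few positions
are open to modification — residues outside the pharmacophore, or positions
where stability, solubility or permeability could be improved — while the rest
of the sequence must stay fixed. `pepfill` treats this as a *masked infilling*
problem over peptide chemistry: given a peptide with some residues replaced by
`?`, propose complete amino acids (natural or non-natural) for exactly those
positions, at the atomic level rather than from a fixed alphabet.

## Representation

Peptides are handled in the CHUCKLES convention: each residue is a SMILES
fragment written N-to-C (backbone amino nitrogen, alpha carbon, sidechain,
backbone carbonyl), so the plain concatenation of residue strings is a valid
peptide SMILES. Residues are joined with `|` to keep monomer boundaries
visible; a masked peptide replaces whole residues with `?`. For a linear
peptide the last carbonyl is completed to a carboxylic acid by appending `O`.

Macrocyclization is encoded with paired two-digit `%nn` ring-closure labels,
starting at `%10` so they can never collide with the single-digit ring labels
inside sidechains:

- **head-to-tail**: label on the N-terminal backbone nitrogen and on the
  C-terminal carbonyl carbon (the terminal acid is not completed — the ring
  consumes it);
- **sidechain-to-tail**: label on a sidechain primary amine and on the
  C-terminal carbonyl carbon, with the amine residue placed at least five
  residues from the C-terminus; here too the lactam consumes the terminal
  carbonyl, so no `O` is appended (appending one would give a five-valent
  carbon);
- **disulfide**: label on two sidechain sulfhydryl sulfurs; the terminal acid
  is completed as in the linear case.

A head-to-tail macrolactam of L alpha-residues therefore has exactly 3L atoms
in its main ring (N, C-alpha, C per residue); this relation is used as a
built-in oracle in the tests.

Validity of an assembled molecule means: separators removed, the string parses
and sanitizes under RDKit's default valence and aromaticity model. An unpaired
peptide-level ring label fails the parse, so an incomplete topology is
automatically an invalid molecule.

## Building blocks

The 20 proteinogenic amino acids ship as hand-written L-isomer templates,
each verified against RDKit's own residue builder (`MolFromSequence`) in the
test suite. Non-natural alpha-amino acids (NNAAs) come from either

1. a user file of SMILES (one per line), neutralized with RDKit's Uncharger,
   rewritten to in-chain CHUCKLES (re-rooted at the backbone nitrogen with the
   carboxyl written last), and deduplicated at the canonical isomeric level; or
2. the built-in **synthetic NNAA generator**: a deterministic fragment grammar
   that grafts sidechains (linkers x decorated benzenes, heteroaryls,
   cycloalkyls, branched/polar aliphatics) onto the `N[C@@H](R)C(=O)`
   L-scaffold, validates each candidate, excludes the naturals, and samples
   without replacement under a fixed seed. It stands in for a large virtual
   library of readily synthesizable NNAAs so that the package runs with no
   external download. It emulates the *coverage role* of such a library
   (diverse sidechain chemistry, thiol- and amine-bearing entries for
   cyclization anchors), not its synthesis-aware enumeration: real reagent
   catalogs are broader and biased differently, so passing tests say nothing
   about synthesizability of specific designs.

Two modifications are supported at the string level: backbone N-methylation
(insert `(C)` after the leading nitrogen; rejected for proline-like residues
whose backbone nitrogen is secondary) and stereo flips (invert the first
`@`/`@@` descriptor, i.e. the alpha carbon; an involution that leaves the
stereo-free constitution unchanged).

## Synthetic corpus

The corpus generator draws, per peptide:

| quantity | distribution | default |
|---|---|---|
| topology | fixed quota | 40% linear, 20% each cyclic class |
| length L | rounded truncated normal | mean 12, sd 3, clipped to [6, 18] |
| NNAA fraction | Beta(5,2) scaled | support [0, 0.3] |
| stereo-flip fraction | Beta(5,2) scaled | support [0, 0.25] |
| N-methyl fraction | Beta(5,2) scaled | support [0, 0.25] |

"Left-skewed" fractions are scaled Beta draws with mass near the upper bound
of the support; Beta(5,2) puts the mode at 0.8 of the range. Residues are
drawn without replacement from the natural and NNAA pools, shuffled (except
cyclization anchors), modified, annotated for topology, assembled and
validity-checked. Topology counts are quota-exact rather than multinomial so
composition tests are deterministic. Duplicates (canonical SMILES level) are
regenerated. The 90/5/5 split is stratified on (topology, length): every cell
receives the floor of its fractional allocation and the remainders are
assigned by largest fractional remainder subject to the exact global counts,
with ties broken by a seeded shuffle.

Training pairs mask ~30% of residues: the masked count is Binomial(L, 0.3)
truncated to at least 1, and the masked positions split between natural and
NNAA residues according to a natural-mask fraction drawn from Beta(3,2) scaled
to [0, 0.5] — mean exactly 0.3 — which biases masking toward NNAAs. Masked
residues move, in order, to the target string; `unmask(mask(p)) = p` exactly.

Two held-out evaluation sets are carved from the test split: a general
sampling-quality set stratified by length within topology, and a
topology-context set in which exactly one of the two cyclization anchors is
masked, so a sample is only valid if the generated residue closes the ring.
At desk scale both sets shrink proportionally, preserving their 10:1 ratio.

## Model

The conditional generator `f(x, y_<t)` is a compact recurrent
encoder-decoder, written against a minimal in-package reverse-mode autodiff
over NumPy (the package has no deep-learning framework dependency):

- embedding (64) shared between encoder and decoder;
- single-layer bidirectional GRU encoder (64 units per direction);
- GRU decoder (128 units) with multiplicative attention over the encoder
  states; the context vector feeds the output head only, which lets training
  run the recurrence first and compute attention for all steps in one batched
  matrix product;
- a remaining-mask-count embedding (16) appended to each decoder input. The
  count is a deterministic function of `(x, y_<t)` — the number of `?` in the
  source minus the separators generated so far — so the model remains a pure
  conditional distribution over next tokens; the feature removes the burden
  of counting separators from the recurrent state. Without it, a model at
  this scale frequently emits the wrong number of residues; with it, filler
  counts are nearly always correct and capacity goes into residue chemistry;
- an open-ring-label flag embedding (8), again a deterministic function of
  `(x, y_<t)`: the parity of peptide-level `%nn` tokens seen so far in source
  plus prefix. It tells the decoder whether a macrocycle closure is still
  owed, which markedly reduces unpaired-ring-label failures on cyclic
  sources.

Tokenization is maximal-munch SMILES: bracket atoms, `Cl`/`Br`, `%nn` labels,
`?` and `|` are single tokens. Sequences are hard-capped at 500 tokens.
Training minimizes the per-token negative log-likelihood with teacher forcing
(Adam, inverse-square-root warm-up, gradient-norm clipping at 5, batches
reshuffled per epoch, early selection at the best validation loss). All
gradients are verified against finite differences in the test suite.

Sampling is either multinomial (temperature 1.0, token-by-token until the end
token) or length-normalized beam search with string-level deduplication. Both
return the fillers (the generated string split on `|`) with per-sequence NLL.
A filler-count mismatch is recorded as a task failure, never raised.

## Scoring and reinforcement learning

Scoring components map an assembled peptide to a raw value and then through a
transform onto [0, 1]:

- `sigmoid` / `reverse_sigmoid` on a window [low, high]: midpoint at the
  window center, steepness k = 10/(high-low) unless overridden;
- `double_sigmoid` on [0, high]: the product of a rising edge fixed at ring
  size 12 (the macrocycle definition) and a falling edge at `high`, each with
  width (high-low)/10 — a plateau that rewards macrocycles up to the
  head-to-tail ring size and penalizes anything larger or smaller.

Bundled raw scorers: largest SSSR ring size; binary custom alerts over a
user-replaceable SMARTS list (default: acyl halide, aldehyde, isocyanate,
enone, nitro, polysulfide); Wildman-Crippen logP; a **solubility surrogate**
(rescaled negated logP, a deterministic stand-in exposing the same component
interface as an external intrinsic-solubility predictor); and a
**permeability surrogate** (a fixed logistic over logP, H-bond donors and
largest ring that returns a permeable-class probability, standing in for a
trained classifier). Both surrogates are deliberately simple, deterministic
functions so that multi-parameter runs are reproducible offline; any callable
scorer can be registered in their place. Scores aggregate by weighted
arithmetic or geometric mean (a zero component zeroes a geometric mean), and
invalid molecules score 0 before any transform so they can never outrank
valid designs.

The diversity filter buckets peptides scoring above 0.4; after 25 members a
bucket closes and later arrivals score 0. The bucket key has two modes:
*identical molecule* (canonical SMILES), used in topology steering where only
exact repetition should be penalized, and *Murcko scaffold*, used in the
multi-parameter scenario to force scaffold-level novelty. The distinction
matters at desk scale: a scaffold-keyed filter under a ring-size objective
saturates the common acyclic buckets within a few steps and then effectively
rewards any novel ring system, which inverts a ring-minimization objective.

RL follows the squared augmented-likelihood scheme: the agent starts as a
copy of the prior, samples 32 filler sets per step, and minimizes
`mean((log P_prior + sigma * score - log P_agent)^2)` with Adam (lr 1e-4,
sigma 120 by default). Two drivers reproduce the study scenarios: ring-size
steering of a topology-free 9-mer of alanine with positions 1, 2, 4 and 9
masked (maximize / macrocycle-window / minimize transforms, triplicate
seeds), and a multi-parameter run on the head-to-tail cyclized Rev-binding
peptide YPAASYR extended with two glycines, with the non-pharmacophore
residues (the alanines and glycines) masked; this input is a synthetic
reconstruction from the sequence, not a transcribed structure. The
C-terminal glycine carries the ring label and sits among the masked
positions, so the agent must regenerate the closure.

## Problem sizes

The package defaults are desk-scale choices: a 20 000-peptide corpus for
production-style runs; the test suite trains its shared prior on a
1500-peptide corpus with three masked pairs per peptide (~4050 training
pairs, 14 epochs, ~0.6 M parameters, float32) and evaluates on the held-out
masked sets; RL runs use 100 steps, batch 32, sigma 120, lr 1e-4, in
triplicate. Sampling quality grows steadily with corpus size under this
recipe (roughly 27% valid at 540 pairs, 77% at 1800, 84% at 5400, and 91% at
16 200 pairs with 20 epochs in our scaling runs), so the desk-scale prior
sits below the asymptote of the approach rather than at it. Full-scale behavior
(million-peptide corpus, ~100 M-token training) is supported by the same
code paths but is not exercised by the tests; the acceptance floors
(validity >= 90%, correct filler counts >= 95% on held-out sources) are the
desk-scale substitutes for full-scale sampling quality, which is higher.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` objects seeded from
  config; equal configs give byte-identical corpora and beam results.
- Probability vectors are computed in float64; the decoder softmax is
  normalized to 1 within 1e-5 (asserted in tests).
- Masked softmax assigns exactly zero weight to padding; an all-padded row
  would divide by zero and is guarded to a uniform-zero row.
- `mask` with empty or duplicate positions raises; `map_fillers` with a count
  mismatch records a task failure instead of raising, because that outcome is
  a metric, not an error.
- A generated filler that does not even start with a backbone nitrogen makes
  the completed peptide unparseable; it flows to the metrics as invalid.
- Beta distributions with a degenerate range (low == high) return the bound.
- The NNAA grammar raises a capacity error when asked for more residues than
  it can enumerate, rather than silently repeating.

## Known limitations

- The corpus is semi-synthetic: generated peptides follow the stated
  distributions but carry no biological signal; models trained on it learn
  chemistry and topology, not activity.
- The solubility and permeability surrogates are monotone descriptor
  functions; they order designs plausibly but are not predictive models, and
  conclusions about absolute solubility/permeability of designs require
  attaching real scorers through the same interface.
- The recurrent model is much smaller than a production transformer; its
  novel-residue proposals are correspondingly more conservative at desk
  scale.
- Stereo flips act on the alpha carbon only; residues with additional
  sidechain stereocenters keep those fixed (diastereomers, not enantiomers).
- No conformer generation: ring-size scoring is topological, not geometric.
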