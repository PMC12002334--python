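"""Peptide scoring components for reinforcement learning.

Each component maps a completed peptide (full-molecule SMILES) to a raw value
and pushes it through a score transform onto [0, 1].  Components aggregate by
weighted arithmetic or geometric mean; a Murcko-scaffold diversity filter
zeroes the reward of over-visited scaffolds.  Invalid molecules always score
zero, so they can never outrank valid designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Lipinski
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chuckles import largest_ring_size as _largest_ring_size

MACROCYCLE_MIN_RING = 12  # a macrocycle is a ring of >= 12 atoms


class TransformShape(str, Enum):
    SIGMOID = "sigmoid"
    REVERSE_SIGMOID = "reverse_sigmoid"
    DOUBLE_SIGMOID = "double_sigmoid"
    NONE = "none"


@dataclass(frozen=True)
class ScoreTransform:
    """Maps a raw component value onto [0, 1].

    ``sigmoid`` rises from ~0 at ``low`` to ~1 at ``high`` with midpoint at
    the window center; ``reverse_sigmoid`` is its mirror.  ``double_sigmoid``
    rewards a plateau: a rising edge at the macrocycle floor (ring size 12)
    and a falling edge at ``high``, each with width (high-low)/10.
    """

    shape: TransformShape = TransformShape.SIGMOID
    low: float = 0.0
    high: float = 1.0
    k: float | None = None  # steepness; default 10/(high-low)
    rising_center: float | None = None  # double sigmoid only

    def __post_init__(self):
        if self.shape != TransformShape.NONE and self.low >= self.high:
            raise ValueError(f"low {self.low} must be < high {self.high}")

    def __call__(self, value: float) -> float:
        lo, hi = self.low, self.high
        if self.shape == TransformShape.NONE:
            return min(1.0, max(0.0, value))
        k = self.k if self.k is not None else 10.0 / (hi - lo)
        if self.shape == TransformShape.SIGMOID:
            return _sigmoid(value, (lo + hi) / 2.0, k)
        if self.shape == TransformShape.REVERSE_SIGMOID:
            return 1.0 - _sigmoid(value, (lo + hi) / 2.0, k)
        # double sigmoid: product of a rising and a falling edge
        edge_k = 10.0 / ((hi - lo) / 10.0)
        rise_at = (
            self.rising_center if self.rising_center is not None else MACROCYCLE_MIN_RING
        )
        return _sigmoid(value, rise_at, edge_k) * (1.0 - _sigmoid(value, hi, edge_k))


def _sigmoid(v: float, center: float, k: float) -> float:
    z = k * (v - center)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-min(z, 500)))
    return math.exp(max(z, -500)) / (1.0 + math.exp(max(z, -500)))


def transform(value: float, t: ScoreTransform) -> float:
    return t(value)


@dataclass
class ScoringComponent:
    """Named raw scorer plus transform and aggregation weight."""

    name: str
    scorer: Callable[[str], float]
    transform: ScoreTransform = field(
        default_factory=lambda: ScoreTransform(TransformShape.NONE)
    )
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")

    def __call__(self, smiles: str) -> tuple[float, float]:
        """Returns (raw, transformed); a scorer exception scores 0."""
        try:
            raw = float(self.scorer(smiles))
        except Exception:
            return float("nan"), 0.0
        return raw, self.transform(raw)


# -- raw scorers --------------------------------------------------------------


def largest_ring_size(smiles: str) -> int:
    return _largest_ring_size(smiles)


def make_custom_alerts(patterns: Sequence[str]) -> Callable[[str], float]:
    """Binary alert scorer: 0 when any SMARTS pattern matches, else 1."""
    queries = []
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ValueError(f"bad SMARTS pattern: {p!r}")
        queries.append(q)

    def score(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return 0.0
        return 0.0 if any(mol.HasSubstructMatch(q) for q in queries) else 1.0

    return score


#: reactive / toxicity motifs penalized by default; fully user-replaceable
DEFAULT_ALERT_SMARTS = (
    "[CX3](=O)[F,Cl,Br,I]",        # acyl halide
    "[CX3H1](=O)[#6]",             # aldehyde
    "N=C=O",                       # isocyanate
    "[CX3]=[CX3][CX3]=O",          # Michael acceptor (enone)
    "[N+](=O)[O-]",                # nitro
    "[SX2][SX2][SX2]",             # polysulfide
)


def lipophilicity(smiles: str) -> float:
    """Wildman-Crippen logP of the assembled peptide."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("unparseable molecule")
    return Crippen.MolLogP(mol)


def solubility_surrogate(smiles: str) -> float:
    """Deterministic stand-in for an intrinsic-solubility predictor.

    Rescaled negated Crippen logP: hydrophilic peptides score high.  Output is
    a raw value roughly on [0, 1] before the component's sigmoid transform.
    """
    logp = lipophilicity(smiles)
    return 1.0 / (1.0 + math.exp(0.35 * logp))


def permeability_surrogate(smiles: str) -> float:
    """Deterministic descriptor-based logistic stand-in for a passive
    membrane-permeability classifier; returns the permeable-class probability.

    Cyclic, moderately lipophilic peptides with few H-bond donors score high,
    the qualitative behavior reported for PAMPA assays of macrocycles.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return 0.0
    logp = Crippen.MolLogP(mol)
    hbd = Lipinski.NumHDonors(mol)
    ring = _largest_ring_size(smiles)
    z = 0.35 * logp - 0.45 * hbd + 0.25 * min(ring, 40) - 1.5
    return 1.0 / (1.0 + math.exp(-z))


# -- aggregation --------------------------------------------------------------


def aggregate(
    scores: Sequence[float],
    weights: Sequence[float],
    mode: str = "geometric_mean",
) -> float:
    """Weighted arithmetic or geometric mean of component scores in [0,1]."""
    if len(scores) != len(weights):
        raise ValueError("scores and weights differ in length")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("at least one positive weight required")
    if mode == "weighted_average":
        return float(sum(s * w for s, w in zip(scores, weights)) / wsum)
    if mode == "geometric_mean":
        if any(s <= 0.0 for s in scores):
            return 0.0
        return float(
            math.exp(sum(w * math.log(s) for s, w in zip(scores, weights)) / wsum)
        )
    raise ValueError(f"unknown aggregation mode: {mode!r}")


# -- diversity filter ---------------------------------------------------------


def murcko_scaffold(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ""
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


@dataclass
class DiversityFilter:
    """Bucket memory that zeroes repeated high-scoring designs.

    Peptides scoring above ``threshold`` enter a bucket keyed either by their
    Murcko scaffold (``key="murcko"``, for multi-parameter optimization) or by
    the identical molecule (``key="identical"``, canonical SMILES — used in
    topology steering, where only exact repetition is penalized).  Once a
    bucket holds ``bucket_size`` members, later arrivals score 0.
    """

    threshold: float = 0.4
    bucket_size: int = 25
    key: str = "murcko"
    memory: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.key not in ("murcko", "identical"):
            raise ValueError(f"unknown diversity-filter key: {self.key!r}")

    def _bucket(self, smiles: str) -> str:
        if self.key == "identical":
            mol = Chem.MolFromSmiles(smiles)
            return Chem.MolToSmiles(mol) if mol is not None else ""
        return murcko_scaffold(smiles)

    def __call__(self, smiles: str, score: float) -> float:
        if score < self.threshold:
            return score
        bucket = self._bucket(smiles)
        count = self.memory.get(bucket, 0)
        self.memory[bucket] = count + 1
        return 0.0 if count >= self.bucket_size else score


# -- scoring function ---------------------------------------------------------


@dataclass
class ScoringFunction:
    """Components + aggregation mode + optional diversity filter."""

    components: list[ScoringComponent]
    mode: str = "geometric_mean"
    diversity_filter: DiversityFilter | None = None

    def __call__(self, smiles: str | None) -> tuple[float, dict[str, tuple[float, float]]]:
        """Score one assembled peptide; None (unassemblable) scores 0."""
        if smiles is None or Chem.MolFromSmiles(smiles) is None:
            detail = {c.name: (float("nan"), 0.0) for c in self.components}
            return 0.0, detail
        detail = {c.name: c(smiles) for c in self.components}
        score = aggregate(
            [detail[c.name][1] for c in self.components],
            [c.weight for c in self.components],
            self.mode,
        )
        if self.diversity_filter is not None:
            score = self.diversity_filter(smiles, score)
        return score, detail
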