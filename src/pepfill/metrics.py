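"""Evaluation suite for the infilling model.

Per masked source peptide: task completion (correct filler count), validity
of the completed molecule, peptide-level uniqueness, amino-acid uniqueness at
three levels (raw string, canonical isomeric SMILES, canonical SMILES without
stereo), and the novelty profile of the proposed amino acids against the
building-block library.

Uniqueness percentages are computed over valid, task-complete samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .building_blocks import BuildingBlockLibrary, monomer_key
from .chuckles import (
    ChucklesError,
    MaskedPeptide,
    canonicalize,
    is_valid,
    map_fillers,
    try_assemble,
)

N_NATURAL = 20


@dataclass
class SourceReport:
    """Metrics for the sample set of one masked source peptide."""

    topology: str
    n_samples: int
    n_task_failures: int
    n_valid: int
    n_unique_peptides: int
    aa_unique_string: int
    aa_unique_isomeric: int
    aa_unique_canonical: int
    n_invalid_residues: int
    novelty: dict[str, int]

    @property
    def task_failure_rate(self) -> float:
        return self.n_task_failures / self.n_samples if self.n_samples else 0.0

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_samples if self.n_samples else 0.0

    @property
    def peptide_uniqueness(self) -> float:
        return self.n_unique_peptides / self.n_valid if self.n_valid else 0.0


def task_completion(samples: Sequence[Sequence[str]], masked: MaskedPeptide) -> int:
    """Count samples whose filler count differs from the mask count."""
    want = len(masked.masked_positions)
    return sum(1 for fillers in samples if len(fillers) != want)


def peptide_uniqueness(smiles_list: Sequence[str]) -> int:
    """Distinct canonical-with-stereo molecules among completed peptides."""
    return len({canonicalize(s, keep_stereo=True) for s in smiles_list})


def aa_uniqueness(residues: Sequence[str]) -> tuple[int, int, int, int]:
    """(string-level, isomeric-level, canonical-level, invalid) counts.

    The three levels are monotonically non-increasing: raw strings >= unique
    molecules with stereo >= unique constitutions.
    """
    strings: set[str] = set()
    isomeric: set[str] = set()
    canonical: set[str] = set()
    invalid = 0
    for r in residues:
        try:
            iso = monomer_key(r, keep_stereo=True)
        except (ChucklesError, ValueError):
            invalid += 1
            continue
        strings.add(r)
        isomeric.add(iso)
        canonical.add(monomer_key(r, keep_stereo=False))
    return len(strings), len(isomeric), len(canonical), invalid


def novelty_profile(
    unique_residues: Sequence[str], library: BuildingBlockLibrary
) -> dict[str, int]:
    """Partition unique amino acids into natural / non-natural / novel."""
    counts = {"natural": 0, "non_natural": 0, "novel": 0}
    for r in unique_residues:
        counts[library.classify(r)] += 1
    return counts


def fold_expansion(aa_unique_count: int) -> float:
    """Unique amino acids relative to the 20 natural ones."""
    return aa_unique_count / N_NATURAL


def evaluate_source(
    masked: MaskedPeptide,
    samples: Sequence[Sequence[str]],
    library: BuildingBlockLibrary,
) -> SourceReport:
    """Full metric set for the samples of one masked source."""
    n_fail = task_completion(samples, masked)
    completed: list[str] = []
    residues: list[str] = []
    for fillers in samples:
        outcome = map_fillers(masked, fillers)
        if outcome.task_failure:
            continue
        smiles = try_assemble(outcome.peptide)
        if smiles is not None and is_valid(smiles):
            completed.append(smiles)
            residues.extend(fillers)
    s_lvl, i_lvl, c_lvl, bad = aa_uniqueness(residues)

    iso_unique: dict[str, str] = {}
    for r in residues:
        try:
            iso_unique.setdefault(monomer_key(r, keep_stereo=True), r)
        except (ChucklesError, ValueError):
            continue
    novelty = novelty_profile(list(iso_unique.values()), library)

    return SourceReport(
        topology=masked.topology.value,
        n_samples=len(samples),
        n_task_failures=n_fail,
        n_valid=len(completed),
        n_unique_peptides=peptide_uniqueness(completed) if completed else 0,
        aa_unique_string=s_lvl,
        aa_unique_isomeric=i_lvl,
        aa_unique_canonical=c_lvl,
        n_invalid_residues=bad,
        novelty=novelty,
    )


def topology_context_validity(
    reports: Sequence[SourceReport],
) -> dict[str, tuple[float, float]]:
    """Mean +/- sd validity per topology.

    A sample from a source with an open ring label only counts as valid when
    the generated fillers close the topology and the molecule sanitizes,
    which :func:`evaluate_source` enforces via assembly + validity.
    """
    out: dict[str, tuple[float, float]] = {}
    for topo in sorted({r.topology for r in reports}):
        vals = [100.0 * r.validity for r in reports if r.topology == topo]
        out[topo] = (float(np.mean(vals)), float(np.std(vals)))
    vals = [100.0 * r.validity for r in reports]
    out["all"] = (float(np.mean(vals)), float(np.std(vals)))
    return out


@dataclass
class EvalReport:
    """Aggregate over source peptides: means +/- sd, overall and per topology."""

    per_source: list[SourceReport] = field(default_factory=list)

    def _agg(self, values: list[float]) -> tuple[float, float]:
        return (float(np.mean(values)), float(np.std(values))) if values else (0.0, 0.0)

    def summary(self) -> dict:
        groups: dict[str, list[SourceReport]] = {"all": list(self.per_source)}
        for r in self.per_source:
            groups.setdefault(r.topology, []).append(r)
        out = {}
        for name, rows in groups.items():
            out[name] = {
                "n_sources": len(rows),
                "task_failure_pct": self._agg([100 * r.task_failure_rate for r in rows]),
                "validity_pct": self._agg([100 * r.validity for r in rows]),
                "peptide_uniqueness_pct": self._agg(
                    [100 * r.peptide_uniqueness for r in rows]
                ),
                "aa_unique_string": self._agg([r.aa_unique_string for r in rows]),
                "aa_unique_isomeric": self._agg([r.aa_unique_isomeric for r in rows]),
                "aa_unique_canonical": self._agg([r.aa_unique_canonical for r in rows]),
                "fold_expansion": self._agg(
                    [fold_expansion(r.aa_unique_canonical) for r in rows]
                ),
                "novelty_natural": self._agg([r.novelty["natural"] for r in rows]),
                "novelty_non_natural": self._agg(
                    [r.novelty["non_natural"] for r in rows]
                ),
                "novelty_novel": self._agg([r.novelty["novel"] for r in rows]),
            }
        return out
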