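"""Amino-acid building-block libraries.

The 20 proteinogenic amino acids ship as verified L-isomer CHUCKLES templates.
Non-natural alpha-amino acids (NNAAs) either come from a user file of SMILES
(e.g. a virtual synthesis library) or from the built-in fragment-grammar
generator, which grafts decorated alkyl/aryl/heteroaryl sidechains onto the
L-alpha-amino-acid scaffold ``N[C@@H](R)C(=O)``.  The generator is the default
so the package runs with no external download.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chuckles import Residue, canonicalize, is_valid

logger = logging.getLogger(__name__)

Category = Literal["natural", "non_natural", "novel"]


class EmptyLibraryError(ValueError):
    pass


class CapacityError(ValueError):
    pass


#: in-chain CHUCKLES templates for the proteinogenic amino acids (L-isomers,
#: glycine achiral); verified to parse to the reference stereochemistry
NATURAL_CHUCKLES: dict[str, str] = {
    "G": "NCC(=O)",
    "A": "N[C@@H](C)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@H](O)C)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "R": "N[C@@H](CCCNC(N)=N)C(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
}

_AA_BACKBONE = Chem.MolFromSmarts("[NX3;H1,H2][CX4;H1,H2][CX3](=[OX1])[OX2H1]")
_UNCHARGER = rdMolStandardize.Uncharger()


_PEPTIDE_LABEL_RE = re.compile(r"%\d{2}")


def monomer_key(chuckles_or_smiles: str, keep_stereo: bool = True) -> str:
    """Canonical free-monomer SMILES used for library membership tests.

    Peptide-level ring labels are stripped: a cyclization anchor is still the
    same building block.
    """
    s = _PEPTIDE_LABEL_RE.sub("", chuckles_or_smiles)
    if s.endswith("C(=O)"):
        s = s + "O"
    return canonicalize(s, keep_stereo=keep_stereo)


def is_alpha_amino_acid(smiles: str) -> bool:
    """Backbone N-Calpha-C(=O)OH present in the free-monomer form."""
    s = smiles + "O" if smiles.endswith("C(=O)") else smiles
    mol = Chem.MolFromSmiles(s)
    return mol is not None and mol.HasSubstructMatch(_AA_BACKBONE)


def neutralize(mol: Chem.Mol) -> Chem.Mol | None:
    mol = _UNCHARGER.uncharge(mol)
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return None
    return mol


def to_chuckles(smiles: str) -> str | None:
    """Rewrite a free alpha-amino-acid SMILES as an in-chain CHUCKLES fragment.

    The molecule is re-rooted at the backbone nitrogen and atom-reordered so
    the carboxyl is written last; the terminal hydroxyl is then dropped,
    leaving the residue ending in ``C(=O)``.  Returns None when the input is
    not a neutralizable alpha-amino acid.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = neutralize(mol)
    if mol is None:
        return None
    matches = mol.GetSubstructMatches(_AA_BACKBONE)
    if not matches:
        return None
    n, ca, cc, od, oh = matches[0]
    backbone = {n, ca, cc, od, oh}
    rest = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in backbone]
    # two traversal orders: sidechain-in-branch (usual) and ring-first
    # (proline-like, where N and Calpha share a ring)
    for order in ([n, ca] + rest + [cc, od, oh], [n] + rest + [ca, cc, od, oh]):
        reordered = Chem.RenumberAtoms(mol, order)
        s = Chem.MolToSmiles(reordered, rootedAtAtom=0, canonical=False)
        if s.endswith("C(=O)O") and s.startswith("N"):
            chk = s[:-1]
            try:
                if monomer_key(chk) == Chem.MolToSmiles(mol):
                    return chk
            except ValueError:
                continue
    return None


@dataclass
class BuildingBlockLibrary:
    """Natural + non-natural residue sets with canonical-SMILES membership index."""

    natural: list[Residue]
    non_natural: list[Residue] = field(default_factory=list)
    index: dict[str, Category] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {}
            for res in self.natural:
                self.index[monomer_key(res.chuckles)] = "natural"
            for res in self.non_natural:
                self.index.setdefault(monomer_key(res.chuckles), "non_natural")

    def classify(self, residue: str) -> Category:
        """Place a residue (CHUCKLES or free SMILES) into natural / non_natural / novel."""
        key = monomer_key(residue)
        return self.index.get(key, "novel")

    def residues(self, category: Category) -> list[Residue]:
        return self.natural if category == "natural" else self.non_natural


def natural_library() -> list[Residue]:
    return [Residue(c) for c in NATURAL_CHUCKLES.values()]


# -- synthetic NNAA generator -------------------------------------------------

_DECORATIONS = ["F", "Cl", "Br", "C", "O", "OC", "C(F)(F)F", "C#N", "CC", "OCC"]
_HETERO_CORES = [
    "c1ccncc1", "c1cccnc1", "c1ccoc1", "c1ccsc1", "c1cnccn1",
    "c1cc2ccccc2cc1" if False else "c1ccc2ccccc2c1",
    "c1cn[nH]c1", "c1csc(C)n1",
]
_CYCLOALKYL = ["C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCOCC1", "C1CCNCC1"]
_ALIPHATIC = [
    "CCCC", "CCCCC", "C(C)CC", "CCC(C)C", "C(C)(C)C", "CC(C)(C)C",
    "CCO", "CCOC", "COC", "CCS", "CCCN", "CCN", "CCC(N)=O", "CCCO",
    "CC(F)(F)F", "CCSC", "CCCS", "CCCCCN",
]
_LINKERS = ["C", "CC"]


def _sidechain_grammar() -> list[str]:
    """Deterministic enumeration of sidechain fragments, attachment-first."""
    sidechains: list[str] = []
    # benzene with 0-2 decorations at ortho/meta/para slots
    slot_patterns = {
        (): "c1ccccc1",
        (2,): "c1c({0})cccc1",
        (3,): "c1cc({0})ccc1",
        (4,): "c1ccc({0})cc1",
        (2, 4): "c1c({0})cc({1})cc1",
        (3, 5): "c1cc({0})cc({1})c1",
        (2, 5): "c1c({0})ccc({1})c1",
    }
    for linker in _LINKERS:
        for slots, pat in slot_patterns.items():
            if len(slots) == 0:
                sidechains.append(linker + pat)
            elif len(slots) == 1:
                for d in _DECORATIONS:
                    sidechains.append(linker + pat.format(d))
            else:
                for d1 in _DECORATIONS:
                    for d2 in _DECORATIONS:
                        sidechains.append(linker + pat.format(d1, d2))
        for core in _HETERO_CORES + _CYCLOALKYL:
            sidechains.append(linker + core)
    sidechains.extend(_ALIPHATIC)
    return sidechains


def generate_synthetic_nnaa(n: int, seed: int = 0) -> list[Residue]:
    """Draw ``n`` distinct non-natural L-alpha-amino-acid residues.

    Residues are sampled without replacement from the fragment grammar,
    validated with RDKit, and checked for novelty against the natural set.
    Fixed seed gives an identical list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    natural_keys = {monomer_key(c) for c in NATURAL_CHUCKLES.values()}
    candidates = _sidechain_grammar()
    rng = np.random.default_rng(seed)
    rng.shuffle(candidates)

    out: list[Residue] = []
    seen: set[str] = set()
    for sc in candidates:
        chk = f"N[C@@H]({sc})C(=O)"
        if not is_valid(chk + "O"):
            continue
        key = monomer_key(chk)
        if key in natural_keys or key in seen or not is_alpha_amino_acid(chk):
            continue
        seen.add(key)
        out.append(Residue(chk))
        if len(out) == n:
            return out
    raise CapacityError(
        f"grammar capacity exhausted: produced {len(out)} of {n} requested NNAAs"
    )


def load_library(
    path: str | Path,
    category: Category = "non_natural",
    natural: Sequence[Residue] | None = None,
) -> BuildingBlockLibrary:
    """Read a one-structure-per-line SMILES/CHUCKLES file into a library.

    Entries are neutralized, rewritten to in-chain CHUCKLES, and deduplicated
    at the canonical-isomeric level.  Unusable lines are logged and skipped.
    """
    path = Path(path)
    entries: list[Residue] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip().split(",")[0].split("\t")[0]
        if not line or line.startswith("#") or line == "smiles":
            continue
        chk = line if line.endswith("C(=O)") and is_valid(line + "O") else to_chuckles(line)
        if chk is None:
            logger.warning("%s:%d: skipped unusable entry %r", path, lineno, line)
            continue
        key = monomer_key(chk)
        if key in seen:
            continue
        seen.add(key)
        entries.append(Residue(chk))
    if not entries:
        raise EmptyLibraryError(f"no usable entries in {path}")

    nat = list(natural) if natural is not None else natural_library()
    if category == "natural":
        return BuildingBlockLibrary(natural=entries)
    nat_keys = {monomer_key(r.chuckles) for r in nat}
    nnaa = [r for r in entries if monomer_key(r.chuckles) not in nat_keys]
    return BuildingBlockLibrary(natural=nat, non_natural=nnaa)


def default_library(n_nnaa: int = 200, seed: int = 0) -> BuildingBlockLibrary:
    """Naturals plus a reproducible synthetic NNAA set."""
    return BuildingBlockLibrary(
        natural=natural_library(),
        non_natural=generate_synthetic_nnaa(n_nnaa, seed=seed),
    )
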