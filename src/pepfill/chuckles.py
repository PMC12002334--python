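"""CHUCKLES monomer-level peptide representation.

CHUCKLES writes each amino acid as a SMILES fragment in N-to-C order: the
backbone amino nitrogen first, then the alpha carbon, the sidechain, and the
backbone carbonyl.  Because every residue ends in ``C(=O)`` and starts with
``N``, plain string concatenation of residues yields a chemically correct
peptide SMILES; the residue boundaries are kept visible by joining with ``|``.

Peptide-level macrocyclization (head-to-tail, sidechain-to-tail, disulfide) is
encoded with two-digit ``%nn`` ring-closure labels placed on the two attachment
atoms, so they cannot collide with the single-digit ring labels used inside
sidechain rings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

MASK_TOKEN = "?"
SEPARATOR = "|"
#: first peptide-level ring label; single digits are reserved for sidechains
PEPTIDE_RING_LABEL_START = 10

_RING_LABEL_RE = re.compile(r"%\d{2}")
_LEADING_N_RE = re.compile(r"^N(?P<label>%\d{2})?(?P<methyl>\(C\))?")


class Topology(str, Enum):
    LINEAR = "linear"
    HEAD_TO_TAIL = "head_to_tail"
    SIDECHAIN_TO_TAIL = "sidechain_to_tail"
    DISULFIDE = "disulfide"


CYCLIC_TOPOLOGIES = (
    Topology.HEAD_TO_TAIL,
    Topology.SIDECHAIN_TO_TAIL,
    Topology.DISULFIDE,
)


class ChucklesError(ValueError):
    """Base class for representation-level failures."""


class MalformedTopologyError(ChucklesError):
    """Unpaired peptide-level ring label at assembly time."""


class MaskedInputError(ChucklesError):
    """A '?' mask reached an operation that needs concrete residues."""


class IneligibleResidueError(ChucklesError):
    """Residue lacks the functional group or eligibility for a modification."""


class TopologyConstraintError(ChucklesError):
    """Topology precondition violated (e.g. cycle span below the floor)."""


@dataclass(frozen=True)
class Residue:
    """One amino acid written as an in-chain CHUCKLES fragment."""

    chuckles: str
    n_methylated: bool = False
    stereo_flipped: bool = False
    ring_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not _LEADING_N_RE.match(self.chuckles):
            raise ChucklesError(
                f"residue must start with a backbone nitrogen token: {self.chuckles!r}"
            )

    @property
    def is_proline_like(self) -> bool:
        """True when the backbone nitrogen is secondary (sits in a sidechain ring)."""
        m = _LEADING_N_RE.match(self.chuckles)
        rest = self.chuckles[m.end():]
        return rest[:1].isdigit()

    def peptide_ring_labels(self) -> tuple[int, ...]:
        return tuple(int(s[1:]) for s in _RING_LABEL_RE.findall(self.chuckles))


@dataclass(frozen=True)
class Peptide:
    """Ordered residues plus a topology label.

    ``rho`` is the joined CHUCKLES string with ``|`` separators; it is derived,
    never stored independently.
    """

    residues: tuple[Residue, ...]
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ChucklesError("peptide needs at least one residue")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def rho(self) -> str:
        return SEPARATOR.join(r.chuckles for r in self.residues)


@dataclass(frozen=True)
class MaskedPeptide:
    """A peptide string with ``?`` at masked residue slots."""

    source: str
    masked_positions: tuple[int, ...]
    parent: Peptide | None = None
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        n_marks = self.source.split(SEPARATOR).count(MASK_TOKEN)
        if n_marks != len(self.masked_positions):
            raise ChucklesError(
                f"{n_marks} mask tokens but {len(self.masked_positions)} positions"
            )


def _terminal_needs_acid(topology: Topology) -> bool:
    # head-to-tail and sidechain-to-tail rings consume the C-terminal carbonyl
    return topology in (Topology.LINEAR, Topology.DISULFIDE)


def assemble_smiles(peptide: Peptide) -> str:
    """Concatenate residue CHUCKLES into the full-molecule SMILES.

    Linear and disulfide peptides get the C-terminal carboxylic acid completed
    with a trailing ``O``; head-to-tail and sidechain-to-tail macrolactams end
    at the ring-closing carbonyl.
    """
    labels: dict[int, int] = {}
    for res in peptide.residues:
        if MASK_TOKEN in res.chuckles:
            raise MaskedInputError("cannot assemble a peptide containing '?' masks")
        for lab in res.peptide_ring_labels():
            labels[lab] = labels.get(lab, 0) + 1
    unpaired = [lab for lab, cnt in labels.items() if cnt != 2]
    if unpaired:
        raise MalformedTopologyError(f"unpaired peptide-level ring labels: {unpaired}")
    if peptide.topology in CYCLIC_TOPOLOGIES and not labels:
        raise MalformedTopologyError(
            f"{peptide.topology.value} peptide carries no peptide-level ring labels"
        )
    smiles = "".join(res.chuckles for res in peptide.residues)
    if _terminal_needs_acid(peptide.topology):
        smiles += "O"
    return smiles


def try_assemble(peptide: Peptide | None) -> str | None:
    """assemble_smiles that maps malformed topologies to None instead of
    raising; generated peptides may legitimately leave a ring label unpaired
    and are then simply invalid."""
    if peptide is None:
        return None
    try:
        return assemble_smiles(peptide)
    except ChucklesError:
        return None


def mask(peptide: Peptide, positions: Sequence[int]) -> tuple[MaskedPeptide, str]:
    """Replace residues at ``positions`` with ``?`` and return (source, target).

    The target string is the masked residues joined with ``|`` in ascending
    position order, so ``map_fillers`` on the pair is the identity.
    """
    if len(positions) == 0:
        raise ChucklesError("mask needs at least one position")
    pos = sorted(set(positions))
    if len(pos) != len(positions):
        raise ChucklesError("mask positions must be distinct")
    if pos[0] < 0 or pos[-1] >= len(peptide):
        raise IndexError(f"mask position out of range for {len(peptide)}-mer: {pos}")
    slots = [r.chuckles for r in peptide.residues]
    target = SEPARATOR.join(slots[i] for i in pos)
    for i in pos:
        slots[i] = MASK_TOKEN
    source = SEPARATOR.join(slots)
    return (
        MaskedPeptide(
            source=source,
            masked_positions=tuple(pos),
            parent=peptide,
            topology=peptide.topology,
        ),
        target,
    )


@dataclass(frozen=True)
class FillOutcome:
    """Result of mapping generated fillers onto a masked source.

    A filler-count mismatch is a recorded task failure, not an exception: the
    generative model is free to emit the wrong number of residues and the
    evaluation counts those cases.
    """

    peptide: Peptide | None
    task_failure: bool
    n_fillers: int


def map_fillers(masked: MaskedPeptide, fillers: Sequence[str]) -> FillOutcome:
    """Substitute filler residue strings into the ``?`` slots in order."""
    if len(fillers) != len(masked.masked_positions):
        return FillOutcome(peptide=None, task_failure=True, n_fillers=len(fillers))
    slots = masked.source.split(SEPARATOR)
    it = iter(fillers)
    out: list[Residue] = []
    try:
        for s in slots:
            out.append(Residue(next(it) if s == MASK_TOKEN else s))
    except ChucklesError:
        # filler does not even start with a nitrogen token: chemically a
        # failure, but count-wise the task was completed
        return FillOutcome(peptide=None, task_failure=False, n_fillers=len(fillers))
    return FillOutcome(
        peptide=Peptide(residues=tuple(out), topology=masked.topology),
        task_failure=False,
        n_fillers=len(fillers),
    )


def n_methylate(residue: Residue) -> Residue:
    """Insert ``(C)`` after the leading backbone-nitrogen token."""
    if residue.is_proline_like:
        raise IneligibleResidueError(
            "backbone nitrogen is secondary (proline-like); cannot N-methylate"
        )
    m = _LEADING_N_RE.match(residue.chuckles)
    if m.group("methyl"):
        raise IneligibleResidueError("residue is already N-methylated")
    insert_at = m.end()
    chuckles = residue.chuckles[:insert_at] + "(C)" + residue.chuckles[insert_at:]
    return replace(residue, chuckles=chuckles, n_methylated=True)


_STEREO_TOKEN_RE = re.compile(r"\[C@@?H?\]")


def flip_stereo(residue: Residue) -> Residue:
    """Invert the alpha-carbon stereo descriptor (``@@`` <-> ``@``).

    The alpha carbon is the first stereocenter after the backbone nitrogen, so
    the first bracket-carbon token is flipped.  Constitution (the stereo-free
    canonical SMILES) is unchanged.
    """
    m = _STEREO_TOKEN_RE.search(residue.chuckles)
    if m is None:
        raise IneligibleResidueError(f"no stereocenter in {residue.chuckles!r}")
    tok = m.group(0)
    flipped = tok.replace("@@", "\0").replace("@", "@@").replace("\0", "@")
    chuckles = residue.chuckles[: m.start()] + flipped + residue.chuckles[m.end():]
    return replace(residue, chuckles=chuckles, stereo_flipped=not residue.stereo_flipped)


# -- cyclization -------------------------------------------------------------

_SULFHYDRYL = Chem.MolFromSmarts("[SX2H1]")
_SIDECHAIN_PRIMARY_AMINE = Chem.MolFromSmarts("[NX3;H2;!$(NC=O)]")


def _residue_mol(residue: Residue) -> Chem.Mol | None:
    body = _RING_LABEL_RE.sub("", residue.chuckles)
    return Chem.MolFromSmiles(body + "O")


def has_sulfhydryl(residue: Residue) -> bool:
    mol = _residue_mol(residue)
    return mol is not None and mol.HasSubstructMatch(_SULFHYDRYL)


def has_sidechain_primary_amine(residue: Residue) -> bool:
    """Primary amine in the sidechain (the backbone N, atom 0, is excluded)."""
    mol = _residue_mol(residue)
    if mol is None:
        return False
    return any(match[0] != 0 for match in mol.GetSubstructMatches(_SIDECHAIN_PRIMARY_AMINE))


def _fresh_label(peptide: Peptide) -> int:
    used = {lab for r in peptide.residues for lab in r.peptide_ring_labels()}
    lab = PEPTIDE_RING_LABEL_START
    while lab in used:
        lab += 1
    if lab > 99:
        raise ChucklesError("ring-label space exhausted")
    return lab


def _label_on_leading_n(res: Residue, label: int) -> Residue:
    # ring-closure digit goes straight after the N atom, before any (C)
    chuckles = "N%" + f"{label:02d}" + res.chuckles[1:]
    return replace(res, chuckles=chuckles, ring_labels=res.ring_labels + (label,))


def _label_on_terminal_carbonyl(res: Residue, label: int) -> Residue:
    if not res.chuckles.endswith("C(=O)"):
        raise IneligibleResidueError(
            f"residue does not end in a carbonyl: {res.chuckles!r}"
        )
    chuckles = res.chuckles[:-5] + "C%" + f"{label:02d}" + "(=O)"
    return replace(res, chuckles=chuckles, ring_labels=res.ring_labels + (label,))


_THIOL_S_RE = re.compile(r"S(?![a-z0-9@A-Z(])|S(?=\))")


def _label_on_thiol(res: Residue, label: int) -> Residue:
    if not has_sulfhydryl(res):
        raise IneligibleResidueError(f"no sidechain sulfhydryl in {res.chuckles!r}")
    m = _THIOL_S_RE.search(res.chuckles)
    if m is None:
        raise IneligibleResidueError(
            f"cannot locate terminal thiol sulfur in {res.chuckles!r}"
        )
    i = m.start() + 1
    chuckles = res.chuckles[:i] + "%" + f"{label:02d}" + res.chuckles[i:]
    return replace(res, chuckles=chuckles, ring_labels=res.ring_labels + (label,))


_AMINE_N_RE = re.compile(r"N(?=\))|N$")


def _label_on_sidechain_amine(res: Residue, label: int) -> Residue:
    if not has_sidechain_primary_amine(res):
        raise IneligibleResidueError(
            f"no sidechain primary amine in {res.chuckles!r}"
        )
    # skip the backbone nitrogen at position 0: search from index 1 on
    m = _AMINE_N_RE.search(res.chuckles, 1)
    if m is None:
        raise IneligibleResidueError(
            f"cannot locate terminal amine nitrogen in {res.chuckles!r}"
        )
    i = m.start() + 1
    chuckles = res.chuckles[:i] + "%" + f"{label:02d}" + res.chuckles[i:]
    return replace(res, chuckles=chuckles, ring_labels=res.ring_labels + (label,))


def annotate_cyclization(
    peptide: Peptide,
    topology: Topology,
    attach_positions: tuple[int, int] | None = None,
) -> Peptide:
    """Place a fresh ``%nn`` ring label on the two cyclization attachment atoms.

    head_to_tail: backbone N of the first residue to the C-terminal carbonyl.
    sidechain_to_tail: a sidechain primary amine to the C-terminal carbonyl,
    with the amine residue at least 5 residues from the end.
    disulfide: the two sidechain sulfhydryl sulfurs.
    """
    L = len(peptide)
    label = _fresh_label(peptide)
    residues = list(peptide.residues)

    if topology == Topology.HEAD_TO_TAIL:
        i, j = 0, L - 1
        if residues[i].is_proline_like:
            raise IneligibleResidueError("head residue has a secondary backbone N")
        residues[i] = _label_on_leading_n(residues[i], label)
        residues[j] = _label_on_terminal_carbonyl(residues[j], label)
    elif topology == Topology.SIDECHAIN_TO_TAIL:
        if attach_positions is None:
            raise ChucklesError("sidechain_to_tail needs attach_positions")
        i, j = attach_positions
        if j != L - 1:
            raise TopologyConstraintError("sidechain_to_tail must end at the C-terminus")
        if j - i + 1 < 5:
            raise TopologyConstraintError(
                f"sidechain_to_tail cycle spans {j - i + 1} residues; needs >= 5"
            )
        residues[i] = _label_on_sidechain_amine(residues[i], label)
        residues[j] = _label_on_terminal_carbonyl(residues[j], label)
    elif topology == Topology.DISULFIDE:
        if attach_positions is None:
            raise ChucklesError("disulfide needs attach_positions")
        i, j = attach_positions
        residues[i] = _label_on_thiol(residues[i], label)
        residues[j] = _label_on_thiol(residues[j], label)
    else:
        raise ChucklesError(f"no cyclization to annotate for topology {topology}")

    return Peptide(residues=tuple(residues), topology=topology)


# -- validity and canonicalization -------------------------------------------


def is_valid(smiles: str) -> bool:
    """True iff the string parses and sanitizes under RDKit's valence model."""
    body = smiles.replace(SEPARATOR, "")
    if not body or MASK_TOKEN in body:
        return False
    return Chem.MolFromSmiles(body) is not None


def canonicalize(smiles: str, keep_stereo: bool = True) -> str:
    body = smiles.replace(SEPARATOR, "")
    mol = Chem.MolFromSmiles(body)
    if mol is None:
        raise ChucklesError(f"cannot parse SMILES: {smiles!r}")
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def largest_ring_size(smiles: str) -> int:
    """Atom count of the largest SSSR ring; 0 for acyclic or unparseable input."""
    mol = Chem.MolFromSmiles(smiles.replace(SEPARATOR, ""))
    if mol is None:
        return 0
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def parse_rho(rho: str, topology: Topology = Topology.LINEAR) -> Peptide:
    """Build a Peptide from a '|'-joined CHUCKLES string."""
    return Peptide(
        residues=tuple(Residue(part) for part in rho.split(SEPARATOR)),
        topology=topology,
    )


def iter_peptide_lines(lines: Iterable[str]) -> Iterable[tuple[str, Topology]]:
    """Parse the one-peptide-per-line text format (optional topology column)."""
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        topo = Topology(parts[1]) if len(parts) > 1 else Topology.LINEAR
        yield parts[0], topo
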