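"""Semi-synthetic peptide corpus generation.

The corpus emulates a training scheme in which peptides of 6-18 residues are
drawn with four topologies (40% linear, 20% each cyclic class), up to 30%
non-natural amino-acid content, and stereo-flip / backbone N-methylation
modifications on small fractions of residues.  Source-target training pairs
mask around 30% of residues per peptide, with the masked set biased toward
NNAAs by drawing the natural-mask fraction from a left-skewed distribution
on [0, 0.5] with mean 0.3.

All "left-skewed" fractions are scaled Beta draws with mass near the upper
bound of their support; parameters are exposed on :class:`GenConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .building_blocks import BuildingBlockLibrary, default_library
from .chuckles import (
    CYCLIC_TOPOLOGIES,
    MaskedPeptide,
    Peptide,
    Residue,
    Topology,
    annotate_cyclization,
    assemble_smiles,
    canonicalize,
    flip_stereo,
    has_sidechain_primary_amine,
    has_sulfhydryl,
    is_valid,
    mask,
    n_methylate,
    parse_rho,
)

logger = logging.getLogger(__name__)

TOPOLOGY_QUOTA = {
    Topology.LINEAR: 0.40,
    Topology.HEAD_TO_TAIL: 0.20,
    Topology.SIDECHAIN_TO_TAIL: 0.20,
    Topology.DISULFIDE: 0.20,
}
SPLIT_FRACTIONS = {"train": 0.90, "validation": 0.05, "test": 0.05}


class GenerationExhaustedError(RuntimeError):
    pass


@dataclass
class GenConfig:
    """Knobs of the corpus generator; defaults are the study conditions."""

    n_peptides: int = 20_000
    topology_quota: dict[Topology, float] = field(
        default_factory=lambda: dict(TOPOLOGY_QUOTA)
    )
    length_range: tuple[int, int] = (6, 18)
    length_mean: float = 12.0
    length_sd: float = 3.0
    nnaa_fraction_range: tuple[float, float] = (0.0, 0.3)
    stereo_fraction_range: tuple[float, float] = (0.0, 0.25)
    nmethyl_fraction_range: tuple[float, float] = (0.0, 0.25)
    #: Beta shape for the left-skewed NNAA / modification fractions
    skew_shape: tuple[float, float] = (5.0, 2.0)
    mask_fraction_target: float = 0.30
    natural_mask_fraction_range: tuple[float, float] = (0.0, 0.5)
    #: Beta shape for the natural-mask fraction; Beta(3,2) on [0,0.5] has mean 0.3
    natural_mask_shape: tuple[float, float] = (3.0, 2.0)
    seed: int = 0
    max_retries_per_peptide: int = 200

    def __post_init__(self) -> None:
        total = sum(self.topology_quota.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"topology quotas must sum to 1, got {total}")
        for rng_ in (
            self.nnaa_fraction_range,
            self.stereo_fraction_range,
            self.nmethyl_fraction_range,
            self.natural_mask_fraction_range,
        ):
            if not (0.0 <= rng_[0] <= rng_[1] <= 1.0):
                raise ValueError(f"fraction range {rng_} outside [0,1]")


def sample_length(config: GenConfig, rng: np.random.Generator) -> int:
    """Rounded truncated-normal length on the configured range."""
    lo, hi = config.length_range
    while True:
        val = int(round(rng.normal(config.length_mean, config.length_sd)))
        if lo <= val <= hi:
            return val


def sample_skewed_fraction(
    frac_range: tuple[float, float],
    rng: np.random.Generator,
    shape: tuple[float, float] = (5.0, 2.0),
) -> float:
    """Scaled Beta draw with mass concentrated near the upper bound."""
    lo, hi = frac_range
    if hi == lo:
        return lo
    return lo + (hi - lo) * rng.beta(*shape)


def _count_from_fraction(fraction: float, total: int) -> int:
    return min(total, int(round(fraction * total)))


def _draw_without_replacement(
    pool: Sequence[Residue], k: int, rng: np.random.Generator
) -> list[Residue]:
    if not pool and k > 0:
        raise GenerationExhaustedError("empty residue pool")
    if k > len(pool):
        # anchors may legitimately repeat (e.g. two cysteines of a disulfide)
        idx = rng.choice(len(pool), size=k, replace=True)
    else:
        idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def compose_peptide(
    config: GenConfig,
    topology: Topology,
    library: BuildingBlockLibrary,
    rng: np.random.Generator,
) -> Peptide:
    """Draw one peptide of the requested topology.

    Residues are sampled without replacement from the natural and NNAA pools
    at a sampled NNAA fraction, shuffled, modified (stereo flips then
    N-methylations), anchored for cyclization, and validated.
    """
    for _ in range(config.max_retries_per_peptide):
        L = sample_length(config, rng)
        nnaa_frac = sample_skewed_fraction(
            config.nnaa_fraction_range, rng, config.skew_shape
        )
        n_nnaa = _count_from_fraction(nnaa_frac, L)

        anchors: dict[int, Residue] = {}
        attach: tuple[int, int] | None = None
        if topology == Topology.DISULFIDE:
            thiols = [r for r in library.natural + library.non_natural if has_sulfhydryl(r)]
            i, j = sorted(rng.choice(L, size=2, replace=False))
            pair = _draw_without_replacement(thiols, 2, rng)
            anchors[int(i)], anchors[int(j)] = pair[0], pair[1]
            attach = (int(i), int(j))
        elif topology == Topology.SIDECHAIN_TO_TAIL:
            amines = [
                r
                for r in library.natural + library.non_natural
                if has_sidechain_primary_amine(r)
            ]
            i = int(rng.integers(0, L - 4))  # cycle spans >= 5 residues
            anchors[i] = _draw_without_replacement(amines, 1, rng)[0]
            attach = (i, L - 1)

        n_free = L - len(anchors)
        n_nnaa_free = min(n_nnaa, n_free)
        n_nat_free = n_free - n_nnaa_free
        body = _draw_without_replacement(
            library.natural, n_nat_free, rng
        ) + _draw_without_replacement(library.non_natural, n_nnaa_free, rng)
        rng.shuffle(body)

        residues: list[Residue] = []
        it = iter(body)
        for pos in range(L):
            residues.append(anchors[pos] if pos in anchors else next(it))

        # stereo flips on a sampled fraction of stereocenter-bearing residues
        stereo_frac = sample_skewed_fraction(
            config.stereo_fraction_range, rng, config.skew_shape
        )
        eligible = [k for k, r in enumerate(residues) if "[C@" in r.chuckles]
        for k in _pick(eligible, _count_from_fraction(stereo_frac, L), rng):
            residues[k] = flip_stereo(residues[k])

        # backbone N-methylation, same selection scheme
        nme_frac = sample_skewed_fraction(
            config.nmethyl_fraction_range, rng, config.skew_shape
        )
        eligible = [
            k
            for k, r in enumerate(residues)
            if not r.is_proline_like and not r.n_methylated
        ]
        if topology == Topology.HEAD_TO_TAIL and 0 in eligible:
            eligible.remove(0)  # keep the ring-closing amide nitrogen unmethylated
        for k in _pick(eligible, _count_from_fraction(nme_frac, L), rng):
            residues[k] = n_methylate(residues[k])

        if topology == Topology.HEAD_TO_TAIL and residues[0].is_proline_like:
            continue

        peptide = Peptide(residues=tuple(residues), topology=Topology.LINEAR)
        if topology in CYCLIC_TOPOLOGIES:
            peptide = annotate_cyclization(peptide, topology, attach)
        else:
            peptide = Peptide(residues=tuple(residues), topology=Topology.LINEAR)

        if is_valid(assemble_smiles(peptide)):
            return peptide
    raise GenerationExhaustedError(
        f"could not compose a valid {topology.value} peptide "
        f"in {config.max_retries_per_peptide} tries"
    )


def _pick(pool: list[int], k: int, rng: np.random.Generator) -> list[int]:
    k = min(k, len(pool))
    if k == 0:
        return []
    return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]


@dataclass
class Dataset:
    peptides: list[Peptide]
    split_labels: list[str]

    def split(self, name: str) -> list[Peptide]:
        return [p for p, s in zip(self.peptides, self.split_labels) if s == name]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rho\ttopology\tsplit\n")
            for p, s in zip(self.peptides, self.split_labels):
                fh.write(f"{p.rho}\t{p.topology.value}\t{s}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Dataset":
        peptides, labels = [], []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("rho")
            for line in fh:
                rho, topo, split_ = line.rstrip("\n").split("\t")
                peptides.append(parse_rho(rho, Topology(topo)))
                labels.append(split_)
        return cls(peptides=peptides, split_labels=labels)


def _largest_remainder(fractions: dict, total: int) -> dict:
    """Integer allocation of ``total`` by quota with largest-remainder rounding."""
    raw = {k: v * total for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def build_dataset(
    config: GenConfig, library: BuildingBlockLibrary | None = None
) -> Dataset:
    """Generate the full corpus: quota-exact topologies, unique at the
    canonical-SMILES level, stratified 90/5/5 split on (topology, length)."""
    library = library if library is not None else default_library(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    quota = _largest_remainder(config.topology_quota, config.n_peptides)

    peptides: list[Peptide] = []
    seen: set[str] = set()
    for topology in TOPOLOGY_QUOTA:  # fixed iteration order for determinism
        produced = 0
        attempts = 0
        limit = quota[topology] * config.max_retries_per_peptide
        while produced < quota[topology]:
            if attempts > limit:
                raise GenerationExhaustedError(
                    f"too many duplicates composing {topology.value} peptides"
                )
            attempts += 1
            p = compose_peptide(config, topology, library, rng)
            key = canonicalize(assemble_smiles(p))
            if key in seen:
                continue
            seen.add(key)
            peptides.append(p)
            produced += 1

    split_labels = _stratified_split(peptides, rng)
    return Dataset(peptides=peptides, split_labels=split_labels)


def _stratified_split(peptides: list[Peptide], rng: np.random.Generator) -> list[str]:
    """90/5/5 split stratified on (topology, length).

    Each cell gets the floor of its fractional allocation per split; the
    leftover slots are then distributed by largest fractional remainder,
    subject to the exact global 90/5/5 counts.  Ties break by a seeded shuffle.
    """
    n = len(peptides)
    cells: dict[tuple, list[int]] = {}
    for i, p in enumerate(peptides):
        cells.setdefault((p.topology.value, len(p)), []).append(i)

    global_counts = _largest_remainder(SPLIT_FRACTIONS, n)
    cell_keys = sorted(cells)
    alloc = {key: {} for key in cell_keys}
    leftovers: list[tuple[float, float, str, str]] = []
    for key in cell_keys:
        size = len(cells[key])
        for split_, frac in SPLIT_FRACTIONS.items():
            raw = frac * size
            alloc[key][split_] = int(np.floor(raw))
            leftovers.append((raw - np.floor(raw), rng.random(), key, split_))
    assigned = {s: sum(alloc[k][s] for k in cell_keys) for s in SPLIT_FRACTIONS}
    cell_left = {k: len(cells[k]) - sum(alloc[k].values()) for k in cell_keys}
    leftovers.sort(key=lambda t: (-t[0], t[1]))
    for _, _, key, split_ in leftovers:
        if cell_left[key] > 0 and assigned[split_] < global_counts[split_]:
            alloc[key][split_] += 1
            cell_left[key] -= 1
            assigned[split_] += 1
    # any residual slots (all preferred splits full) go to the fullest gap
    for key in cell_keys:
        while cell_left[key] > 0:
            split_ = max(SPLIT_FRACTIONS, key=lambda s: global_counts[s] - assigned[s])
            alloc[key][split_] += 1
            cell_left[key] -= 1
            assigned[split_] += 1

    labels = [""] * n
    for key in cell_keys:
        idxs = list(cells[key])
        rng.shuffle(idxs)
        cursor = 0
        for split_ in ("train", "validation", "test"):
            for i in idxs[cursor : cursor + alloc[key][split_]]:
                labels[i] = split_
            cursor += alloc[key][split_]
    return labels


# -- training pairs -----------------------------------------------------------


@dataclass(frozen=True)
class TrainingPair:
    source: str
    target: str
    n_masked: int


def sample_mask_count(L: int, config: GenConfig, rng: np.random.Generator) -> int:
    """Binomial(L, mask_fraction_target) truncated to [1, L]."""
    return int(np.clip(rng.binomial(L, config.mask_fraction_target), 1, L))


def choose_mask_positions(
    peptide: Peptide,
    library: BuildingBlockLibrary,
    config: GenConfig,
    rng: np.random.Generator,
    force_include: int | None = None,
    exclude: Sequence[int] = (),
) -> list[int]:
    """Pick which residues to mask.

    The count is ~Binomial(L, 0.3) (at least 1); its split between natural and
    NNAA residues follows the sampled natural-mask fraction, which biases the
    masked set toward NNAAs.
    """
    L = len(peptide)
    k = sample_mask_count(L, config, rng)
    k = min(k, L - len(exclude))
    nat_frac = sample_skewed_fraction(
        config.natural_mask_fraction_range, rng, config.natural_mask_shape
    )
    natural_pos, nnaa_pos = [], []
    for i, r in enumerate(peptide.residues):
        if i in exclude or i == force_include:
            continue
        (natural_pos if library.classify(r.chuckles) == "natural" else nnaa_pos).append(i)

    chosen: list[int] = [] if force_include is None else [force_include]
    budget = k - len(chosen)
    n_nat = min(_count_from_fraction(nat_frac, budget), len(natural_pos))
    n_nnaa = min(budget - n_nat, len(nnaa_pos))
    n_nat = min(budget - n_nnaa, len(natural_pos))  # rebalance if NNAA pool short
    chosen += _pick(natural_pos, n_nat, rng)
    chosen += _pick(nnaa_pos, n_nnaa, rng)
    if not chosen:
        chosen = _pick([i for i in range(L) if i not in exclude], 1, rng)
    return sorted(chosen)


def make_pair(
    peptide: Peptide,
    library: BuildingBlockLibrary,
    config: GenConfig,
    rng: np.random.Generator,
) -> TrainingPair:
    positions = choose_mask_positions(peptide, library, config, rng)
    masked, target = mask(peptide, positions)
    return TrainingPair(source=masked.source, target=target, n_masked=len(positions))


def make_pairs(
    dataset_or_peptides: Dataset | Sequence[Peptide],
    library: BuildingBlockLibrary,
    config: GenConfig,
    rng: np.random.Generator,
    pairs_per_peptide: int = 1,
) -> list[TrainingPair]:
    peptides = (
        dataset_or_peptides.peptides
        if isinstance(dataset_or_peptides, Dataset)
        else list(dataset_or_peptides)
    )
    out = []
    for p in peptides:
        for _ in range(pairs_per_peptide):
            out.append(make_pair(p, library, config, rng))
    return out


def write_pairs(pairs: Sequence[TrainingPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for p in pairs:
            fh.write(f"{p.source}\t{p.target}\n")


def read_pairs(path: str | Path) -> list[TrainingPair]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            source, target = line.rstrip("\n").split("\t")
            out.append(
                TrainingPair(
                    source=source,
                    target=target,
                    n_masked=source.split("|").count("?"),
                )
            )
    return out


# -- evaluation sets ----------------------------------------------------------


def build_eval_sets(
    dataset: Dataset,
    library: BuildingBlockLibrary,
    config: GenConfig,
    rng: np.random.Generator,
    per_topology: int = 100,
    topology_per_topology: int = 10,
) -> tuple[list[MaskedPeptide], list[MaskedPeptide]]:
    """Carve the two evaluation sets out of the test split.

    ``model_eval`` aims at ``per_topology`` masked peptides per topology,
    stratified by length; ``topology_eval`` peptides keep one cyclization
    anchor unmasked while the other anchor is masked.  When the test split is
    small the sizes scale down, preserving the 10:1 ratio.
    """
    test = dataset.split("test")
    by_topo: dict[Topology, list[Peptide]] = {t: [] for t in TOPOLOGY_QUOTA}
    for p in test:
        by_topo[p.topology].append(p)

    model_eval: list[MaskedPeptide] = []
    topology_eval: list[MaskedPeptide] = []
    for topology, pool in by_topo.items():
        n_model = min(per_topology, len(pool))
        if n_model < per_topology:
            logger.warning(
                "test split has only %d %s peptides (wanted %d); scaling down",
                len(pool), topology.value, per_topology,
            )
        n_topo = max(1, min(topology_per_topology, n_model * topology_per_topology // max(per_topology, 1)))
        pool = sorted(pool, key=len)  # length stratification via even strides
        idx = np.linspace(0, len(pool) - 1, num=n_model).astype(int) if pool else []
        chosen = [pool[i] for i in dict.fromkeys(idx)]
        for p in chosen:
            positions = choose_mask_positions(p, library, config, rng)
            model_eval.append(mask(p, positions)[0])
        for p in chosen[:n_topo]:
            if topology == Topology.LINEAR:
                positions = choose_mask_positions(p, library, config, rng)
            else:
                anchor_pos = [
                    i for i, r in enumerate(p.residues) if r.peptide_ring_labels()
                ]
                keep, masked_anchor = (
                    (anchor_pos[0], anchor_pos[1])
                    if rng.random() < 0.5
                    else (anchor_pos[1], anchor_pos[0])
                )
                positions = choose_mask_positions(
                    p, library, config, rng,
                    force_include=masked_anchor, exclude=[keep],
                )
            topology_eval.append(mask(p, positions)[0])
    return model_eval, topology_eval
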