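"""Reinforcement-learning loop steering the infilling model.

The agent starts as a copy of the pretrained prior and is tuned to maximize a
peptide-level scoring function.  Each step samples a batch of filler sets for
the fixed masked source, maps them onto peptides, scores them (invalid
molecules score 0), applies the diversity filter, and minimizes the squared
augmented-likelihood residual

    L = mean_b ( log P_prior(y_b|x) + sigma * score_b - log P_agent(y_b|x) )^2

so sequences scoring high become more likely under the agent than under the
prior, by a margin controlled by ``sigma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _autograd as ag
from .building_blocks import NATURAL_CHUCKLES
from .chuckles import (
    MaskedPeptide,
    Peptide,
    Residue,
    Topology,
    annotate_cyclization,
    is_valid,
    map_fillers,
    mask as mask_peptide,
    try_assemble,
)
from .model import Seq2SeqModel
from .scoring import (
    DEFAULT_ALERT_SMARTS,
    DiversityFilter,
    ScoreTransform,
    ScoringComponent,
    ScoringFunction,
    TransformShape,
    largest_ring_size,
    lipophilicity,
    make_custom_alerts,
    permeability_surrogate,
    solubility_surrogate,
)

logger = logging.getLogger(__name__)


@dataclass
class RLConfig:
    source: str
    n_steps: int = 100
    batch_size: int = 32
    sigma: float = 120.0
    learning_rate: float = 1e-4
    seed: int = 0
    sample_max_len: int = 300

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class StepRecord:
    step: int
    rhos: list[str]
    valid: list[bool]
    scores: list[float]
    raw_components: dict[str, list[float]]
    transformed_components: dict[str, list[float]]
    agent_nll: list[float]
    prior_nll: list[float]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def validity(self) -> float:
        return float(np.mean(self.valid))

    def mean_raw(self, name: str, valid_only: bool = True) -> float:
        vals = [
            v
            for v, ok in zip(self.raw_components[name], self.valid)
            if np.isfinite(v) and (ok or not valid_only)
        ]
        return float(np.mean(vals)) if vals else float("nan")


def rl_step(
    agent: Seq2SeqModel,
    prior: Seq2SeqModel,
    config: RLConfig,
    scoring: ScoringFunction,
    opt: ag.Adam,
    rng: np.random.Generator,
    step: int,
    masked: MaskedPeptide,
) -> StepRecord:
    """One RL update; returns the per-peptide batch record."""
    samples = agent.sample_multinomial(
        config.source, config.batch_size, rng, max_len=config.sample_max_len
    )
    targets = ["|".join(f) for f, _ in samples]

    rhos, valids, scores = [], [], []
    raw: dict[str, list[float]] = {c.name: [] for c in scoring.components}
    tra: dict[str, list[float]] = {c.name: [] for c in scoring.components}
    for fillers, _ in samples:
        outcome = map_fillers(masked, fillers)
        smiles = try_assemble(outcome.peptide)
        ok = smiles is not None and is_valid(smiles)
        score, detail = scoring(smiles if ok else None)
        rhos.append(outcome.peptide.rho if outcome.peptide is not None else "")
        valids.append(ok)
        scores.append(score)
        for name, (r, t) in detail.items():
            raw[name].append(r)
            tra[name].append(t)

    with ag.no_grad():
        prior_nll = prior.sequence_nll(
            [config.source] * len(targets), targets
        ).data.copy()
    agent_nll = agent.sequence_nll([config.source] * len(targets), targets)

    # residual of the augmented likelihood; NLL = -log P
    residual_const = -prior_nll + config.sigma * np.asarray(scores)
    diff = ag.add(agent_nll, residual_const)
    loss = ag.mean(ag.mul(diff, diff))
    opt.zero_grad()
    loss.backward()
    opt.step()

    return StepRecord(
        step=step,
        rhos=rhos,
        valid=valids,
        scores=scores,
        raw_components=raw,
        transformed_components=tra,
        agent_nll=agent_nll.data.tolist(),
        prior_nll=prior_nll.tolist(),
    )


def run_rl(
    prior: Seq2SeqModel,
    config: RLConfig,
    scoring: ScoringFunction,
    masked: MaskedPeptide,
) -> tuple[Seq2SeqModel, list[StepRecord]]:
    agent = prior.clone()
    opt = ag.Adam(agent.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    records = []
    for step in range(config.n_steps):
        rec = rl_step(agent, prior, config, scoring, opt, rng, step, masked)
        records.append(rec)
        logger.info(
            "step %d: score %.3f validity %.2f", step, rec.mean_score, rec.validity
        )
    return agent, records


# -- scenario drivers ---------------------------------------------------------


def ring_size_component(objective: str) -> ScoringComponent:
    """The three ring-size objectives: maximize, macrocycle window, minimize."""
    transforms = {
        "maximize": ScoreTransform(TransformShape.SIGMOID, 0.0, 60.0),
        "macrocycle_window": ScoreTransform(TransformShape.DOUBLE_SIGMOID, 0.0, 30.0),
        "minimize": ScoreTransform(TransformShape.REVERSE_SIGMOID, 0.0, 60.0),
    }
    return ScoringComponent(
        name="largest_ring", scorer=largest_ring_size, transform=transforms[objective]
    )


def topology_scenario_input() -> MaskedPeptide:
    """9-mer with positions 1, 2, 4 and 9 masked, the rest alanine, and no
    topological information, so any topology can emerge."""
    ala = Residue(NATURAL_CHUCKLES["A"])
    peptide = Peptide(residues=(ala,) * 9, topology=Topology.LINEAR)
    masked, _ = mask_peptide(peptide, [0, 1, 3, 8])
    return masked


def rbp_scenario_input() -> MaskedPeptide:
    """Head-to-tail cyclized Rev-binding peptide YPAASYR + GG with the
    non-pharmacophore residues (both alanines, both glycines) masked.

    Synthetic reconstruction of the macrocyclized RBP design: the sequence is
    extended with two glycines and cyclized head-to-tail; the C-terminal
    glycine carries the ring closure and sits among the masked positions.
    """
    seq = "YPAASYRGG"
    residues = tuple(Residue(NATURAL_CHUCKLES[a]) for a in seq)
    peptide = annotate_cyclization(
        Peptide(residues=residues), Topology.HEAD_TO_TAIL
    )
    masked, _ = mask_peptide(peptide, [2, 3, 7, 8])
    return masked


def run_topology_scenario(
    prior: Seq2SeqModel,
    objective: str = "maximize",
    n_steps: int = 100,
    seeds: Sequence[int] = (1, 2, 3),
    batch_size: int = 32,
    sigma: float = 120.0,
    learning_rate: float = 1e-4,
) -> list[list[StepRecord]]:
    """Steer a topology-free 9-mer toward a ring-size objective; one learning
    curve per seed (triplicate by default)."""
    masked = topology_scenario_input()
    curves = []
    for seed in seeds:
        # topology steering penalizes only exact repetition; scaffold-level
        # bucketing is reserved for the MPO scenario
        scoring = ScoringFunction(
            components=[ring_size_component(objective)],
            mode="geometric_mean",
            diversity_filter=DiversityFilter(key="identical"),
        )
        config = RLConfig(
            source=masked.source,
            n_steps=n_steps,
            batch_size=batch_size,
            sigma=sigma,
            learning_rate=learning_rate,
            seed=seed,
        )
        _, records = run_rl(prior, config, scoring, masked)
        curves.append(records)
    return curves


def mpo_components() -> list[ScoringComponent]:
    """Topology + custom alerts + solubility + permeability, as used in the
    soluble-permeable-macrocycle design scenario."""
    return [
        ScoringComponent(
            name="largest_ring",
            scorer=largest_ring_size,
            transform=ScoreTransform(TransformShape.DOUBLE_SIGMOID, 0.0, 30.0),
        ),
        ScoringComponent(
            name="custom_alerts",
            scorer=make_custom_alerts(DEFAULT_ALERT_SMARTS),
        ),
        ScoringComponent(
            name="solubility",
            scorer=solubility_surrogate,
            transform=ScoreTransform(TransformShape.SIGMOID, 0.0, 0.5, k=10.0),
        ),
        ScoringComponent(name="permeability", scorer=permeability_surrogate),
    ]


def run_mpo_scenario(
    prior: Seq2SeqModel,
    n_steps: int = 200,
    seed: int = 1,
    batch_size: int = 32,
    sigma: float = 120.0,
    learning_rate: float = 1e-4,
    top_k: int = 100,
) -> tuple[list[StepRecord], list[dict], list[float]]:
    """Multi-parameter optimization on the cyclized RBP input.

    Returns the learning curve, the ranked unique designs, and the per-step
    mean lipophilicity tracker.
    """
    masked = rbp_scenario_input()
    scoring = ScoringFunction(
        components=mpo_components(),
        mode="geometric_mean",
        diversity_filter=DiversityFilter(),
    )
    config = RLConfig(
        source=masked.source,
        n_steps=n_steps,
        batch_size=batch_size,
        sigma=sigma,
        learning_rate=learning_rate,
        seed=seed,
    )
    _, records = run_rl(prior, config, scoring, masked)

    logp_curve = []
    best: dict[str, dict] = {}
    for rec in records:
        logps = []
        for rho, ok, score in zip(rec.rhos, rec.valid, rec.scores):
            if not ok:
                continue
            smiles = try_assemble(parse_rho_safe(rho))
            if smiles is None:
                continue
            logps.append(lipophilicity(smiles))
            entry = best.get(rho)
            if entry is None or score > entry["score"]:
                detail = {
                    name: rec.transformed_components[name][rec.rhos.index(rho)]
                    for name in rec.transformed_components
                }
                best[rho] = {
                    "rho": rho,
                    "smiles": smiles,
                    "score": score,
                    **detail,
                }
        logp_curve.append(float(np.mean(logps)) if logps else float("nan"))
    designs = sorted(best.values(), key=lambda d: -d["score"])[:top_k]
    return records, designs, logp_curve


def parse_rho_safe(rho: str) -> Peptide | None:
    from .chuckles import ChucklesError, parse_rho

    try:
        return parse_rho(rho, Topology.HEAD_TO_TAIL)
    except ChucklesError:
        return None
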