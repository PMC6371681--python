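"""Simulation of iid-site alignments and pattern counts on small trees.

Sites evolve independently, so an n-site JC dataset is distributionally a
single multinomial draw of size n over the exact pattern-class
probabilities.  That multinomial shortcut is the default (exact and fast);
a sequence-level simulator (root drawn from the stationary distribution,
per-branch transition matrices, matrix exponential for general models) is
retained for general reversible models and end-to-end I/O tests.

Reproducibility: one master seed spawns per-replicate child streams
(`numpy.random.SeedSequence.spawn`), so replicate r of a configuration is
identical regardless of how the replicate stream is chunked or
parallelized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .patterns import PatternCounts3, pattern_class_probs_3
from .quartet import quartet_class_probs

__all__ = [
    "ThreeTaxonTree",
    "QuartetTree",
    "GeneralModel",
    "SimConfig",
    "simulate_counts_3",
    "simulate_counts_4",
    "iter_counts_3",
    "simulate_alignment",
    "experiment_grid",
    "EXPERIMENTS",
    "true_class_probs",
    "write_fasta",
    "write_phylip",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ThreeTaxonTree:
    """Unrooted three-taxon tree with branches to A, B, C."""

    d_A: float
    d_B: float
    d_C: float

    def __post_init__(self):
        if any(not (d >= 0) for d in (self.d_A, self.d_B, self.d_C)):
            raise ValueError("branch lengths must be >= 0")

    @property
    def taxa(self):
        return ("A", "B", "C")


@dataclass(frozen=True)
class QuartetTree:
    """Four-taxon tree: W and X at the ends of a fixed path with the long
    branches to Y and Z attached along it (Y nearer W; topology WY|XZ).

    ``y_pos`` and ``z_pos`` are the attachment points as fractions of the
    W-X path; "evenly spaced" is y_pos=1/3, z_pos=2/3.
    """

    long_length: float
    path_length: float = 0.1
    y_pos: float = 1.0 / 3.0
    z_pos: float = 2.0 / 3.0

    def __post_init__(self):
        if not (0 <= self.y_pos <= self.z_pos <= 1):
            raise ValueError("need 0 <= y_pos <= z_pos <= 1")
        if self.long_length < 0 or self.path_length < 0:
            raise ValueError("branch lengths must be >= 0")

    @property
    def taxa(self):
        return ("W", "X", "Y", "Z")

    @property
    def branch_lengths(self) -> tuple:
        """(b_W, b_X, b_Y, b_Z, b_internal) on topology WY|XZ."""
        return (
            self.y_pos * self.path_length,
            (1 - self.z_pos) * self.path_length,
            self.long_length,
            self.long_length,
            (self.z_pos - self.y_pos) * self.path_length,
        )


@dataclass(frozen=True)
class GeneralModel:
    """A general 4x4 reversible substitution model.

    ``rates``: symmetric exchangeability parameters for the pairs
    (AC, AG, AT, CG, CT, GT); ``freqs``: stationary base frequencies.
    The generator is scaled to one expected substitution per unit branch
    length.  ``GeneralModel.jc()`` gives the JC special case.
    """

    rates: tuple
    freqs: tuple

    def __post_init__(self):
        r = np.asarray(self.rates, float)
        f = np.asarray(self.freqs, float)
        if r.shape != (6,) or (r < 0).any():
            raise ValueError("need 6 non-negative exchangeabilities")
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("frequencies must be positive and sum to 1")

    @classmethod
    def jc(cls) -> "GeneralModel":
        return cls(rates=(1.0,) * 6, freqs=(0.25,) * 4)

    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q (rows sum to 0, -sum(pi_i Q_ii) = 1)."""
        r = np.asarray(self.rates, float)
        f = np.asarray(self.freqs, float)
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(pairs):
            Q[i, j] = r[k] * f[j]
            Q[j, i] = r[k] * f[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.dot(f, np.diag(Q)))
        return Q / scale

    def transition(self, d: float) -> np.ndarray:
        from scipy.linalg import expm

        if math.isinf(d):
            return np.tile(np.asarray(self.freqs, float), (4, 1))
        return expm(self.rate_matrix() * d)

    @property
    def is_jc(self) -> bool:
        return (
            np.allclose(self.rates, self.rates[0])
            and np.allclose(self.freqs, 0.25)
        )


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition: tree, sites, replicates, seed, model."""

    tree: object
    n: int = 300
    reps: int = 5000
    seed: int | None = None
    model: GeneralModel = field(default_factory=GeneralModel.jc)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def to_json(self) -> str:
        d = asdict(self)
        d["tree_kind"] = type(self.tree).__name__
        return json.dumps(d)


def true_class_probs(config: SimConfig) -> np.ndarray:
    """Exact aggregated pattern-class probabilities for a JC configuration."""
    if not config.model.is_jc:
        raise ValueError("exact class probabilities are for the JC model")
    t = config.tree
    if isinstance(t, ThreeTaxonTree):
        return pattern_class_probs_3((t.d_A, t.d_B, t.d_C))
    bl = t.branch_lengths
    e = [np.array([0.0 if math.isinf(d) else math.exp(-4 * d / 3)]) for d in bl]
    from .patterns import CLASS_MULT_4

    return quartet_class_probs("WY|XZ", e)[0] * CLASS_MULT_4


def _child_rngs(seed, reps) -> list:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(reps)]


def simulate_counts_3(config: SimConfig) -> np.ndarray:
    """Simulate replicate pattern counts on a three-taxon JC tree.

    Each replicate is one multinomial draw of size n over the exact class
    probabilities.  Returns an (reps, 5) integer array (class order
    xxx, xxy, xyx, yxx, xyz); wrap rows with PatternCounts3 as needed.
    """
    if not isinstance(config.tree, ThreeTaxonTree):
        raise ValueError("simulate_counts_3 needs a ThreeTaxonTree config")
    if not config.model.is_jc:
        raise ValueError(
            "multinomial shortcut is JC-only; use simulate_alignment for "
            "general models"
        )
    p = true_class_probs(config)
    out = np.empty((config.reps, 5), dtype=np.int64)
    for r, rng in enumerate(_child_rngs(config.seed, config.reps)):
        out[r] = rng.multinomial(config.n, p)
    return out


def simulate_counts_4(config: SimConfig) -> np.ndarray:
    """Simulate replicate 15-class pattern counts on the quartet tree."""
    if not isinstance(config.tree, QuartetTree):
        raise ValueError("simulate_counts_4 needs a QuartetTree config")
    if not config.model.is_jc:
        raise ValueError("multinomial shortcut is JC-only")
    p = true_class_probs(config)
    out = np.empty((config.reps, 15), dtype=np.int64)
    for r, rng in enumerate(_child_rngs(config.seed, config.reps)):
        out[r] = rng.multinomial(config.n, p)
    return out


def iter_counts_3(config: SimConfig) -> Iterator[PatternCounts3]:
    """Stream of PatternCounts3 replicates (same stream as simulate_counts_3)."""
    for row in simulate_counts_3(config):
        yield PatternCounts3(*row)


def _tree_edges(tree) -> tuple[list, list]:
    """(nodes, edges) for sequence-level simulation; edge = (parent, child, d).

    Node 0 is the root (an internal node); tips are labelled by taxon name.
    """
    if isinstance(tree, ThreeTaxonTree):
        return (
            ["root", "A", "B", "C"],
            [("root", "A", tree.d_A), ("root", "B", tree.d_B), ("root", "C", tree.d_C)],
        )
    if isinstance(tree, QuartetTree):
        bW, bX, bY, bZ, bI = tree.branch_lengths
        return (
            ["u", "v", "W", "X", "Y", "Z"],
            [
                ("u", "W", bW),
                ("u", "Y", bY),
                ("u", "v", bI),
                ("v", "X", bX),
                ("v", "Z", bZ),
            ],
        )
    raise ValueError(f"unknown tree type {type(tree).__name__}")


def simulate_alignment(config: SimConfig, replicate: int = 0) -> dict:
    """Simulate one replicate alignment at the sequence level.

    The root state is drawn per site from the stationary distribution and
    propagated along each branch with the model's transition matrix.
    Returns {taxon: sequence}.  Replicate r uses the r-th child stream of
    the master seed, so counts-level and sequence-level paths share the
    seeding scheme (not the same draws).
    """
    rng = _child_rngs(config.seed, max(config.reps, replicate + 1))[replicate]
    nodes, edges = _tree_edges(config.tree)
    freqs = np.asarray(config.model.freqs, float)
    states = {nodes[0]: rng.choice(4, size=config.n, p=freqs)}
    for parent, child, d in edges:
        P = config.model.transition(d)
        parent_states = states[parent]
        u = rng.random(config.n)
        cum = np.cumsum(P[parent_states], axis=1)
        states[child] = (u[:, None] < cum).argmax(axis=1)
    return {
        t: "".join(_BASES[i] for i in states[t]) for t in config.tree.taxa
    }


def write_fasta(alignment: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


def write_phylip(alignment: dict, path) -> None:
    n = len(next(iter(alignment.values())))
    with open(path, "w") as fh:
        fh.write(f" {len(alignment)} {n}\n")
        for name, seq in alignment.items():
            fh.write(f"{name:<10}{seq}\n")


# ---------------------------------------------------------------------------
# Named experiment grids: the simulation conditions of the study.
# ---------------------------------------------------------------------------

_DC_GRID = (0.1, 0.5, 1.0, 1.25, 1.5, 2.0)
_DAB_GRID = (0.05, 0.1, 0.2, 0.3)
_LBJ_LENGTHS = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0)

EXPERIMENTS = ("fig3", "fig4", "fig5", "table4", "fig8g", "fig8h")


def experiment_grid(name: str, seed: int | None = None) -> list[SimConfig]:
    """The named simulation grids of the study.

    fig3/fig4/table4: d_A=d_B=0.1, d_C in {0.1,0.5,1,1.25,1.5,2}, n=300,
    R=5000.  fig5: additionally d_A=d_B in {0.05,0.1,0.2,0.3}.  fig8g: the
    quartet tree with long branches 1.5, n=1000, R=5000.  fig8h: long
    branch lengths from 0.1 to 10, n=1000, R=2000.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; one of {EXPERIMENTS}")

    def cell_seeds(k):
        # distinct, reproducible sub-seeds per grid cell
        if seed is None:
            return [None] * k
        return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) >> 1]

    if name in ("fig3", "fig4", "table4"):
        return [
            SimConfig(ThreeTaxonTree(0.1, 0.1, dc), n=300, reps=5000, seed=s)
            for dc, s in zip(_DC_GRID, cell_seeds(len(_DC_GRID)))
        ]
    if name == "fig5":
        cells = [(dab, dc) for dab in _DAB_GRID for dc in _DC_GRID]
        return [
            SimConfig(ThreeTaxonTree(dab, dab, dc), n=300, reps=5000, seed=s)
            for (dab, dc), s in zip(cells, cell_seeds(len(cells)))
        ]
    if name == "fig8g":
        return [SimConfig(QuartetTree(1.5), n=1000, reps=5000, seed=cell_seeds(1)[0])]
    return [
        SimConfig(QuartetTree(L), n=1000, reps=2000, seed=s)
        for L, s in zip(_LBJ_LENGTHS, cell_seeds(len(_LBJ_LENGTHS)))
    ]
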