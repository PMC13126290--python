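"""Synthetic ploidy-scaled neuron trees.

Emulates sparse-labeled Xenopus forebrain neurons: a spherical soma
with a handful of neurite stems that wander outward as chains of short
segments, bifurcating with a fixed per-segment probability up to a
maximum centrifugal branch level.  Segment lengths are lognormal and
diameters taper multiplicatively at branch points (Rall-style).

Triploidy is applied as a deterministic rescaling of the diploid draw
(same topology, same seed): soma radius x soma_volume_fold^(1/3),
every neurite segment length x neurite_length_fold, every neurite
radius x neurite_diameter_fold.  With the default folds
(1.5, 1.95, sqrt(1.5/1.95)) the neurite volume fold equals the soma
volume fold, as observed for the compartment volumes, while neurite
surface area superscales at sqrt(1.5 * 1.95) ≈ 1.71.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..swc import NEURITE, SOMA, NeuronTree

DIPLOID = "diploid"
TRIPLOID = "triploid"


@dataclass
class PloidyFactors:
    soma_volume_fold: float = 1.5
    neurite_length_fold: float = 1.95
    neurite_diameter_fold: float = math.sqrt(1.5 / 1.95)


@dataclass
class NeuronSimParams:
    """Generator settings for one synthetic neuron population.

    Defaults are calibrated so that a diploid neuron carries roughly
    five times more membrane surface on its neurites than on its soma,
    the partition observed for the profiled forebrain neurons, and so
    that ``neurite_length_fold * neurite_diameter_fold**2 ==
    soma_volume_fold`` (neurite and soma volume share one fold).
    """

    soma_radius_mean: float = 6.0          # μm, lognormal location
    soma_radius_cv: float = 0.10
    n_stems: int = 3
    branch_prob: float = 0.18              # per segment, below max level
    terminate_prob: float = 0.10           # per segment
    segment_length_mean: float = 8.0       # μm
    segment_length_cv: float = 0.30
    max_branch_level: int = 5
    stem_diameter_mean: float = 1.3        # μm
    stem_diameter_cv: float = 0.10
    taper_ratio: float = 0.85              # child/parent diameter at branch
    direction_jitter: float = 0.35         # rad sd of the segment random walk
    max_segments: int = 4000               # hard cap against runaway growth
    ploidy_factors: PloidyFactors = field(default_factory=PloidyFactors)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("soma_radius_mean", "segment_length_mean", "stem_diameter_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.branch_prob < 1.0:
            raise ValueError("branch_prob must be in [0, 1)")
        if not 0.0 <= self.terminate_prob <= 1.0:
            raise ValueError("terminate_prob must be in [0, 1]")
        if not 0.0 < self.taper_ratio <= 1.0:
            raise ValueError("taper_ratio must be in (0, 1]")
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        f = self.ploidy_factors
        if min(f.soma_volume_fold, f.neurite_length_fold, f.neurite_diameter_fold) <= 0:
            raise ValueError("ploidy factors must be positive")


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw with arithmetic mean ``mean`` and coefficient of variation ``cv``."""
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _jitter_direction(rng: np.random.Generator, d: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return d
    v = d + rng.normal(0.0, sd, size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else d


def _stem_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n roughly spread unit vectors (random, with resampling to avoid overlap)."""
    dirs = []
    for _ in range(n):
        for _ in range(64):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if all(float(v @ d) < 0.85 for d in dirs):
                break
        dirs.append(v)
    return np.asarray(dirs)


def simulate_neuron(
    params: NeuronSimParams,
    ploidy: str = DIPLOID,
    seed: int | None = None,
) -> NeuronTree:
    """Grow one synthetic neuron tree, reproducible under a fixed seed.

    ``ploidy`` selects whether the triploid rescaling factors are applied
    to the (seed-identical) diploid draw.
    """
    params.validate()
    if ploidy not in (DIPLOID, TRIPLOID):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    r_soma = _lognormal(rng, params.soma_radius_mean, params.soma_radius_cv)
    xyz = [np.zeros(3)]
    radius = [r_soma]
    node_type = [SOMA]
    parent = [-1]

    stem_dirs = _stem_directions(rng, params.n_stems)
    # branch tips: (parent node index, position, direction, level, radius)
    tips = []
    for s in range(params.n_stems):
        d = stem_dirs[s]
        stem_r = _lognormal(rng, params.stem_diameter_mean, params.stem_diameter_cv) / 2.0
        tips.append((0, np.zeros(3) + d * r_soma, d, 1, stem_r))

    n_segments = 0
    while tips and n_segments < params.max_segments:
        parent_idx, pos, d, level, r = tips.pop(0)
        seg_len = _lognormal(rng, params.segment_length_mean, params.segment_length_cv)
        d = _jitter_direction(rng, d, params.direction_jitter)
        new_pos = pos + d * seg_len
        xyz.append(new_pos)
        radius.append(r)
        node_type.append(NEURITE)
        parent.append(parent_idx)
        node = len(xyz) - 1
        n_segments += 1

        u = rng.uniform()
        can_branch = level < params.max_branch_level
        p_branch = params.branch_prob if can_branch else 0.0
        p_term = params.terminate_prob if can_branch else (
            params.terminate_prob + params.branch_prob
        )
        if u < p_branch:
            child_r = r * params.taper_ratio
            for _ in range(2):
                cd = _jitter_direction(rng, d, params.direction_jitter + 0.45)
                tips.append((node, new_pos, cd, level + 1, child_r))
        elif u < p_branch + p_term:
            pass  # terminal point
        else:
            tips.append((node, new_pos, d, level, r))

    tree = NeuronTree(
        np.arange(len(xyz)), np.asarray(parent),
        np.asarray(node_type), np.asarray(xyz), np.asarray(radius),
        metadata=dict(ploidy=ploidy),
    )
    if ploidy == TRIPLOID:
        f = params.ploidy_factors
        tree = tree.rescaled(
            length_factor=f.neurite_length_fold,
            neurite_radius_factor=f.neurite_diameter_fold,
            soma_radius_factor=f.soma_volume_fold ** (1.0 / 3.0),
        )
        tree.metadata["ploidy"] = TRIPLOID
    return tree


def simulate_population(
    params: NeuronSimParams,
    n_neurons: int,
    ploidy: str,
    seed: int,
) -> list[NeuronTree]:
    """Population of i.i.d. neurons; neuron i of either ploidy shares seed."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_neurons)
    out = []
    for i, s in enumerate(seeds):
        t = simulate_neuron(params, ploidy=ploidy, seed=int(s))
        t.metadata.update(neuron_id=f"{ploidy}_{i:03d}")
        out.append(t)
    return out
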