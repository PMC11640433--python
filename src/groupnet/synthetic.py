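"""Synthetic focal point-sampling datasets.

The generator emulates a focal-follow design over a latent dyadic
association model: each individual is the focal of
``follows_per_individual`` follows of ``samples_per_follow``
one-minute instantaneous samples (defaults 18 x 10).  In each sample,
every non-focal joins the focal's proximity party independently with
probability

    clip(p_pair(focal, j) * g_focal * g_j, 0, 1)

where ``p_pair`` is ``p_within`` for same-species dyads and
``p_between`` for mixed-species dyads (optionally damped by a
shared-space overlap factor, or by a cross-clique multiplier when one
species is split into subgroups), and the ``g`` are per-individual
log-normal gregariousness multipliers with mean 1.

Default compositions mirror a two-species colony: 18 + 9 (West-like)
and 17 + 17 (East-like).  With species-assortative defaults
(``p_within >> p_between``) the generated data reproduce the
qualitative structure the analysis targets: dense within-species
blocks, sparse mixed-species ties.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import yaml

from .observation import IndividualRecord, PointSample, ValidationError

WEST_LIKE_SIZES = {"capuchin": 18, "squirrel_monkey": 9}
EAST_LIKE_SIZES = {"capuchin": 17, "squirrel_monkey": 17}


@dataclasses.dataclass(frozen=True)
class SubgroupSplit:
    """Split one species into cliques with damped cross-clique association."""

    species: str
    n_subgroups: int
    cross_multiplier: float = 0.1


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    species_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(WEST_LIKE_SIZES)
    )
    p_within: float = 0.15
    p_between: float = 0.01
    gregariousness_sd: float = 0.0
    subgroup_split: SubgroupSplit | None = None
    mixed_space_overlap: float | None = None
    follows_per_individual: int = 18
    samples_per_follow: int = 10
    group_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between):
            if not 0 <= p <= 1:
                raise ValidationError("association probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.species_sizes.values()):
            raise ValidationError("species sizes must be >= 1")
        if self.follows_per_individual < 1 or self.samples_per_follow < 1:
            raise ValidationError("follows and samples per follow must be >= 1")

    @property
    def n_individuals(self) -> int:
        return sum(self.species_sizes.values())

    @property
    def periods_per_individual(self) -> int:
        return self.follows_per_individual * self.samples_per_follow

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.get("subgroup_split") is not None:
            data["subgroup_split"] = SubgroupSplit(**data["subgroup_split"])
        return cls(**data)


def west_like(**overrides) -> SyntheticConfig:
    overrides.setdefault("group_label", "West-like")
    return SyntheticConfig(species_sizes=dict(WEST_LIKE_SIZES), **overrides)


def east_like(**overrides) -> SyntheticConfig:
    overrides.setdefault("group_label", "East-like")
    return SyntheticConfig(species_sizes=dict(EAST_LIKE_SIZES), **overrides)


def _abbrev(species: str) -> str:
    parts = species.replace("-", "_").split("_")
    return "".join(p[0] for p in parts if p) if len(parts) > 1 else species[:3]


def generate_roster(config: SyntheticConfig) -> list[IndividualRecord]:
    """Deterministic roster for a config: ids, species, random sexes."""
    rng = np.random.default_rng(config.seed)
    roster = []
    for species, size in config.species_sizes.items():
        prefix = _abbrev(species)
        for k in range(size):
            roster.append(
                IndividualRecord(
                    id=f"{prefix}{k + 1:02d}",
                    species=species,
                    sex=str(rng.choice(["F", "M"])),
                    group=config.group_label,
                    age=float(rng.integers(1, 20)),
                )
            )
    return roster


def _pair_probabilities(
    roster: Sequence[IndividualRecord], config: SyntheticConfig
) -> np.ndarray:
    n = len(roster)
    species = [r.species for r in roster]
    probs = np.empty((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if species[i] == species[j]:
                probs[i, j] = config.p_within
            else:
                probs[i, j] = config.p_between
                if config.mixed_space_overlap is not None:
                    probs[i, j] *= config.mixed_space_overlap
    if config.subgroup_split is not None:
        split = config.subgroup_split
        members = [i for i in range(n) if species[i] == split.species]
        clique = {m: k % split.n_subgroups for k, m in enumerate(members)}
        for i in members:
            for j in members:
                if i != j and clique[i] != clique[j]:
                    probs[i, j] = config.p_within * split.cross_multiplier
    np.fill_diagonal(probs, 0.0)
    return probs


def _gregariousness(n: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.gregariousness_sd == 0:
        return np.ones(n)
    sd = config.gregariousness_sd
    # log-normal with exact mean 1
    return np.exp(rng.normal(-0.5 * sd**2, sd, size=n))


def simulate_point_samples(
    roster: Sequence[IndividualRecord], config: SyntheticConfig
) -> list[PointSample]:
    """Simulate the full focal schedule; reproducible per seed.

    Follows are scheduled round-robin over individuals so every
    individual accrues follows evenly through the run.  Neighbor draws
    are independent Bernoulli per dyad per sample; a party is the focal
    plus whoever joined.
    """
    rng = np.random.default_rng(config.seed)
    n = len(roster)
    probs = _pair_probabilities(roster, config)
    greg = _gregariousness(n, config, rng)
    joint = np.clip(probs * greg[:, None] * greg[None, :], 0.0, 1.0)
    samples: list[PointSample] = []
    ids = [r.id for r in roster]
    for follow in range(config.follows_per_individual):
        for focal_idx, focal in enumerate(ids):
            row = joint[focal_idx]
            draws = rng.random((config.samples_per_follow, n)) < row
            draws[:, focal_idx] = False
            for minute in range(config.samples_per_follow):
                neighbors = frozenset(ids[j] for j in np.flatnonzero(draws[minute]))
                period = f"{focal}_f{follow + 1:02d}_m{minute + 1:02d}"
                samples.append(PointSample(period, focal, neighbors))
    return samples


def expected_sri(config: SyntheticConfig, species_a: str, species_b: str) -> float:
    """Plug-in expected SRI for a dyad class under the homogeneous model.

    Evaluates E[x] / (E[x] + E[ya] + E[yb]) exactly from the sampling
    schedule — an approximation to E[SRI] (the ratio of expectations,
    not the expectation of the ratio), good to a few percent at the
    default schedule.  Requires ``gregariousness_sd == 0`` and no
    subgroup split (the closed form assumes exchangeable individuals
    within species).
    """
    if config.gregariousness_sd != 0:
        raise ValidationError("expected_sri requires a homogeneous model (sd = 0)")
    if config.subgroup_split is not None:
        raise ValidationError("expected_sri does not support subgroup splits")
    sizes = config.species_sizes
    for s in (species_a, species_b):
        if s not in sizes:
            raise ValidationError(f"unknown species {s!r}")
    if species_a == species_b and sizes[species_a] < 2:
        raise ValidationError(f"species {species_a!r} has no within-species dyad")
    between = config.p_between * (
        config.mixed_space_overlap if config.mixed_space_overlap is not None else 1.0
    )

    def pair_p(sa: str, sb: str) -> float:
        return config.p_within if sa == sb else between

    periods = config.periods_per_individual
    p_ab = pair_p(species_a, species_b)
    e_x = 2 * periods * p_ab
    e_ya = periods * (1 - p_ab)
    e_yb = periods * (1 - p_ab)
    for species, size in sizes.items():
        n_others = size - (species == species_a) - (species == species_b)
        if n_others <= 0:
            continue
        p_oa = pair_p(species, species_a)
        p_ob = pair_p(species, species_b)
        e_x += n_others * periods * p_oa * p_ob
        e_ya += n_others * periods * p_oa * (1 - p_ob)
        e_yb += n_others * periods * p_ob * (1 - p_oa)
    denom = e_x + e_ya + e_yb
    return e_x / denom if denom > 0 else 0.0
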