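"""Synthetic clinical datasets with planted ground truth.

The generator emulates the structure of a reference TCM observation dataset
for hepatocellular carcinoma: 300 samples over 147 symptom columns arranged into 27
syndrome groups of known sizes, a mix of mutually-exclusive (one-hot with a
"none" state) and concurrent (independent binary/small-ordinal) groups, and
a positive score built as a weighted sum of a planted subset of syndrome
values plus Gaussian noise.  Because the planted subset is known, ranking
and subset-search code can be validated by recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import load_group_specs
from .hierarchy import GroupSpec, SymptomTable, build_hierarchy

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "hcc_shaped_spec",
           "default_group_sizes", "default_exclusive_flags"]

#: the reference configuration's 27 group sizes (sum = 147 symptom columns)
DEFAULT_GROUP_SIZES = (
    4, 4, 3, 5, 3, 7, 5, 8, 8, 1, 1, 1, 1, 2, 13, 4, 16, 7, 10, 2, 3, 10,
    1, 1, 1, 13, 13,
)
#: groups coded one-hot in the raw data: lip color, tongue color,
#: coated tongue color (indices 0, 1, 4)
DEFAULT_EXCLUSIVE = tuple(i in (0, 1, 4) for i in range(27))
#: planted relevant syndromes: complexion, facial features, sternocostal and
#: abdominal pain, diet, skin of the limbs — large, informative groups
DEFAULT_PLANTED = (7, 14, 16, 17, 21)

#: probability that no member of an exclusive group is positive in a row
NONE_STATE_PROB = 0.4


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape, planted signal and noise level of one synthetic dataset."""

    n_samples: int = 300
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    exclusive_flags: tuple[bool, ...] = DEFAULT_EXCLUSIVE
    planted_relevant: tuple[int, ...] = DEFAULT_PLANTED
    weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 0.5
    positivity: float = 0.25  # per-symptom chance of being positive
    max_level: int = 3  # ordinal symptoms range 0..max_level
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.exclusive_flags):
            raise ValueError("one exclusivity flag per group required")
        if not set(self.planted_relevant) <= set(range(len(self.group_sizes))):
            raise ValueError("planted_relevant must index the groups")
        if len(self.weights) != len(self.planted_relevant):
            raise ValueError("one weight per planted group required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    planted_relevant: tuple[int, ...]
    weights: tuple[float, ...]
    syndrome_values: np.ndarray = field(repr=False)
    noiseless_score: np.ndarray = field(repr=False)


def _group_names(spec: SyntheticSpec) -> list[GroupSpec]:
    """Group specs with the reference names when sizes match, else generic."""
    bundled = load_group_specs()
    if (
        tuple(len(g.member_columns) for g in bundled) == spec.group_sizes
        and tuple(g.exclusive for g in bundled) == spec.exclusive_flags
    ):
        return [GroupSpec(g.group_name, g.member_columns, g.exclusive)
                for g in bundled]
    groups = []
    for gi, (size, excl) in enumerate(zip(spec.group_sizes, spec.exclusive_flags)):
        members = [f"g{gi}_s{j}" for j in range(size)]
        groups.append(GroupSpec(f"group_{gi}", members, excl))
    return groups


def generate(spec: SyntheticSpec) -> tuple[SymptomTable, list[GroupSpec], GroundTruth]:
    """Draw one synthetic symptom table with a planted positive score.

    Exclusive groups are one-hot categorical (a "none" state included);
    concurrent groups mix binary and small-ordinal symptoms, each positive
    independently with probability ``positivity``.  The positive score is
    ``sum_g w_g * syndrome_g`` over the planted groups plus
    ``N(0, noise_sd^2)`` noise, clipped at zero (scores are non-negative by
    construction of the instrument).
    """
    rng = np.random.default_rng(spec.seed)
    groups = _group_names(spec)
    n = spec.n_samples

    columns: list[np.ndarray] = []
    for g, size in zip(groups, spec.group_sizes):
        if g.exclusive:
            # categorical: state 0 = none, else exactly one member positive
            state = rng.choice(
                size + 1,
                size=n,
                p=[NONE_STATE_PROB] + [(1 - NONE_STATE_PROB) / size] * size,
            )
            block = np.zeros((n, size), dtype=int)
            rows = np.nonzero(state > 0)[0]
            block[rows, state[rows] - 1] = 1
        else:
            levels = rng.integers(1, spec.max_level + 1, size=size)
            block = np.zeros((n, size), dtype=int)
            for j in range(size):
                positive = rng.random(n) < spec.positivity
                block[positive, j] = rng.integers(
                    1, levels[j] + 1, size=positive.sum()
                )
        columns.append(block)
    values = np.hstack(columns)
    names = [m for g in groups for m in g.member_columns]

    # syndrome values for the planted score: row sums for concurrent groups;
    # for exclusive groups the positive-member indicator block row sum is the
    # occurrence flag, which is what the score instrument responds to
    offsets = np.cumsum([0] + list(spec.group_sizes))
    syndromes = np.column_stack(
        [values[:, offsets[i]:offsets[i + 1]].sum(axis=1)
         for i in range(len(spec.group_sizes))]
    )
    signal = np.zeros(n)
    for w, gi in zip(spec.weights, spec.planted_relevant):
        signal = signal + w * syndromes[:, gi]
    score = signal + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else signal
    score = np.maximum(score, 0.0)

    table = SymptomTable(values, score, names)
    truth = GroundTruth(spec.planted_relevant, spec.weights, syndromes, signal)
    return table, groups, truth


def hcc_shaped_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reference-shaped default: 300 samples, 27 groups over 147 symptoms,
    three exclusive groups, five planted relevant syndromes."""
    return SyntheticSpec(seed=seed, **overrides)


def default_group_sizes() -> tuple[int, ...]:
    return DEFAULT_GROUP_SIZES


def default_exclusive_flags() -> tuple[bool, ...]:
    return DEFAULT_EXCLUSIVE


def build_synthetic_hierarchy(spec: SyntheticSpec):
    """Convenience: generate + aggregate in one call."""
    table, groups, truth = generate(spec)
    return build_hierarchy(table, groups), truth
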