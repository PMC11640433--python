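"""Permutation inference for association data and network metrics.

Two resampling routes:

* **data-stream randomization** — a serial chain of swaps on the GBI
  that exchanges two individuals between two periods while preserving
  every individual's number of observations (column sums) and every
  period's party size (row sums).  A test statistic of the association
  matrix is recorded along the chain, giving a null distribution of
  networks with the observed sampling structure but randomized
  membership.
* **node-label permutation t-test** — the per-individual values of a
  network metric are compared between two species by shuffling the
  species labels and recomputing the mean difference.

p-values are the proportion of null values equal to or more extreme
than the observed statistic.  The raw proportion is the primary value
(it can be 0 at finite iterations); the add-one variant (b+1)/(N+1),
which is bounded away from 0, is always reported alongside.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .association import AssociationMatrix, association_matrix
from .observation import GroupByIndividualMatrix, ValidationError

_EQ_ATOL = 1e-12


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null, and p-values."""

    observed: float
    null_values: np.ndarray
    iterations: int
    seed: int | None
    p_lower: float
    p_upper: float
    p_two_tailed: float
    p_lower_add_one: float
    p_upper_add_one: float
    p_two_tailed_add_one: float
    add_one_correction: bool
    method: str
    settings: dict

    def summary(self, include_null: bool = False) -> dict:
        null = np.asarray(self.null_values, dtype=float)
        out = {
            "observed": self.observed,
            "iterations": self.iterations,
            "seed": self.seed,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "p_two_tailed": self.p_two_tailed,
            "p_lower_add_one": self.p_lower_add_one,
            "p_upper_add_one": self.p_upper_add_one,
            "p_two_tailed_add_one": self.p_two_tailed_add_one,
            "add_one_correction": self.add_one_correction,
            "method": self.method,
            "settings": self.settings,
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
            "null_min": float(null.min()),
            "null_max": float(null.max()),
        }
        if include_null:
            out["null_values"] = null.tolist()
        return out

    def to_json(self, path: str | Path, include_null: bool = False) -> None:
        Path(path).write_text(json.dumps(self.summary(include_null), indent=2))


def _tail_ps(observed: float, null: np.ndarray, two_tailed: str) -> dict[str, float]:
    n = null.size
    lower = int((null <= observed + _EQ_ATOL).sum())
    upper = int((null >= observed - _EQ_ATOL).sum())
    if two_tailed == "absolute":
        extreme = int((np.abs(null) >= abs(observed) - _EQ_ATOL).sum())
        p_two = extreme / n
        p_two_add = (extreme + 1) / (n + 1)
    else:  # doubled smaller tail, for nulls not centered at zero
        p_two = min(1.0, 2.0 * min(lower, upper) / n)
        p_two_add = min(1.0, 2.0 * (min(lower, upper) + 1) / (n + 1))
    return {
        "p_lower": lower / n,
        "p_upper": upper / n,
        "p_two_tailed": p_two,
        "p_lower_add_one": (lower + 1) / (n + 1),
        "p_upper_add_one": (upper + 1) / (n + 1),
        "p_two_tailed_add_one": p_two_add,
    }


def datastream_swap(
    gbi: GroupByIndividualMatrix,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> GroupByIndividualMatrix:
    """Return a copy of the GBI after one margin-preserving swap."""
    out = gbi.copy()
    _swap_in_place(out.matrix, rng, max_tries)
    return out


def _swap_in_place(matrix: np.ndarray, rng: np.random.Generator, max_tries: int) -> None:
    """Exchange individuals A, B between periods p, q; A in p only, B in q only.

    Because each period is a single party and A is absent from q (and B
    from p), the swapped individuals are never co-members of either
    party.  Row and column sums are preserved exactly.
    """
    n_periods = matrix.shape[0]
    if n_periods < 2:
        raise ValidationError("data-stream swap needs at least two periods")
    for _ in range(max_tries):
        p, q = rng.choice(n_periods, size=2, replace=False)
        only_p = np.flatnonzero(matrix[p] & ~matrix[q])
        only_q = np.flatnonzero(matrix[q] & ~matrix[p])
        if only_p.size == 0 or only_q.size == 0:
            continue
        a = only_p[rng.integers(only_p.size)]
        b = only_q[rng.integers(only_q.size)]
        matrix[p, a], matrix[q, a] = 0, 1
        matrix[q, b], matrix[p, b] = 0, 1
        return
    raise ValidationError(
        f"no valid data-stream swap found in {max_tries} tries; "
        "the GBI is degenerate (identical or nested periods)"
    )


def network_randomization_test(
    gbi: GroupByIndividualMatrix,
    statistic: Callable[[AssociationMatrix], float],
    iterations: int = 1000,
    burn_in: int = 1000,
    swaps_per_iteration: int = 10,
    seed: int | None = None,
    method: str = "datastream",
) -> PermutationResult:
    """Compare an association-matrix statistic against randomized networks.

    ``datastream`` (default) runs one serial swap chain: ``burn_in``
    swaps first, then the statistic is recorded after every
    ``swaps_per_iteration`` further swaps, ``iterations`` times.
    ``node`` instead permutes node identities of the observed
    association matrix independently each iteration (a coarser null
    that keeps the network fixed and randomizes who is who).
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(statistic(association_matrix(gbi)))
    if not np.isfinite(observed):
        raise ValidationError("observed statistic is not finite")
    null = np.empty(iterations, dtype=float)
    if method == "datastream":
        work = gbi.copy()
        for _ in range(burn_in):
            _swap_in_place(work.matrix, rng, max_tries=1000)
        for it in range(iterations):
            for _ in range(swaps_per_iteration):
                _swap_in_place(work.matrix, rng, max_tries=1000)
            null[it] = statistic(association_matrix(work))
    elif method == "node":
        base = association_matrix(gbi)
        for it in range(iterations):
            perm = rng.permutation(base.n)
            shuffled = AssociationMatrix(
                base.values[np.ix_(perm, perm)], base.ids, species=base.species
            )
            null[it] = statistic(shuffled)
    else:
        raise ValidationError("method must be 'datastream' or 'node'")
    if not np.isfinite(null).all():
        raise ValidationError("null statistic is not finite")
    ps = _tail_ps(observed, null, two_tailed="doubled")
    return PermutationResult(
        observed=observed,
        null_values=null,
        iterations=iterations,
        seed=seed,
        add_one_correction=False,
        method=f"network_randomization:{method}",
        settings={
            "burn_in": burn_in if method == "datastream" else None,
            "swaps_per_iteration": swaps_per_iteration if method == "datastream" else None,
        },
        **ps,
    )


def node_label_permutation_test(
    values: Sequence[float],
    labels: Sequence[str],
    iterations: int = 1000,
    seed: int | None = None,
    levels: tuple[str, str] | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation t-test of a metric between two classes of nodes.

    Observed statistic: mean(level 1) - mean(level 2); levels default to
    sorted label order.  NaN values (metrics undefined for a node) are
    dropped together with their labels.  Two-tailed p is the proportion
    of |null| >= |observed|.

    With ``exhaustive=True`` the null enumerates every distinct
    assignment of labels to values (all n-choose-n1 splits) instead of
    ``iterations`` random shuffles, giving exact p-values for small
    inputs.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=object)
    if vals.shape != labs.shape:
        raise ValidationError("values and labels must align")
    keep = ~np.isnan(vals)
    vals, labs = vals[keep], labs[keep]
    if levels is None:
        uniq = sorted(set(labs))
        if len(uniq) != 2:
            raise ValidationError(f"need exactly two label levels, got {uniq}")
        levels = (uniq[0], uniq[1])
    mask1 = labs == levels[0]
    mask2 = labs == levels[1]
    if not mask1.any() or not mask2.any():
        raise ValidationError(f"both levels {levels} need at least one member")
    observed = float(vals[mask1].mean() - vals[mask2].mean())
    n1 = int(mask1.sum())
    pool_mask = mask1 | mask2
    pool = vals[pool_mask]
    if exhaustive:
        total = pool.sum()
        null = np.array(
            [
                (s := sum(combo)) / n1 - (total - s) / (pool.size - n1)
                for combo in itertools.combinations(pool, n1)
            ],
            dtype=float,
        )
        iterations = null.size
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(iterations, dtype=float)
        for it in range(iterations):
            perm = rng.permutation(pool.size)
            null[it] = pool[perm[:n1]].mean() - pool[perm[n1:]].mean()
    ps = _tail_ps(observed, null, two_tailed="absolute")
    return PermutationResult(
        observed=observed,
        null_values=null,
        iterations=iterations,
        seed=seed,
        add_one_correction=False,
        method="node_label_permutation",
        settings={
            "levels": list(levels),
            "n": [n1, int(mask2.sum())],
            "exhaustive": exhaustive,
        },
        **ps,
    )


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Family-wise adjusted significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("number of comparisons must be >= 1")
    return alpha / m
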