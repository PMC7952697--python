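"""Shell-size analyses: paired differences, permutation correlation,
within-quadrat random pairing, and spatial segregation by size.

All resampling procedures require an explicit seed; defaults follow the
field-study design of 10 000 permutations / iterations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import CopulationRecord, IndividualRecord, classify_pair
from .taxonomy import FEMALE, MALE, Stratum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedSizeResult:
    """Paired t-test of active-minus-passive shell height for one group."""

    stratum: Stratum
    active_species: str
    passive_class: str
    n_pairs: int
    mean_difference_mm: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int
    n_perm: int
    exact: bool


@dataclass(frozen=True)
class RandomPairingResult:
    """Monte-Carlo null for size correlation under within-quadrat random pairing."""

    p_value: float
    observed_r: float
    n_valid: int
    n_dropped: int
    mean_null_r: float


@dataclass(frozen=True)
class SegregationResult:
    """Permutation test of spatial segregation by size across quadrats."""

    stratum: Stratum
    species: str
    observed_mean_rank_variance: float
    p_value: float
    n_perm: int
    seed: int
    n_samples_used: int
    degenerate: bool = False


def paired_size_difference(
    records: Sequence[CopulationRecord], min_pairs: int = 5
) -> list[PairedSizeResult]:
    """Paired t-tests of partner shell sizes in heterosexual pairs.

    Groups by active species, stratum and mating class; male-male pairs
    are excluded, as are records lacking either height (logged).
    Groups with fewer than ``min_pairs`` pairs are skipped with a log
    entry, following the study's >= 5 pairs rule.
    """
    groups: dict[tuple, list[tuple[float, float]]] = {}
    n_missing = 0
    for rec in records:
        if rec.passive.status == MALE:
            continue
        if rec.active_height_mm is None or rec.passive_height_mm is None:
            n_missing += 1
            continue
        key = (rec.stratum, rec.active.species, classify_pair(rec).value)
        groups.setdefault(key, []).append(
            (rec.active_height_mm, rec.passive_height_mm)
        )
    if n_missing:
        logger.info("paired_size_difference: %d records without heights skipped", n_missing)
    out = []
    for (stratum, species, mclass), pairs in sorted(groups.items()):
        if len(pairs) < min_pairs:
            logger.info(
                "paired_size_difference: %s %s %s skipped (%d < %d pairs)",
                stratum, species, mclass, len(pairs), min_pairs,
            )
            continue
        a, p = np.array(pairs).T
        if np.allclose(a - p, (a - p)[0]):
            # zero-variance differences: t undefined or infinite
            t, pval = (0.0, 1.0) if np.allclose(a, p) else (math.inf, 0.0)
        else:
            t, pval = stats.ttest_rel(a, p)
        out.append(
            PairedSizeResult(
                stratum=stratum,
                active_species=species,
                passive_class=mclass,
                n_pairs=len(pairs),
                mean_difference_mm=float(np.mean(a - p)),
                t_statistic=float(t),
                p_value=float(pval),
            )
        )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def size_correlation_perm(
    active_heights: Sequence[float],
    passive_heights: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool | None = None,
) -> CorrelationResult:
    """Pearson correlation of partner sizes with a permutation p-value.

    Passive heights are shuffled against active heights; p is the
    fraction of permutations with |r*| >= |r_obs| (+1-corrected for the
    Monte-Carlo version).  When ``exact`` is requested — or n_perm
    covers all n! arrangements of a small sample — every permutation is
    enumerated and p is the exact fraction.
    """
    x = np.asarray(active_heights, dtype=float)
    y = np.asarray(passive_heights, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in heights: correlation undefined")
    r_obs = _pearson(x, y)
    n = len(x)
    if exact is None:
        exact = n <= 9 and n_perm >= math.factorial(n)
    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        hits = sum(
            abs(_pearson(x, y[list(perm)])) >= abs(r_obs) - 1e-12
            for perm in itertools.permutations(range(n))
        )
        return CorrelationResult(
            r=r_obs, p_value=hits / math.factorial(n), n_pairs=n,
            n_perm=math.factorial(n), exact=True,
        )
    if seed is None:
        raise ValueError("Monte-Carlo permutation requires an explicit seed")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += abs(_pearson(x, rng.permutation(y))) >= abs(r_obs) - 1e-12
    return CorrelationResult(
        r=r_obs, p_value=(hits + 1) / (n_perm + 1), n_pairs=n, n_perm=n_perm,
        exact=False,
    )


def random_pairing_mc(
    census: Sequence[IndividualRecord],
    observed_r: float,
    species: str,
    stratum: Stratum,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> RandomPairingResult:
    """Null distribution of size correlation under within-quadrat random mating.

    Each iteration pairs males with mature conspecific females at
    random, without replacement, within every quadrat (up to the
    smaller sex count), pools the pairs across quadrats and computes
    Pearson r of partner sizes.  The p-value is the (+1-corrected)
    proportion of iterations with |r*| >= |observed_r|.  Iterations
    yielding fewer than 3 pooled pairs, or degenerate heights, are
    dropped and counted.
    """
    if seed is None:
        raise ValueError("random_pairing_mc requires an explicit seed")
    quadrats: dict[str, tuple[list[float], list[float]]] = {}
    for rec in census:
        if rec.stratum != stratum or not rec.older_than_one_year:
            continue
        if rec.category.species != species:
            continue
        males, females = quadrats.setdefault(rec.quadrat_id, ([], []))
        if rec.category.status == MALE:
            males.append(rec.shell_height_mm)
        elif rec.category.status == FEMALE:
            females.append(rec.shell_height_mm)
    # canonical content-based order: p-values do not depend on quadrat labels
    usable = sorted(
        (
            (np.array(sorted(m)), np.array(sorted(f)))
            for m, f in quadrats.values()
            if len(m) >= 1 and len(f) >= 1
        ),
        key=lambda mf: (mf[0].tolist(), mf[1].tolist()),
    )
    if not usable:
        raise ValueError(
            f"no quadrat with both {species} males and mature females in {stratum}"
        )
    rng = np.random.default_rng(seed)
    hits = 0
    n_valid = 0
    null_sum = 0.0
    for _ in range(n_iter):
        xs: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        for males, females in usable:
            k = min(len(males), len(females))
            xs.append(rng.choice(males, size=k, replace=False))
            ys.append(rng.choice(females, size=k, replace=False))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = _pearson(x, y)
        n_valid += 1
        null_sum += r
        hits += abs(r) >= abs(observed_r) - 1e-12
    if n_valid == 0:
        raise ValueError("all Monte-Carlo iterations degenerate")
    return RandomPairingResult(
        p_value=(hits + 1) / (n_valid + 1),
        observed_r=observed_r,
        n_valid=n_valid,
        n_dropped=n_iter - n_valid,
        mean_null_r=null_sum / n_valid,
    )


def mean_rank_variance(ranks: np.ndarray, sizes: np.ndarray) -> float:
    """Mean over samples of the population variance of 0/1 size ranks."""
    ends = np.cumsum(sizes)
    starts = ends - sizes
    means = np.add.reduceat(ranks, starts) / sizes
    return float(np.mean(means - means**2))  # Bernoulli: var = m - m^2


def segregation_test(
    census: Sequence[IndividualRecord],
    species: str,
    stratum: Stratum,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> SegregationResult:
    """Permutation test of spatial segregation by size across quadrats.

    Individuals of the focal species are split at the stratum-wide
    median shell height (ties to the small class): rank 0 below the
    median, rank 1 otherwise.  The statistic is the mean over quadrats
    (with >= 2 individuals) of the per-quadrat variance of ranks; low
    values mean quadrats are internally size-homogeneous, i.e. spatial
    segregation by size.  The null shuffles ranks across quadrats
    holding quadrat sizes fixed; p = (#{mean variance* < observed} + 1)
    / (n_perm + 1).
    """
    if seed is None:
        raise ValueError("segregation_test requires an explicit seed")
    by_quadrat: dict[str, list[float]] = {}
    for rec in census:
        if (
            rec.stratum == stratum
            and rec.older_than_one_year
            and rec.category.species == species
        ):
            by_quadrat.setdefault(rec.quadrat_id, []).append(rec.shell_height_mm)
    heights_all = [h for hs in by_quadrat.values() for h in hs]
    if not heights_all:
        raise ValueError(f"no {species} individuals in {stratum}")
    median = float(np.median(heights_all))
    samples = {q: hs for q, hs in sorted(by_quadrat.items()) if len(hs) >= 2}
    if len(samples) < 2:
        raise ValueError("need >= 2 quadrats with >= 2 focal individuals")
    sizes = np.array([len(hs) for hs in samples.values()])
    ranks = np.concatenate(
        [(np.array(hs) >= median).astype(float) for hs in samples.values()]
    )
    observed = mean_rank_variance(ranks, sizes)
    degenerate = ranks.min() == ranks.max()

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    ends = np.cumsum(sizes)
    starts = ends - sizes
    means = np.add.reduceat(perms, starts, axis=1) / sizes
    stat_null = np.mean(means - means**2, axis=1)
    p = (np.sum(stat_null < observed - 1e-12) + 1) / (n_perm + 1)
    return SegregationResult(
        stratum=stratum,
        species=species,
        observed_mean_rank_variance=observed,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        n_samples_used=len(samples),
        degenerate=bool(degenerate),
    )
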