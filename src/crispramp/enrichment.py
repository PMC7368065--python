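"""Selective-depletion enrichment dynamics: cleave wild type, re-amplify, repeat.

One enrichment round exposes every molecule to the effector and then
re-amplifies the survivors to saturation.  With per-round wild-type cleavage
efficiency ``c`` and per-allele escape probability ``pi`` (the chance one
cleavage exposure leaves the allele intact), the survival weight of allele
``a`` is::

    w(a) = 1 - c * (1 - pi(a))

and the post-round fractions are the pre-round fractions reweighted by ``w``
and renormalised (saturating PCR restores total abundance, so only relative
composition matters).  For a two-class pool (mutant fraction ``m``, wild type
``1 - m``, ``pi(wt) = 0``) this reduces to::

    m' = m * w_mut / (m * w_mut + (1 - m) * (1 - c)),    w_mut = 1 - c (1 - pi)

and with full protection (``pi = 1``)::

    m' = m / (m + (1 - m) (1 - c))

i.e. the mutant odds m/(1-m) grow by the factor 1/(1-c) per round — the
exponential sensitivity gain that lets three rounds at c = 0.99 lift a 1e-7
mutant fraction above the ~0.5% sequencing detection limit.

The stochastic variant additionally models the finite template bottleneck:
only a small carryover fraction (2% by default) of each reaction seeds the
next round, so at extreme dilution the mutant lineage can be lost outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .design import EnrichmentGuide
from .seqcore import (
    Deletion,
    EffectorSpec,
    IUPAC,
    Insertion,
    Mutation,
    Substitution,
    WildType,
    iupac_base_match,
)

__all__ = [
    "AlleleClass",
    "AllelePool",
    "RoundParams",
    "EnrichmentTrajectory",
    "EscapeParams",
    "CompleteDepletionError",
    "StochasticDropoutError",
    "enrich_round",
    "enrich_trajectory",
    "stochastic_round",
    "escape_probability",
    "fit_cleavage_efficiency",
    "CleavageFit",
]

_SUM_TOL = 1e-12


class CompleteDepletionError(RuntimeError):
    """Every allele class has survival weight 0 (c = 1 with no escape)."""


class StochasticDropoutError(RuntimeError):
    """All molecules were lost in the sampling/cleavage bottleneck."""


@dataclass(frozen=True)
class AlleleClass:
    """One allele class with its escape probability.

    ``escape`` is the probability pi that a single cleavage exposure leaves
    the allele intact.  Wild type is the cleavage substrate by definition, so
    ``pi(wild_type) == 0`` is enforced.
    """

    label: str
    mutation: Mutation
    escape: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.escape <= 1.0):
            raise ValueError("escape probability outside [0, 1]")
        if isinstance(self.mutation, WildType) and self.escape != 0.0:
            raise ValueError("wild type must have escape 0 (it is the substrate)")

    @property
    def is_wild_type(self) -> bool:
        return isinstance(self.mutation, WildType)


@dataclass(frozen=True)
class AllelePool:
    """Relative fractions of allele classes at one locus.

    ``total_molecules`` is only used by the stochastic simulator and denotes
    the (renormalised) molecule count the pool represents.
    """

    classes: tuple[AlleleClass, ...]
    fractions: tuple[float, ...]
    total_molecules: int | None = None

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.fractions):
            raise ValueError("classes/fractions length mismatch")
        if any(f < 0 for f in self.fractions):
            raise ValueError("negative fraction")
        if abs(sum(self.fractions) - 1.0) > _SUM_TOL:
            raise ValueError(f"fractions sum to {sum(self.fractions)!r}, not 1")
        if self.total_molecules is not None and self.total_molecules < 1:
            raise ValueError("total_molecules must be >= 1")

    @classmethod
    def two_class(
        cls,
        mutant_fraction: float,
        escape: float = 1.0,
        mutation: Mutation | None = None,
        total_molecules: int | None = None,
    ) -> "AllelePool":
        """Wild type plus a single mutant class (default: fully protected)."""
        mut = mutation if mutation is not None else Deletion(0, 1)
        return cls(
            classes=(
                AlleleClass("wild_type", WildType(), 0.0),
                AlleleClass("mutant", mut, escape),
            ),
            fractions=(1.0 - mutant_fraction, mutant_fraction),
            total_molecules=total_molecules,
        )

    @property
    def mutant_fraction(self) -> float:
        return sum(f for a, f in zip(self.classes, self.fractions) if not a.is_wild_type)

    def fraction_of(self, label: str) -> float:
        for a, f in zip(self.classes, self.fractions):
            if a.label == label:
                return f
        raise KeyError(label)


@dataclass(frozen=True)
class RoundParams:
    """Per-round enrichment parameters.

    c : wild-type cleavage efficiency per round, in [0, 1].
    carryover : fraction of the reaction used as next-round template
        (default 0.02, i.e. 2% v/v).
    rounds_max : cap on enrichment rounds (default 3; repeated PCR accumulates
        polymerase/sequencing errors, so deeper enrichment is untrustworthy).
    detection_limit : amplicon-sequencing detection floor in percent
        (default 0.5%).
    """

    c: float
    carryover: float = 0.02
    rounds_max: int = 3
    detection_limit: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("c outside [0, 1]")
        if not (0.0 < self.carryover <= 1.0):
            raise ValueError("carryover outside (0, 1]")
        if self.rounds_max < 1:
            raise ValueError("rounds_max must be >= 1")
        if self.detection_limit < 0:
            raise ValueError("negative detection limit")


@dataclass(frozen=True)
class EnrichmentTrajectory:
    """Per-round pool snapshots and fold increase of the mutant fraction.

    ``fold[k] = mutant_fraction[k] / mutant_fraction[0]``; when the pool
    starts with no mutant the fold is reported as 1 by convention.
    ``detection_round`` is the first round index at which the mutant frequency
    reaches the detection limit (None if never).
    """

    pools: tuple[AllelePool, ...]
    fold: tuple[float, ...]
    detection_round: int | None

    @property
    def mutant_fractions(self) -> tuple[float, ...]:
        return tuple(p.mutant_fraction for p in self.pools)

    @property
    def rounds(self) -> int:
        return len(self.pools) - 1


def _survival_weights(pool: AllelePool, c: float) -> np.ndarray:
    pis = np.array([a.escape for a in pool.classes])
    return 1.0 - c * (1.0 - pis)


def enrich_round(pool: AllelePool, params: RoundParams) -> AllelePool:
    """One deterministic cleave-and-renormalise round."""
    w = _survival_weights(pool, params.c)
    weighted = np.asarray(pool.fractions) * w
    total = weighted.sum()
    if total <= 0.0:
        raise CompleteDepletionError(
            "complete depletion: every allele class is cleaved with certainty"
        )
    new = weighted / total
    new = new / new.sum()  # guard against accumulated rounding
    return replace(pool, fractions=tuple(new))


def enrich_trajectory(
    pool: AllelePool,
    params: RoundParams,
    rounds: int,
    allow_extra_rounds: bool = False,
) -> EnrichmentTrajectory:
    """Iterate :func:`enrich_round` and track mutant-fraction fold increase."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds > params.rounds_max and not allow_extra_rounds:
        raise ValueError(
            f"rounds={rounds} exceeds rounds_max={params.rounds_max}; deeper "
            "enrichment accumulates amplification errors — pass "
            "allow_extra_rounds=True to override"
        )
    pools = [pool]
    for _ in range(rounds):
        pools.append(enrich_round(pools[-1], params))
    m0 = pool.mutant_fraction
    if m0 > 0:
        fold = tuple(p.mutant_fraction / m0 for p in pools)
    else:
        fold = tuple(1.0 for _ in pools)
    detection = next(
        (
            k
            for k, p in enumerate(pools)
            if 100.0 * p.mutant_fraction >= params.detection_limit
        ),
        None,
    )
    return EnrichmentTrajectory(tuple(pools), fold, detection)


def stochastic_round(
    pool: AllelePool,
    params: RoundParams,
    seed: int | np.random.Generator,
) -> AllelePool:
    """One finite-template round: carryover bottleneck, survival draws,
    deterministic renormalisation back to ``total_molecules``.

    The template take is ``ceil(carryover * N)`` molecules drawn from the pool
    composition; each template molecule then survives cleavage independently
    with probability ``1 - c (1 - pi)``.  Saturating PCR restores the count to
    N without changing composition.  Reproducible under a fixed seed.
    """
    if pool.total_molecules is None:
        raise ValueError("stochastic mode requires total_molecules")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = pool.total_molecules
    take = math.ceil(params.carryover * N)
    counts = rng.multinomial(take, np.asarray(pool.fractions))
    w = _survival_weights(pool, params.c)
    survivors = rng.binomial(counts, w)
    total = survivors.sum()
    if total == 0:
        raise StochasticDropoutError(
            "stochastic dropout: no molecule survived the bottleneck"
        )
    return replace(pool, fractions=tuple(survivors / total))


@dataclass(frozen=True)
class EscapeParams:
    """Rule-based escape probabilities by mutation class.

    Indels of size >= ``s_big`` anywhere in the protospacer (or PAM) escape
    with ``pi_big``; 1-bp indels with ``pi_small`` (a 1-bp change still leaves
    a near-perfect target, so re-cleavage is likely); substitutions escape
    with ``pi_seed`` in the seed, ``pi_distal`` elsewhere in the protospacer;
    a substitution that breaks a constrained PAM base escapes with certainty.
    These are model parameters, not measured constants; every downstream
    number that depends on them is model-dependent.
    """

    pi_small: float = 0.3
    pi_big: float = 1.0
    pi_seed: float = 0.9
    pi_distal: float = 0.1
    s_big: int = 2


def escape_probability(
    mutation: Mutation,
    guide: EnrichmentGuide,
    effector: EffectorSpec,
    params: EscapeParams = EscapeParams(),
) -> float:
    """Escape probability of a mutant allele against an enrichment guide."""
    site = guide.site
    lo, hi = site.footprint(effector)

    if isinstance(mutation, WildType):
        return 0.0
    if isinstance(mutation, (Deletion, Insertion)):
        if isinstance(mutation, Deletion):
            overlaps = mutation.start < hi and mutation.end > lo
        else:  # insertion at a gap index splits the site only strictly inside
            overlaps = lo < mutation.position < hi
        if not overlaps:
            return 0.0
        return params.pi_big if mutation.size >= params.s_big else params.pi_small
    if isinstance(mutation, Substitution):
        p = mutation.position
        ps, pe = site.pam_interval(effector)
        if ps <= p < pe:
            # index of this amplicon position within the PAM pattern
            idx = (p - ps) if site.strand == "+" else (pe - 1 - p)
            patt_ch = effector.pam[idx]
            alt_on_pam_strand = (
                mutation.alt if site.strand == "+" else _complement(mutation.alt)
            )
            if IUPAC[patt_ch] != "ACGT" and not iupac_base_match(
                patt_ch, alt_on_pam_strand
            ):
                return 1.0  # PAM disrupted: the mutant is never a substrate
            return params.pi_distal
        if site.start <= p < site.end:
            return (
                params.pi_seed
                if p in site.seed_positions(effector)
                else params.pi_distal
            )
        return 0.0
    raise TypeError(f"unknown mutation type {type(mutation)!r}")


def _complement(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]


@dataclass(frozen=True)
class CleavageFit:
    c: float
    residual: float
    warning: str | None = None


def fit_cleavage_efficiency(
    mutant_fractions: Sequence[float],
    pi: float = 1.0,
) -> CleavageFit:
    """Least-squares estimate of the per-round cleavage efficiency ``c``.

    Fits the two-class recurrence ``m' = m w / (m w + (1-m)(1-c))`` with
    ``w = 1 - c (1 - pi)`` to an observed mutant-fraction trajectory
    (round 0 first) by bounded 1-D minimisation.  A trajectory no value of
    ``c`` can produce (e.g. decreasing with ``pi = 1``) yields the best
    attainable fit plus a warning.
    """
    m = [float(x) for x in mutant_fractions]
    if len(m) < 2:
        raise ValueError("need at least two observed rounds (m0 plus one round)")
    if any(not (0.0 < x < 1.0) for x in m):
        raise ValueError("observed fractions must lie strictly in (0, 1)")

    def predict(c: float) -> list[float]:
        w = 1.0 - c * (1.0 - pi)
        out = [m[0]]
        for _ in range(len(m) - 1):
            x = out[-1]
            denom = x * w + (1.0 - x) * (1.0 - c)
            out.append(x * w / denom if denom > 0 else 1.0)
        return out

    def sse(c: float) -> float:
        return sum((p - o) ** 2 for p, o in zip(predict(c), m))

    res = minimize_scalar(sse, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    c_hat = float(res.x)
    # the bounded minimiser never evaluates the exact endpoints; snap if better
    for edge in (0.0, 1.0):
        if sse(edge) <= sse(c_hat):
            c_hat = edge
    residual = float(sse(c_hat))
    warning = None
    if any(b < a - 1e-9 for a, b in zip(m, m[1:])) and pi >= 1.0:
        warning = "non-monotone trajectory is inconsistent with any c at pi=1"
    elif max(m) - min(m) < 1e-12:
        warning = "constant trajectory: c is confounded with pi"
    return CleavageFit(c=c_hat, residual=residual, warning=warning)
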