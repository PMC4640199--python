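"""Closed-form genetics of the G1 x G2 backcross scheme.

A mutagenized G0 sire transmits a private set of ENU-induced variants to a G1
male.  The G1 male is crossed to wild-type females; his G2 daughters are
backcrossed to him, and recessive phenotypes segregate in the G3 offspring.
For any given G1 variant:

* a G2 daughter carries it with probability 1/2;
* given a carrier (het) dam, the het x het backcross offspring is homozygous
  with probability 1/4.

Hence a G3 mouse is homozygous for the causal variant — and therefore
affected, under full penetrance — with probability 1/8 (12.5 %), and the same
1/8 applies to any locus unlinked to the mutation, which is what makes a
spurious all-homozygous region in a pool of N mice as improbable as 0.125^N.

All default-model quantities are exact rationals (``fractions.Fraction``);
floats appear only when a non-dyadic penetrance is supplied.  Each closed
form has a vectorised Monte-Carlo counterpart used as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np

__all__ = [
    "CrossModel",
    "p_homozygous_unlinked",
    "p_spurious_region",
    "expected_affected_fraction",
    "expected_pool_naf",
    "mc_homozygous_unlinked",
    "mc_spurious_region",
    "mc_pool_naf_unlinked",
]

Number = Fraction | float


@dataclass(frozen=True)
class CrossModel:
    """Transmission parameters of the backcross scheme.

    ``p_g2_carrier`` — probability a G2 daughter inherits a given G1 variant.
    ``p_hom_given_carrier`` — probability the backcross offspring of a carrier
    dam is homozygous.  ``penetrance`` — probability a homozygote expresses
    the phenotype.  ``pool_size`` — number of affected mice pooled for
    sequencing.
    """

    p_g2_carrier: Number = Fraction(1, 2)
    p_hom_given_carrier: Number = Fraction(1, 4)
    penetrance: Number = Fraction(1)
    pool_size: int = 4

    def __post_init__(self) -> None:
        for name in ("p_g2_carrier", "p_hom_given_carrier", "penetrance"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def p_homozygous_unlinked(model: CrossModel = CrossModel()) -> Number:
    """P(a G3 mouse is homozygous at a locus unlinked to the mutation).

    Exact product p_g2_carrier * p_hom_given_carrier; 1/8 for the defaults.
    """
    return model.p_g2_carrier * model.p_hom_given_carrier


def p_spurious_region(model: CrossModel = CrossModel(), n: int | None = None) -> Number:
    """P(all N pooled mice are simultaneously homozygous at an unlinked locus).

    This is the per-region false-positive rate of strict homozygosity
    mapping: 0.125**N, e.g. ~2.44e-4 for the minimum pool of four.
    """
    n = model.pool_size if n is None else n
    if n < 1:
        raise ValueError("pool size must be >= 1")
    return p_homozygous_unlinked(model) ** n


def expected_affected_fraction(model: CrossModel = CrossModel()) -> Number:
    """Expected fraction of G3 progeny affected by a monogenic recessive.

    1/8 * penetrance: 12.5 % at full penetrance.
    """
    return p_homozygous_unlinked(model) * model.penetrance


def expected_pool_naf(
    model: CrossModel = CrossModel(),
    locus: Literal["causal", "unlinked"] = "unlinked",
    conditioning: Literal["dam_carrier", "marginal"] = "dam_carrier",
) -> Number:
    """Expected pooled non-reference allele fraction.

    * ``causal`` — a pool of affected (homozygous) mice: every chromosome
      carries the variant, so the expectation is 1.
    * ``unlinked, dam_carrier`` — het sire x carrier het dam: enumerate the
      backcross genotypes (1/4 hom, 1/2 het, 1/4 wt), mean dosage 1 of 2,
      i.e. the "random 50 %" expectation in unlinked regions.
    * ``unlinked, marginal`` — additionally average over whether the dam
      carries at all: 1/2 * 1/2 + 1/2 * 1/4 = 3/8.

    Computed by exact enumeration of (dam carrier?, transmitted alleles).
    """
    if locus == "causal":
        return Fraction(1)
    if locus != "unlinked":
        raise ValueError(f"unknown locus kind {locus!r}")
    p_carrier = {
        "dam_carrier": Fraction(1),
        "marginal": model.p_g2_carrier,
    }[conditioning]
    half = Fraction(1, 2)
    total: Number = 0
    for dam_carrier, p_dam in ((True, p_carrier), (False, 1 - p_carrier)):
        if p_dam == 0:
            continue
        mat_alleles = ((1, half), (0, half)) if dam_carrier else ((0, Fraction(1)),)
        for pat, p_pat in ((1, half), (0, half)):  # het sire
            for mat, p_mat in mat_alleles:
                total += p_dam * p_pat * p_mat * Fraction(pat + mat, 2)
    return total


# ---------------------------------------------------------------------------
# Monte-Carlo counterparts (single-locus transmission draws).  Each returns
# (estimate, standard_error).
# ---------------------------------------------------------------------------


def _draw_dosage(
    rng: np.random.Generator, n: int, p_carrier: float
) -> np.ndarray:
    """Allele dosage (0/1/2) at an unlinked locus for n independent G3 mice."""
    dam_carrier = rng.random(n) < p_carrier
    pat = rng.integers(0, 2, size=n)  # het sire transmits 0/1 equally
    mat = np.where(dam_carrier, rng.integers(0, 2, size=n), 0)
    return pat + mat


def mc_homozygous_unlinked(
    model: CrossModel = CrossModel(),
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulate n G3 trios; fraction homozygous at an unlinked locus."""
    rng = rng or np.random.default_rng()
    hom = _draw_dosage(rng, n_draws, float(model.p_g2_carrier)) == 2
    p = hom.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n_draws))


def mc_spurious_region(
    model: CrossModel = CrossModel(),
    n: int | None = None,
    n_pools: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulate pools of N mice; fraction of pools all-homozygous."""
    rng = rng or np.random.default_rng()
    n = model.pool_size if n is None else n
    dosage = _draw_dosage(rng, n_pools * n, float(model.p_g2_carrier))
    all_hom = (dosage.reshape(n_pools, n) == 2).all(axis=1)
    p = all_hom.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n_pools))


def mc_pool_naf_unlinked(
    model: CrossModel = CrossModel(),
    conditioning: Literal["dam_carrier", "marginal"] = "dam_carrier",
    n_pools: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulate pooled allele fractions at an unlinked locus.

    Pool membership (being affected) is independent of an unlinked locus, so
    pool members are plain backcross offspring; under ``dam_carrier`` every
    member's dam carries the variant.
    """
    rng = rng or np.random.default_rng()
    n = model.pool_size
    p_carrier = 1.0 if conditioning == "dam_carrier" else float(model.p_g2_carrier)
    dosage = _draw_dosage(rng, n_pools * n, p_carrier).reshape(n_pools, n)
    naf = dosage.sum(axis=1) / (2 * n)
    return float(naf.mean()), float(naf.std(ddof=1) / np.sqrt(n_pools))
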