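"""Filtering cascade producing the presumptive ENU-induced marker set.

Raw pooled SNV calls contain strain polymorphisms, repeat artefacts and
low-confidence calls.  The cascade removes, in a fixed attribution order:

1. variants present in known databases (dbSNP-like) or in-house controls,
   matched by exact (chrom, pos, ref, alt);
2. variants inside repeat-masked regions;
3. low-likelihood calls (qual < 30 — boundary kept);
4. low-coverage calls (depth < 5 — boundary kept);
5. multiallelic sites;
6. sex-chromosome variants (the breeding scheme cannot maintain X/Y-linked
   mutations).

Each removed variant is attributed to the first rule it trips, so the report
counts are a partition of the input: input = passing + sum of removals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .variant_model import GenomeLayout, IntervalSet, Variant

__all__ = [
    "EXOME_CATEGORIES",
    "FilterConfig",
    "FilterReport",
    "filter_variants",
    "virtual_exome",
]

KnownSet = frozenset | set

#: Categories counted as exon-resident for virtual whole-exome analysis.
EXOME_CATEGORIES = frozenset(
    {"exonic_nonsynonymous", "exonic_synonymous", "stopgain", "stoploss", "splicing"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches of the cascade.

    Inequalities are strict as printed in the method (< Q30, < 5x), so the
    boundary values qual = 30 and depth = 5 pass.
    """

    min_qual: float = 30.0
    min_depth: int = 5
    biallelic_only: bool = True
    exclude_known: bool = True
    exclude_repeats: bool = True
    exclude_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterReport:
    """Per-rule removal counts; serialises to JSON with these field names."""

    input_count: int = 0
    known_db: int = 0
    in_house: int = 0
    repeat: int = 0
    low_qual: int = 0
    low_depth: int = 0
    multiallelic: int = 0
    sex_chromosome: int = 0
    passing_count: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.known_db
            + self.in_house
            + self.repeat
            + self.low_qual
            + self.low_depth
            + self.multiallelic
            + self.sex_chromosome
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _matches_known(variant: Variant, known: KnownSet) -> bool:
    return any(
        (variant.chrom, variant.pos, variant.ref, alt) in known for alt in variant.alts
    )


def filter_variants(
    variants: Sequence[Variant],
    known: Iterable[KnownSet] = (),
    repeats: IntervalSet | None = None,
    layout: GenomeLayout | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[Variant], FilterReport]:
    """Apply the cascade; returns (passing variants in input order, report).

    ``known`` is a sequence of (chrom, pos, ref, alt) tuple sets; the first is
    treated as the public database (``known_db`` in the report) and any
    further sets as in-house controls.  A variant flagged ``in_known_db`` or
    ``in_repeat`` at parse time trips the corresponding rule as well.
    Sex chromosomes are taken from ``layout`` ({"X","Y"} if no layout given).
    """
    known = list(known)
    db = known[0] if known else frozenset()
    in_house = known[1:]
    sex = layout.sex_chromosomes if layout is not None else frozenset({"X", "Y"})

    report = FilterReport(input_count=len(variants))
    passing: list[Variant] = []
    for v in variants:
        if cfg.exclude_known and (v.in_known_db or _matches_known(v, db)):
            report.known_db += 1
        elif cfg.exclude_known and any(_matches_known(v, s) for s in in_house):
            report.in_house += 1
        elif cfg.exclude_repeats and (
            v.in_repeat or (repeats is not None and repeats.contains(v.chrom, v.pos0))
        ):
            report.repeat += 1
        elif v.qual < cfg.min_qual:
            report.low_qual += 1
        elif v.depth < cfg.min_depth:
            report.low_depth += 1
        elif cfg.biallelic_only and v.is_multiallelic:
            report.multiallelic += 1
        elif cfg.exclude_sex_chromosomes and v.chrom in sex:
            report.sex_chromosome += 1
        else:
            passing.append(v)
    report.passing_count = len(passing)
    assert report.input_count == report.passing_count + report.removed_total
    return passing, report


def virtual_exome(variants: Sequence[Variant]) -> list[Variant]:
    """Restrict to exon-resident and splice-site variants.

    Emulates whole-exome capture from a whole-genome variant set, so that the
    exome-scale mapping behaviour can be studied from the same pool.
    Unannotated variants are excluded (one summary warning).  Idempotent.
    """
    kept: list[Variant] = []
    unannotated = 0
    for v in variants:
        if v.annotation is None:
            unannotated += 1
        elif v.annotation.category in EXOME_CATEGORIES:
            kept.append(v)
    if unannotated:
        warnings.warn(f"{unannotated} unannotated variant(s) excluded from virtual exome")
    return kept
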