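"""Candidate causal mutation extraction and segregation concordance.

Within a mapped region, the causal mutation is expected among the variants
that can plausibly damage a gene product: non-synonymous coding changes,
stop gains/losses (read as non-synonymous), and splice-site variants (within
10 bp of an exon).  Two selection modes mirror the two mapping strategies:

* ``require_hom`` — keep only sites classed homozygous (strict homozygosity
  mapping);
* NAF floor — keep sites whose pooled allele fraction reaches a floor
  (the fallback used when one pooled mouse may not be homozygous).

Candidates are ordered by descending NAF and carry a competition rank
(ties share a rank: rank = 1 + number of candidates with strictly higher
NAF), since markers on the same intact recombinant haplotype are genuinely
indistinguishable by pooled read fractions alone.  Final discrimination is
by genotyping further mice (:func:`concordance_table`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .homozygosity_mapper import MappingRegion, call_zygosity
from .variant_model import GenomeLayout, Variant

__all__ = [
    "DAMAGING_CATEGORIES",
    "CandidateMutation",
    "candidate_mutations",
    "candidates_to_tsv",
    "concordance_table",
]

#: Categories eligible as causal candidates.
DAMAGING_CATEGORIES = frozenset(
    {"exonic_nonsynonymous", "stopgain", "stoploss", "splicing"}
)


@dataclass(frozen=True)
class CandidateMutation:
    """A damaging-category variant inside a mapped region."""

    variant: Variant
    gene: str | None
    category: str
    naf: float
    zygosity: str  # "hom" | "het"
    region: MappingRegion
    rank: int = 0

    @property
    def key(self) -> str:
        """Stable identifier used in genotype tables: ``chrom:pos``."""
        return f"{self.variant.chrom}:{self.variant.pos}"


def candidate_mutations(
    variants: Sequence[Variant],
    regions: Sequence[MappingRegion],
    naf_floor: float = 0.7,
    require_hom: bool = False,
    hom_naf_threshold: float = 0.9,
    layout: GenomeLayout | None = None,
) -> list[CandidateMutation]:
    """Extract candidates from variants lying inside any mapped region.

    With ``require_hom`` true only homozygous-classed sites are kept;
    otherwise sites with naf >= ``naf_floor`` are kept.  Output is sorted by
    descending naf then genome order, with competition ranks assigned.
    Unannotated variants inside a region are excluded (one counted warning).
    """
    if layout is not None:
        chrom_order = {name: i for i, name in enumerate(layout.names)}
    else:
        chrom_order = {}
        for r in regions:
            chrom_order.setdefault(r.chrom, len(chrom_order))

    selected: list[CandidateMutation] = []
    unannotated = 0
    for v in variants:
        region = next((r for r in regions if r.contains(v.chrom, v.pos0)), None)
        if region is None:
            continue
        if v.annotation is None:
            unannotated += 1
            continue
        if v.annotation.category not in DAMAGING_CATEGORIES:
            continue
        if v.naf is None:
            continue
        zyg = call_zygosity(v, hom_naf_threshold)
        if require_hom:
            if zyg != "hom":
                continue
        elif v.naf < naf_floor:
            continue
        selected.append(
            CandidateMutation(
                variant=v,
                gene=v.annotation.gene,
                category=v.annotation.category,
                naf=v.naf,
                zygosity=zyg,
                region=region,
                rank=0,
            )
        )
    if unannotated:
        warnings.warn(f"{unannotated} unannotated variant(s) in regions were skipped")

    selected.sort(
        key=lambda c: (-c.naf, chrom_order.get(c.variant.chrom, 10**9), c.variant.pos)
    )
    ranked: list[CandidateMutation] = []
    for i, c in enumerate(selected):
        rank = 1 + sum(1 for other in selected if other.naf > c.naf)
        ranked.append(CandidateMutation(**{**c.__dict__, "rank": rank}))
    return ranked


def candidates_to_tsv(candidates: Sequence[CandidateMutation], path: str | Path) -> None:
    """Write a candidate table: gene, NAF, chrom, bp, ref, alt, category,
    AA change, zygosity, rank."""
    with open(path, "w") as fh:
        fh.write("gene\tnaf\tchrom\tbp\tref\talt\tcategory\taa_change\tzygosity\trank\n")
        for c in candidates:
            v = c.variant
            aa = v.annotation.aa_change if v.annotation and v.annotation.aa_change else "NA"
            fh.write(
                f"{c.gene or 'NA'}\t{c.naf:.4f}\t{v.chrom}\t{v.pos}\t{v.ref}\t"
                f"{','.join(v.alts)}\t{c.category}\t{aa}\t{c.zygosity}\t{c.rank}\n"
            )


def concordance_table(
    candidates: Sequence[CandidateMutation],
    genotyped_mice: pd.DataFrame,
) -> pd.DataFrame:
    """Segregation concordance of candidates in individually genotyped mice.

    ``genotyped_mice`` columns: ``mouse_id``, ``phenotype`` ("affected" /
    "unaffected"), then one column per candidate key (``chrom:pos``) holding
    "hom", "het", "wt", or NA for untyped.  A recessive causal candidate must
    be homozygous in every affected mouse and in no unaffected mouse; a
    single discordant mouse excludes it.  Candidates with no genotyped mice
    are reported "untested".  Row order of the input is irrelevant.
    """
    required = {"mouse_id", "phenotype"}
    if not required.issubset(genotyped_mice.columns):
        raise ValueError("genotype table needs mouse_id and phenotype columns")
    geno_cols = [c for c in genotyped_mice.columns if c not in required]
    keys = {c.key for c in candidates}
    unknown = [col for col in geno_cols if col not in keys]
    if unknown:
        raise ValueError(f"genotype table has unknown candidate id(s): {unknown}")

    rows = []
    for cand in candidates:
        if cand.key not in geno_cols:
            rows.append(
                {
                    "candidate": cand.key,
                    "gene": cand.gene,
                    "affected_hom": 0,
                    "affected_not_hom": 0,
                    "unaffected_hom": 0,
                    "status": "untested",
                }
            )
            continue
        sub = genotyped_mice[["phenotype", cand.key]].dropna(subset=[cand.key])
        if sub.empty:
            status_counts = (0, 0, 0)
            status = "untested"
        else:
            affected = sub[sub["phenotype"] == "affected"]
            unaffected = sub[sub["phenotype"] == "unaffected"]
            a_hom = int((affected[cand.key] == "hom").sum())
            a_not = int((affected[cand.key] != "hom").sum())
            u_hom = int((unaffected[cand.key] == "hom").sum())
            status_counts = (a_hom, a_not, u_hom)
            status = "excluded" if (a_not > 0 or u_hom > 0) else "concordant"
        rows.append(
            {
                "candidate": cand.key,
                "gene": cand.gene,
                "affected_hom": status_counts[0],
                "affected_not_hom": status_counts[1],
                "unaffected_hom": status_counts[2],
                "status": status,
            }
        )
    return pd.DataFrame(rows)
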