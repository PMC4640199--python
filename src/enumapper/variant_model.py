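"""Domain types and I/O for variants, interval masks, and genome layouts.

The mapping method treats ENU-induced single-nucleotide variants, called from
a pooled library of affected mice, as segregating markers on an otherwise
inbred background.  This module holds the variant/interval containers and the
VCF/BED/TSV readers and writers everything else is built on.

Coordinate conventions: VCF positions are 1-based; all internal interval
arithmetic is 0-based half-open.  Conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "CATEGORIES",
    "CODING_CATEGORIES",
    "FunctionalAnnotation",
    "GenomeLayout",
    "IntervalSet",
    "Variant",
    "VcfParseError",
    "annotate_by_intervals",
    "read_bed",
    "read_known_sites",
    "read_vcf",
    "write_vcf",
]

#: Closed set of functional categories (ANNOVAR-style refGene classes).
CATEGORIES = frozenset(
    {
        "exonic_nonsynonymous",
        "exonic_synonymous",
        "stopgain",
        "stoploss",
        "splicing",
        "intronic",
        "intergenic",
        "utr",
        "unknown",
    }
)

#: Categories for which an amino-acid change annotation is meaningful.
CODING_CATEGORIES = frozenset(
    {"exonic_nonsynonymous", "exonic_synonymous", "stopgain", "stoploss"}
)


class VcfParseError(ValueError):
    """Raised for malformed VCF input; carries the offending line number."""


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Gene-model annotation of a variant.

    ``category`` is one of :data:`CATEGORIES`; ``aa_change`` (e.g. ``"V549>A"``)
    is only meaningful for coding categories.
    """

    gene: str | None = None
    category: str = "unknown"
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown functional category: {self.category!r}")
        if self.aa_change is not None and self.category not in CODING_CATEGORIES:
            raise ValueError(
                f"aa_change given for non-coding category {self.category!r}"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths, with a set of sex chromosomes.

    The breeding scheme cannot maintain X- or Y-linked mutations, so the sex
    chromosomes are excluded from window construction and (optionally) from
    the filtered marker set.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sex_chromosomes: frozenset[str] = frozenset({"X", "Y"})

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def autosomes(self) -> tuple[tuple[str, int], ...]:
        return tuple(
            (name, length)
            for name, length in self.chromosomes
            if name not in self.sex_chromosomes
        )

    def chrom_index(self, chrom: str) -> int:
        """Position of ``chrom`` in genome order (for sorting)."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(chrom) from None

    @classmethod
    def from_tsv(cls, path: str | Path, sex_chromosomes: Iterable[str] = ("X", "Y")) -> "GenomeLayout":
        """Read a two-column (name, length) TSV."""
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                chroms.append((parts[0], int(parts[1])))
        return cls(tuple(chroms), frozenset(sex_chromosomes))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class Variant:
    """One SNV from the pooled sample.

    ``naf`` — the novel (non-reference) allele frequency — is the fraction of
    pooled reads supporting the first alternate allele; it is the per-site
    statistic the whole mapping method rests on.  It is ``None`` when no reads
    cover the site.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    depth: int = 0
    alt_depth: int = 0
    annotation: FunctionalAnnotation | None = None
    in_known_db: bool = False
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= max(self.depth, 0):
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_depth {self.alt_depth} outside "
                f"[0, depth={self.depth}]"
            )
        if self.depth < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative depth")

    @property
    def naf(self) -> float | None:
        if self.depth == 0:
            return None
        return self.alt_depth / self.depth

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def pos0(self) -> int:
        """0-based coordinate."""
        return self.pos - 1


class IntervalSet:
    """Per-chromosome sorted, merged half-open intervals with optional labels.

    Backed by numpy arrays so membership is a binary search.  Normalisation
    merges overlapping/abutting intervals; when labelled intervals merge the
    first label is kept (gene models rarely overlap across genes, and masks
    are unlabelled).
    """

    def __init__(
        self,
        intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
        labels: Mapping[str, Sequence[str | None]] | None = None,
    ) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, list[str | None]]] = {}
        if intervals:
            for chrom, pairs in intervals.items():
                labs = list(labels[chrom]) if labels and chrom in labels else [None] * len(pairs)
                self._chroms[chrom] = self._normalize(pairs, labs)

    @staticmethod
    def _normalize(
        pairs: Sequence[tuple[int, int]], labs: Sequence[str | None]
    ) -> tuple[np.ndarray, np.ndarray, list[str | None]]:
        if len(pairs) != len(labs):
            raise ValueError("labels and intervals differ in length")
        order = sorted(range(len(pairs)), key=lambda i: pairs[i])
        starts: list[int] = []
        ends: list[int] = []
        merged_labs: list[str | None] = []
        for i in order:
            s, e = pairs[i]
            if s >= e:
                raise ValueError(f"invalid interval [{s}, {e})")
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
                merged_labs.append(labs[i])
        return (
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            merged_labs,
        )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._chroms:
            return []
        starts, ends, _ = self._chroms[chrom]
        return list(zip(starts.tolist(), ends.tolist()))

    def labels(self, chrom: str) -> list[str | None]:
        if chrom not in self._chroms:
            return []
        return list(self._chroms[chrom][2])

    def __len__(self) -> int:
        return sum(len(starts) for starts, _, _ in self._chroms.values())

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        if chrom not in self._chroms:
            return False
        starts, ends, _ = self._chroms[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def locate(self, chrom: str, pos0: int) -> tuple[int, str | None] | None:
        """Index and label of the interval containing ``pos0``, or None."""
        if chrom not in self._chroms:
            return None
        starts, ends, labs = self._chroms[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return i, labs[i]
        return None

    def gene_bodies(self) -> "IntervalSet":
        """Span from first to last interval of each label (per chromosome)."""
        pairs: dict[str, list[tuple[int, int]]] = {}
        labels: dict[str, list[str | None]] = {}
        for chrom, (starts, ends, labs) in self._chroms.items():
            spans: dict[str, tuple[int, int]] = {}
            for s, e, lab in zip(starts.tolist(), ends.tolist(), labs):
                if lab is None:
                    continue
                if lab in spans:
                    s0, e0 = spans[lab]
                    spans[lab] = (min(s0, s), max(e0, e))
                else:
                    spans[lab] = (s, e)
            if spans:
                pairs[chrom] = list(spans.values())
                labels[chrom] = list(spans.keys())
        return IntervalSet(pairs, labels)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3/4-column BED (0-based half-open; column 4 = label) into an
    :class:`IntervalSet`, merging overlaps."""
    pairs: dict[str, list[tuple[int, int]]] = {}
    labels: dict[str, list[str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            pairs.setdefault(chrom, []).append((start, end))
            labels.setdefault(chrom, []).append(parts[3] if len(parts) > 3 else None)
    return IntervalSet(pairs, labels)


def annotate_by_intervals(
    variant: Variant, exons: IntervalSet, splice_margin: int = 10
) -> FunctionalAnnotation:
    """Annotate a variant against an exon model.

    A position inside an exon is exon-resident but cannot be classified into
    a coding sub-category without sequence-level annotation, so it is returned
    as category ``unknown`` with the gene attached.  A position within
    ``splice_margin`` bp outside an exon is ``splicing`` (the method's
    splice-site rule: within 10 bp of an exon).  Otherwise the variant is
    ``intronic`` if it falls in a gene body, ``intergenic`` if not.
    """
    chrom, pos0 = variant.chrom, variant.pos0
    if chrom not in exons.chromosomes:
        warnings.warn(f"chromosome {chrom!r} absent from exon model; intergenic")
        return FunctionalAnnotation(category="intergenic")
    hit = exons.locate(chrom, pos0)
    if hit is not None:
        return FunctionalAnnotation(gene=hit[1], category="unknown")
    starts, ends, labs = exons._chroms[chrom]
    i = int(np.searchsorted(starts, pos0, side="right")) - 1
    best_dist, best_lab = None, None
    if i >= 0:  # nearest exon to the left; pos0 >= ends[i]
        d = pos0 - int(ends[i]) + 1  # 1 for the base just past the exon
        best_dist, best_lab = d, labs[i]
    if i + 1 < len(starts):
        d = int(starts[i + 1]) - pos0
        if best_dist is None or d < best_dist:
            best_dist, best_lab = d, labs[i + 1]
    if best_dist is not None and best_dist <= splice_margin:
        return FunctionalAnnotation(gene=best_lab, category="splicing")
    body = exons.gene_bodies().locate(chrom, pos0)
    if body is not None:
        return FunctionalAnnotation(gene=body[1], category="intronic")
    return FunctionalAnnotation(category="intergenic")


# ---------------------------------------------------------------------------
# VCF I/O
#
# Reserved INFO keys: EM_NAF (float), EM_GENE, EM_CAT, EM_AA (strings),
# EM_KNOWN, EM_REP (flags).  Depth is read from DP; alt reads from AD
# (second value) or DP4 (sum of the two alt-supporting counts) when AD is
# absent.  naf is always recomputed as alt_depth/depth, never trusted from
# EM_NAF.
# ---------------------------------------------------------------------------

_INFO_HEADERS = [
    ('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'),
    ('##INFO=<ID=AD,Number=R,Type=Integer,Description="Allelic read depths">'),
    ('##INFO=<ID=EM_NAF,Number=1,Type=Float,Description="Non-reference allele frequency">'),
    ('##INFO=<ID=EM_GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=EM_CAT,Number=1,Type=String,Description="Functional category">'),
    ('##INFO=<ID=EM_AA,Number=1,Type=String,Description="Amino acid change">'),
    ('##INFO=<ID=EM_KNOWN,Number=0,Type=Flag,Description="Present in a known-variant database">'),
    ('##INFO=<ID=EM_REP,Number=0,Type=Flag,Description="In a repeat-masked region">'),
]


def _info_get(rec: pysam.VariantRecord, key: str, default=None):
    """INFO accessor tolerant of keys absent from the header (pysam raises)."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _alt_depth_from_record(rec: pysam.VariantRecord) -> tuple[int, int] | None:
    """(depth, alt_depth) from INFO/FORMAT fields, or None if unavailable."""
    depth = _info_get(rec, "DP")
    ad = _info_get(rec, "AD")
    dp4 = _info_get(rec, "DP4")
    if ad is None and rec.samples:
        sample = rec.samples[0]
        if "AD" in sample and sample["AD"] is not None:
            ad = sample["AD"]
        if depth is None and "DP" in sample:
            depth = sample["DP"]
    if depth is None:
        return None
    alt_depth: int | None = None
    if ad is not None and len(ad) >= 2 and ad[1] is not None:
        alt_depth = int(ad[1])
    elif dp4 is not None and len(dp4) == 4:
        alt_depth = int(dp4[2]) + int(dp4[3])
    if alt_depth is None:
        return None
    return int(depth), min(alt_depth, int(depth))


def read_vcf(path: str | Path, min_fields: bool = False) -> list[Variant]:
    """Read a VCF v4.x of SNVs into :class:`Variant` records, in input order.

    Records lacking usable depth information get ``depth = 0`` (naf
    undefined) with a warning, or raise if ``min_fields`` is true.
    """
    variants: list[Variant] = []
    missing_depth = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    with vcf:
        for rec in vcf:
            ann = None
            cat = _info_get(rec, "EM_CAT")
            gene = _info_get(rec, "EM_GENE")
            aa = _info_get(rec, "EM_AA")
            if cat is not None or gene is not None:
                ann = FunctionalAnnotation(
                    gene=gene, category=cat if cat is not None else "unknown", aa_change=aa
                )
            depths = _alt_depth_from_record(rec)
            if depths is None:
                if min_fields:
                    raise VcfParseError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks depth fields"
                    )
                missing_depth += 1
                depth, alt_depth = 0, 0
            else:
                depth, alt_depth = depths
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    depth=depth,
                    alt_depth=alt_depth,
                    annotation=ann,
                    in_known_db=bool(_info_get(rec, "EM_KNOWN", False)),
                    in_repeat=bool(_info_get(rec, "EM_REP", False)),
                )
            )
    if missing_depth:
        warnings.warn(f"{missing_depth} record(s) lacked depth fields; depth set to 0")
    return variants


def write_vcf(
    variants: Sequence[Variant], layout: GenomeLayout, path: str | Path
) -> Path:
    """Write variants as VCF v4.2 with contig lines from ``layout``.

    Input must already be sorted by (layout chromosome order, position);
    unsorted input raises rather than being silently sorted.
    """
    order = {name: i for i, name in enumerate(layout.names)}
    keys = []
    for v in variants:
        if v.chrom not in order:
            raise ValueError(f"variant chromosome {v.chrom!r} not in layout")
        keys.append((order[v.chrom], v.pos))
    if keys != sorted(keys):
        raise ValueError("variants are not sorted by layout order and position")

    header = pysam.VariantHeader()
    for line in _INFO_HEADERS:
        header.add_line(line)
    for name, length in layout.chromosomes:
        header.add_line(f"##contig=<ID={name},length={length}>")

    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos0,
                stop=v.pos0 + len(v.ref),
                alleles=(v.ref, *v.alts),
                qual=v.qual,
            )
            rec.info["DP"] = v.depth
            rec.info["AD"] = (v.depth - v.alt_depth, v.alt_depth) + (0,) * (
                len(v.alts) - 1
            )
            if v.naf is not None:
                rec.info["EM_NAF"] = round(v.naf, 6)
            if v.annotation is not None:
                if v.annotation.gene is not None:
                    rec.info["EM_GENE"] = v.annotation.gene
                rec.info["EM_CAT"] = v.annotation.category
                if v.annotation.aa_change is not None:
                    rec.info["EM_AA"] = v.annotation.aa_change
            if v.in_known_db:
                rec.info["EM_KNOWN"] = True
            if v.in_repeat:
                rec.info["EM_REP"] = True
            out.write(rec)
    return path


def read_known_sites(path: str | Path) -> frozenset[tuple[str, int, str, str]]:
    """Load a known-variant set as (chrom, pos, ref, alt) tuples.

    Accepts a VCF (one tuple per alt allele) or a 4-column TSV
    (chrom, pos, ref, alt).  Matching is by exact allele, not position alone:
    a novel alt at a known SNP position is still a novel variant.
    """
    path = Path(path)
    sites: set[tuple[str, int, str, str]] = set()
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    sites.add((rec.chrom, rec.pos, rec.ref, alt))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                sites.add((parts[0], int(parts[1]), parts[2], parts[3]))
    return frozenset(sites)
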