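"""Forward simulator of the ENU backcross scheme with a pooled-VCF output.

The simulator realises the breeding design the mapping method is built for:
a G1 male carries one mutagenized haplotype per chromosome bearing all of his
~3000 ENU-induced variants (ENU acts on G0 spermatogonia, so the G1 inherits
a single mutagenized gamete); he is crossed to wild-type females, and his G2
daughters are backcrossed to him.  G3 offspring homozygous for a designated
causal variant — and expressing the phenotype under the configured
penetrance — are collected into a sequencing pool.  Pooled read counts are
drawn per site as depth ~ Poisson(coverage) and alt reads ~ Binomial(depth,
dosage / 2N), with an optional per-read error flip, and sites with at least
one alt read are emitted as a VCF.  The truth channel (causal locus,
per-mouse genotypes, dam identities) makes end-to-end recovery testable.

Meiosis uses the Haldane model: crossover counts are Poisson in genetic map
length (recomb_rate, cM/Mb), breakpoints uniform, no interference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .variant_model import (
    FunctionalAnnotation,
    GenomeLayout,
    IntervalSet,
    Variant,
    write_vcf,
)

__all__ = [
    "Haplotype",
    "MutationSet",
    "SimConfig",
    "SimOutput",
    "default_layout",
    "draw_mutations",
    "meiosis",
    "simulate_cross",
    "simulate_screen",
    "spike_outlier",
]

_BASES = np.array(list("ACGT"))

#: Split of the exon-resident fraction across functional categories, and of
#: the remainder across non-coding categories.  Non-synonymous changes
#: dominate the exonic ENU spectrum; splice-site hits (within 10 bp of an
#: exon) and stop gains are rarer.
_EXON_SPLIT = {
    "exonic_nonsynonymous": 0.50,
    "exonic_synonymous": 0.25,
    "splicing": 0.20,
    "stopgain": 0.05,
}
_NONEXON_SPLIT = {"intronic": 0.35, "intergenic": 0.65}

#: Categories a recessive phenotype-causing allele can fall in.
_CAUSAL_CATEGORIES = ("exonic_nonsynonymous", "stopgain", "splicing")


def default_layout(n_autosomes: int = 19, length: int = 130_000_000) -> GenomeLayout:
    """Desk-scale mouse-like genome: 19 autosomes x 130 Mb (~2.47 Gb)."""
    return GenomeLayout(
        tuple((str(i + 1), length) for i in range(n_autosomes)),
        frozenset({"X", "Y"}),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated screen.

    ``mutation_rate`` (variants/Mb, 1.2 by default, ~3000 genome-wide on the
    default layout), ``recomb_rate`` (cM/Mb), ``pool_size`` (affected mice
    pooled, 3-5 in practice), ``coverage`` (mean pooled depth), ``penetrance``
    (P(homozygote is phenotypic)), ``n_g2_dams`` (G2 daughters backcrossed),
    ``exon_fraction`` (fraction of variants assigned exon-resident
    categories), ``seq_error`` (per-read flip probability).

    ``causal_choice`` is ``"random_exonic"`` (a random damaging-category
    exon-resident variant becomes causal) or ``"fixed"`` with
    ``causal_chrom``/``causal_pos`` (the nearest drawn variant on that
    chromosome is relocated to the requested position and made causal).
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    mutation_rate: float = 1.2
    recomb_rate: float = 0.5
    pool_size: int = 4
    coverage: float = 15.0
    penetrance: float = 1.0
    n_g2_dams: int = 4
    causal_choice: str = "random_exonic"
    causal_chrom: str | None = None
    causal_pos: int | None = None
    exon_fraction: float = 0.05
    seq_error: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0 or self.recomb_rate < 0 or self.coverage <= 0:
            raise ValueError("rates and coverage must be positive")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if not 0 <= self.exon_fraction <= 1:
            raise ValueError("exon_fraction must lie in [0, 1]")


@dataclass
class MutationSet:
    """The G1 founder's induced variants, per chromosome.

    Arrays are position-sorted; ``genes`` holds synthetic labels for
    exon-resident variants and ``None`` elsewhere.  ``causal`` is
    (chromosome, index into that chromosome's arrays).
    """

    positions: dict[str, np.ndarray]  # 1-based bp
    categories: dict[str, np.ndarray]  # object array of category strings
    genes: dict[str, np.ndarray]  # object array of labels / None
    causal: tuple[str, int]

    @property
    def n_variants(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @property
    def causal_position(self) -> tuple[str, int]:
        chrom, idx = self.causal
        return chrom, int(self.positions[chrom][idx])


@dataclass
class Haplotype:
    """Carrier status of one chromosome set over a :class:`MutationSet`.

    ``carried[chrom]`` is a boolean array aligned with the mutation
    positions: piecewise-constant between crossover breakpoints by
    construction.
    """

    mutations: MutationSet
    carried: dict[str, np.ndarray]

    @classmethod
    def uniform(cls, mutations: MutationSet, value: bool) -> "Haplotype":
        return cls(
            mutations,
            {c: np.full(len(p), value) for c, p in mutations.positions.items()},
        )


def draw_mutations(cfg: SimConfig, rng: np.random.Generator) -> MutationSet:
    """Draw the G1 founder's variant set.

    Per chromosome the count is Poisson(mutation_rate x length_Mb) and
    positions are uniform.  Categories are multinomial per the exon split;
    exon-resident variants get synthetic gene labels.  One damaging-category
    exon-resident variant is designated causal (a redraw is attempted once if
    none was drawn).
    """
    for attempt in range(2):
        positions: dict[str, np.ndarray] = {}
        categories: dict[str, np.ndarray] = {}
        genes: dict[str, np.ndarray] = {}
        cat_names = list(_EXON_SPLIT) + list(_NONEXON_SPLIT)
        probs = [cfg.exon_fraction * p for p in _EXON_SPLIT.values()] + [
            (1 - cfg.exon_fraction) * p for p in _NONEXON_SPLIT.values()
        ]
        gene_counter = 0
        for chrom, length in cfg.layout.autosomes():
            n = rng.poisson(cfg.mutation_rate * length / 1e6)
            pos = np.unique(rng.integers(1, length + 1, size=n))
            cats = np.array(cat_names, dtype=object)[
                rng.choice(len(cat_names), size=len(pos), p=np.array(probs) / sum(probs))
            ]
            labs = np.full(len(pos), None, dtype=object)
            for i, cat in enumerate(cats):
                if cat in _EXON_SPLIT:
                    labs[i] = f"Gene{chrom}_{gene_counter:04d}"
                    gene_counter += 1
            positions[chrom] = pos
            categories[chrom] = cats
            genes[chrom] = labs

        if cfg.causal_choice == "fixed":
            if cfg.causal_chrom is None or cfg.causal_pos is None:
                raise ValueError("fixed causal_choice requires causal_chrom and causal_pos")
            chrom = cfg.causal_chrom
            if len(positions[chrom]) == 0:
                continue
            idx = int(np.argmin(np.abs(positions[chrom] - cfg.causal_pos)))
            positions[chrom][idx] = cfg.causal_pos
            order = np.argsort(positions[chrom], kind="stable")
            positions[chrom] = positions[chrom][order]
            categories[chrom] = categories[chrom][order]
            genes[chrom] = genes[chrom][order]
            idx = int(np.searchsorted(positions[chrom], cfg.causal_pos))
            categories[chrom][idx] = "exonic_nonsynonymous"
            if genes[chrom][idx] is None:
                genes[chrom][idx] = f"Gene{chrom}_causal"
            return MutationSet(positions, categories, genes, (chrom, idx))

        candidates = [
            (chrom, i)
            for chrom in positions
            for i in np.flatnonzero(np.isin(categories[chrom], _CAUSAL_CATEGORIES))
        ]
        if candidates:
            causal = candidates[rng.integers(len(candidates))]
            return MutationSet(positions, categories, genes, (causal[0], int(causal[1])))
    raise RuntimeError("no damaging exon-resident variant drawn after redraw")


def meiosis(
    homolog_a: Haplotype,
    homolog_b: Haplotype,
    cfg: SimConfig,
    rng: np.random.Generator,
    chroms: Sequence[str] | None = None,
) -> Haplotype:
    """One gamete from a pair of homologs under the Haldane model.

    Per chromosome the crossover count is Poisson(length_Mb x recomb_rate /
    100 Morgans), breakpoints are uniform, and the gamete alternates source
    homolog at each breakpoint starting from a fair-coin choice.  ``chroms``
    restricts transmission to a subset of chromosomes (crossovers are
    independent across chromosomes, so partial transmission is exact).
    """
    muts = homolog_a.mutations
    carried: dict[str, np.ndarray] = {}
    for chrom in chroms if chroms is not None else muts.positions:
        length = cfg.layout.length(chrom)
        pos = muts.positions[chrom]
        n_co = rng.poisson(length / 1e6 * cfg.recomb_rate / 100.0)
        start = rng.integers(2)
        if n_co == 0:
            source = np.full(len(pos), start)
        else:
            breakpoints = np.sort(rng.integers(0, length, size=n_co))
            source = (start + np.searchsorted(breakpoints, pos - 1, side="right")) % 2
        carried[chrom] = np.where(
            source == 0, homolog_a.carried[chrom], homolog_b.carried[chrom]
        )
    return Haplotype(muts, carried)


@dataclass
class _Pedigree:
    """G1 homolog pair and G2 dam homolog pairs (truth-side machinery)."""

    mutations: MutationSet
    g1_mut: Haplotype
    g1_wt: Haplotype
    dam_gametes: list[Haplotype]  # each dam's G1-derived homolog (other is wt)

    def dam_carries_causal(self, dam: int) -> bool:
        chrom, idx = self.mutations.causal
        return bool(self.dam_gametes[dam].carried[chrom][idx])


@dataclass
class SimOutput:
    """Simulation truth plus the pooled variant calls it implies."""

    config: SimConfig
    mutations: MutationSet
    pool_dosage: dict[str, np.ndarray]  # (pool_size, n_variants[chrom]) int8
    mouse_dams: list[int]
    dam_carrier: dict[str, np.ndarray]  # (n_dams, n_variants[chrom]) bool
    depth: dict[str, np.ndarray]
    alt_depth: dict[str, np.ndarray]
    n_screened: int
    n_affected_screened: int
    spiked_index: int | None = None
    pedigree: _Pedigree | None = None

    @property
    def causal(self) -> tuple[str, int]:
        return self.mutations.causal_position

    def pooled_variants(self, min_alt_reads: int = 1, qual: float = 60.0) -> list[Variant]:
        """Variants a pooled caller would report (>= min_alt_reads alt reads),
        sorted in layout order, with annotations attached."""
        rng = np.random.default_rng(
            0 if self.config.seed is None else self.config.seed
        )  # allele letters only; cosmetic
        out: list[Variant] = []
        for chrom, _ in self.config.layout.autosomes():
            pos = self.mutations.positions[chrom]
            cats = self.mutations.categories[chrom]
            labs = self.mutations.genes[chrom]
            dp = self.depth[chrom]
            ad = self.alt_depth[chrom]
            ref_i = rng.integers(0, 4, size=len(pos))
            alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
            for i in np.flatnonzero(ad >= min_alt_reads):
                cat = str(cats[i])
                aa = "X1>Y" if cat in {"exonic_nonsynonymous", "exonic_synonymous", "stopgain"} else None
                out.append(
                    Variant(
                        chrom=chrom,
                        pos=int(pos[i]),
                        ref=str(_BASES[ref_i[i]]),
                        alts=(str(_BASES[alt_i[i]]),),
                        qual=qual,
                        depth=int(dp[i]),
                        alt_depth=int(ad[i]),
                        annotation=FunctionalAnnotation(
                            gene=labs[i], category=cat, aa_change=aa
                        ),
                    )
                )
        return out

    def exon_model(self, exon_halfwidth: int = 100) -> IntervalSet:
        """Synthetic exon intervals around exon-resident variants (splicing
        variants are placed just outside their exon)."""
        pairs: dict[str, list[tuple[int, int]]] = {}
        labels: dict[str, list[str | None]] = {}
        for chrom, length in self.config.layout.autosomes():
            pos = self.mutations.positions[chrom]
            cats = self.mutations.categories[chrom]
            labs = self.mutations.genes[chrom]
            for i in range(len(pos)):
                cat = cats[i]
                if cat not in _EXON_SPLIT:
                    continue
                p0 = int(pos[i]) - 1
                if cat == "splicing":  # variant 5 bp outside the exon edge
                    s, e = p0 + 5, p0 + 5 + 2 * exon_halfwidth
                else:
                    s, e = p0 - exon_halfwidth, p0 + exon_halfwidth
                s = max(0, s)
                e = min(length, e)
                if s < e:
                    pairs.setdefault(chrom, []).append((s, e))
                    labels.setdefault(chrom, []).append(labs[i])
        return IntervalSet(pairs, labels)

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write pooled.vcf, truth.json, exons.bed, genome.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "pooled.vcf",
            "truth": outdir / "truth.json",
            "exons": outdir / "exons.bed",
            "genome": outdir / "genome.tsv",
        }
        write_vcf(self.pooled_variants(), self.config.layout, paths["vcf"])
        self.config.layout.to_tsv(paths["genome"])
        exons = self.exon_model()
        with open(paths["exons"], "w") as fh:
            for chrom in exons.chromosomes:
                for (s, e), lab in zip(exons.intervals(chrom), exons.labels(chrom)):
                    fh.write(f"{chrom}\t{s}\t{e}\t{lab or '.'}\n")
        chrom, pos = self.causal
        c_chrom, c_idx = self.mutations.causal
        truth = {
            "causal": {
                "chrom": chrom,
                "pos": pos,
                "gene": self.mutations.genes[c_chrom][c_idx],
                "category": str(self.mutations.categories[c_chrom][c_idx]),
            },
            "n_variants": self.mutations.n_variants,
            "n_screened": self.n_screened,
            "n_affected_screened": self.n_affected_screened,
            "pool_size": self.config.pool_size,
            "mouse_dams": self.mouse_dams,
            "spiked_index": self.spiked_index,
            "genotypes": {
                c: d.tolist() for c, d in self.pool_dosage.items()
            },
            "positions": {c: p.tolist() for c, p in self.mutations.positions.items()},
        }
        paths["truth"].write_text(json.dumps(truth))
        return paths


def _offspring_dosage(
    ped: _Pedigree,
    dam: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    chroms: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Dosage (0/1/2 mutant alleles) of one G3 offspring of a given dam."""
    pat = meiosis(ped.g1_mut, ped.g1_wt, cfg, rng, chroms)
    wt = Haplotype.uniform(ped.mutations, False)
    mat = meiosis(ped.dam_gametes[dam], wt, cfg, rng, chroms)
    return {
        c: pat.carried[c].astype(np.int8) + mat.carried[c].astype(np.int8)
        for c in pat.carried
    }


def _pool_reads(
    cfg: SimConfig,
    dosage_sum: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    depth: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    two_n = 2 * cfg.pool_size
    for chrom, dsum in dosage_sum.items():
        d = rng.poisson(cfg.coverage, size=len(dsum))
        a = rng.binomial(d, dsum / two_n)
        if cfg.seq_error > 0:
            a = rng.binomial(a, 1 - cfg.seq_error) + rng.binomial(d - a, cfg.seq_error)
        depth[chrom] = d
        alt[chrom] = a
    return depth, alt


def _build_pedigree(cfg: SimConfig, muts: MutationSet, rng: np.random.Generator) -> _Pedigree:
    g1_mut = Haplotype.uniform(muts, True)
    g1_wt = Haplotype.uniform(muts, False)
    ped = _Pedigree(muts, g1_mut, g1_wt, [])
    chrom, idx = muts.causal
    for _ in range(1000):
        ped.dam_gametes = [
            meiosis(g1_mut, g1_wt, cfg, rng) for _ in range(cfg.n_g2_dams)
        ]
        if any(ped.dam_carries_causal(d) for d in range(cfg.n_g2_dams)):
            return ped
    raise RuntimeError("no carrier dam obtained")  # pragma: no cover


def simulate_cross(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimOutput:
    """Run the full breeding scheme and generate pooled reads.

    G3 offspring (random dam per birth) are screened until ``pool_size``
    affected mice — homozygous causal and penetrant — are collected.  Dam
    sets with no carrier of the causal variant are redrawn, since such a
    pedigree yields no affected mice and would never reach sequencing.
    Screening is staged: the causal chromosome is transmitted first and the
    rest of the genome only for affected mice (chromosomes segregate
    independently, so this is distributionally exact).
    """
    if cfg.penetrance == 0:
        raise ValueError("penetrance 0 yields no affected mice")
    rng = rng or np.random.default_rng(cfg.seed)
    muts = draw_mutations(cfg, rng)
    ped = _build_pedigree(cfg, muts, rng)
    causal_chrom, causal_idx = muts.causal
    other_chroms = [c for c in muts.positions if c != causal_chrom]

    pool: list[dict[str, np.ndarray]] = []
    mouse_dams: list[int] = []
    n_screened = 0
    max_screened = 200_000
    while len(pool) < cfg.pool_size:
        if n_screened >= max_screened:  # pragma: no cover
            raise RuntimeError("screening cap reached; check penetrance/pedigree")
        dam = int(rng.integers(cfg.n_g2_dams))
        n_screened += 1
        causal_dos = _offspring_dosage(ped, dam, cfg, rng, chroms=[causal_chrom])
        affected = causal_dos[causal_chrom][causal_idx] == 2 and (
            rng.random() < cfg.penetrance
        )
        if affected:
            rest = _offspring_dosage(ped, dam, cfg, rng, chroms=other_chroms)
            rest[causal_chrom] = causal_dos[causal_chrom]
            pool.append(rest)
            mouse_dams.append(dam)

    pool_dosage = {
        c: np.stack([m[c] for m in pool]).astype(np.int8) for c in muts.positions
    }
    dosage_sum = {c: pool_dosage[c].sum(axis=0) for c in pool_dosage}
    depth, alt = _pool_reads(cfg, dosage_sum, rng)
    dam_carrier = {
        c: np.stack([g.carried[c] for g in ped.dam_gametes]) for c in muts.positions
    }
    return SimOutput(
        config=cfg,
        mutations=muts,
        pool_dosage=pool_dosage,
        mouse_dams=mouse_dams,
        dam_carrier=dam_carrier,
        depth=depth,
        alt_depth=alt,
        n_screened=n_screened,
        n_affected_screened=len(pool),
        pedigree=ped,
    )


def spike_outlier(
    output: SimOutput, cfg: SimConfig, rng: np.random.Generator
) -> SimOutput:
    """Replace one pooled mouse with a non-homozygous mouse and regenerate
    the pooled reads.

    Models the failure mode strict homozygosity mapping is vulnerable to: a
    phenocopy, a penetrant heterozygote, or a sample mix-up entering the
    pool.  With a heterozygous outlier the causal-site NAF expectation drops
    from 1 to (2N-1)/2N.
    """
    if cfg.pool_size < 2:
        raise ValueError("spiking requires pool_size >= 2")
    if output.pedigree is None:
        raise ValueError("output lacks pedigree state; rerun simulate_cross")
    ped = output.pedigree
    causal_chrom, causal_idx = output.mutations.causal
    for _ in range(100_000):
        dam = int(rng.integers(cfg.n_g2_dams))
        dos = _offspring_dosage(ped, dam, cfg, rng)
        if dos[causal_chrom][causal_idx] < 2:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw a non-homozygous mouse")
    victim = int(rng.integers(cfg.pool_size))
    pool_dosage = {c: d.copy() for c, d in output.pool_dosage.items()}
    for c in pool_dosage:
        pool_dosage[c][victim] = dos[c]
    mouse_dams = list(output.mouse_dams)
    mouse_dams[victim] = dam
    dosage_sum = {c: pool_dosage[c].sum(axis=0) for c in pool_dosage}
    depth, alt = _pool_reads(cfg, dosage_sum, rng)
    return replace(
        output,
        pool_dosage=pool_dosage,
        mouse_dams=mouse_dams,
        depth=depth,
        alt_depth=alt,
        spiked_index=victim,
    )


def simulate_screen(
    cfg: SimConfig, rng: np.random.Generator, n_offspring: int, litter_size: int = 40
) -> tuple[int, int]:
    """Screen ``n_offspring`` G3 mice across fresh unconditioned pedigrees.

    Unlike :func:`simulate_cross`, dam sets are NOT conditioned on containing
    a carrier, so the affected fraction estimates the unconditional expected
    mutant frequency (1/8 x penetrance).  Only the causal chromosome is
    transmitted, which is sufficient for phenotype status.  Returns
    (n_affected, n_screened).
    """
    affected = 0
    screened = 0
    chrom = None
    while screened < n_offspring:
        muts = draw_mutations(cfg, rng)
        chrom, idx = muts.causal
        g1_mut = Haplotype.uniform(muts, True)
        g1_wt = Haplotype.uniform(muts, False)
        ped = _Pedigree(
            muts,
            g1_mut,
            g1_wt,
            [meiosis(g1_mut, g1_wt, cfg, rng, chroms=[chrom]) for _ in range(cfg.n_g2_dams)],
        )
        wt = Haplotype.uniform(muts, False)
        for _ in range(min(litter_size, n_offspring - screened)):
            dam = int(rng.integers(cfg.n_g2_dams))
            pat = meiosis(ped.g1_mut, ped.g1_wt, cfg, rng, chroms=[chrom])
            mat = meiosis(ped.dam_gametes[dam], wt, cfg, rng, chroms=[chrom])
            dosage = int(pat.carried[chrom][idx]) + int(mat.carried[chrom][idx])
            screened += 1
            if dosage == 2 and rng.random() < cfg.penetrance:
                affected += 1
    return affected, screened
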