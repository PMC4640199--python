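import numpy as np
import pytest

from enumapper.variant_model import FunctionalAnnotation, GenomeLayout, Variant


@pytest.fixture
def layout():
    """Small genome: three 50 Mb autosomes plus sex chromosomes."""
    return GenomeLayout(
        (("1", 50_000_000), ("2", 50_000_000), ("3", 50_000_000),
         ("X", 40_000_000), ("Y", 10_000_000)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_variant(chrom="1", pos=1000, ref="A", alts=("T",), qual=60.0,
                 depth=20, alt_depth=20, category=None, gene=None, **kw):
    ann = None
    if category is not None:
        aa = "A1>B" if category in {"exonic_nonsynonymous", "exonic_synonymous",
                                    "stopgain", "stoploss"} else None
        ann = FunctionalAnnotation(gene=gene, category=category, aa_change=aa)
    return Variant(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
                   depth=depth, alt_depth=alt_depth, annotation=ann, **kw)
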