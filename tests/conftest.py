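import numpy as np
import pytest

from tsmr.harmonize import HarmonizedInstrument
from tsmr.summary_io import SummaryStats, VariantAssociation


def mk_inst(gamma, se_gamma, alpha, se_alpha, variant_id=None, action="aligned"):
    return HarmonizedInstrument(
        variant_id=variant_id or f"rs{abs(hash((gamma, alpha))) % 10_000}",
        gamma=gamma,
        se_gamma=se_gamma,
        alpha=alpha,
        se_alpha=se_alpha,
        action=action,
    )


def mk_instruments(gamma, se_g, alpha, se_a):
    """Vector version: arrays -> list of HarmonizedInstrument."""
    return [
        HarmonizedInstrument(
            variant_id=f"rs{j}", gamma=float(g), se_gamma=float(sg),
            alpha=float(a), se_alpha=float(sa), action="aligned",
        )
        for j, (g, sg, a, sa) in enumerate(zip(gamma, se_g, alpha, se_a))
    ]


def mk_record(variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
              eaf=0.3, beta=0.1, se=0.02, pvalue=1e-8, n=10000.0):
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=oa, eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


def mk_stats(records, trait="trait", trait_type="quantitative"):
    return SummaryStats(trait_name=trait, records=list(records), trait_type=trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)
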