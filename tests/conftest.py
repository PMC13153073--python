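import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SummaryDataset, VariantAssociation


def build_hset(beta_exp, beta_out, se_out, se_exp=None, exposure_id="exposure",
               outcome_id="outcome"):
    """Assemble a HarmonizedSet directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.broadcast_to(np.asarray(se_out, float), beta_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.broadcast_to(np.asarray(se_exp, float), beta_exp.shape)
    pairs = pd.DataFrame({
        "variant_id": [f"s{i}" for i in range(len(beta_exp))],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "flipped": False,
    })
    return HarmonizedSet(exposure_id, outcome_id, pairs)


def make_variant(variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.1, se=0.02, pval=1e-9, n=10000.0, trait_id="trait"):
    return VariantAssociation(variant_id, chrom, pos, ea, oa, eaf, beta, se, pval,
                              n, trait_id)


def make_dataset(records, trait_id="trait", trait_type="binary"):
    return SummaryDataset.from_records(trait_id, records, trait_type)


@pytest.fixture
def worked_hset():
    """3-variant fixture whose IVW/Egger/weighted-median values are known in
    closed form: ratios (0.4, 0.6, 0.4) with weights (25, 100, 56.25)."""
    return build_hset([0.1, 0.2, 0.15], [0.04, 0.12, 0.06], 0.02)


@pytest.fixture
def proportional_hset():
    """Noise-free proportional fixture: beta_out = 0.5 * beta_exp exactly."""
    bx = np.array([0.08, 0.1, 0.15, 0.2, 0.25])
    return build_hset(bx, 0.5 * bx, 0.02)
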