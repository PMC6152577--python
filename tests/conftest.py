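import numpy as np
import pytest

from tsmr.harmonize import HarmonizedInstrument
from tsmr.summary_io import SummaryDataset, SummaryRecord


def make_instruments(gamma, Gamma, se_Gamma, se_gamma=None):
    """Build harmonized instruments from parallel effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_Gamma = np.broadcast_to(np.asarray(se_Gamma, dtype=float), gamma.shape)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    else:
        se_gamma = np.broadcast_to(np.asarray(se_gamma, dtype=float), gamma.shape)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{j + 1}",
            gamma=float(gamma[j]),
            se_gamma=float(se_gamma[j]),
            Gamma=float(Gamma[j]),
            se_Gamma=float(se_Gamma[j]),
        )
        for j in range(len(gamma))
    ]


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-6,
                eaf=0.3, n=10000):
    return SummaryRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, n=n,
    )


def make_dataset(records, trait_type="continuous", name="trait"):
    return SummaryDataset(records=list(records), trait_name=name, trait_type=trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)
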