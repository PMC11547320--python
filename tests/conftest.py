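import numpy as np
import pandas as pd
import pytest

from mrpipe.summary_stats import GwasSummary, HarmonizedData, SnpAssociation

ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def make_snp(rsid="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
             beta=0.02, se=0.002, pval=1e-10, n=100_000, n_case=None):
    return SnpAssociation(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea,
                          other_allele=oa, eaf=eaf, beta=beta, se=se,
                          pval=pval, n=n, n_case=n_case)


def make_gwas(records, trait="trait", trait_type="quantitative", n=100_000,
              n_case=None):
    return GwasSummary(trait=trait, trait_type=trait_type, n=n,
                       records=list(records), n_case=n_case)


def make_harmonized(beta_exp, se_exp, beta_out, se_out, binary=False,
                    rsids=None, eaf=None):
    """HarmonizedData straight from effect arrays (for estimator tests)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = beta_exp.size
    rsids = rsids or [f"rs{j + 1}" for j in range(k)]
    snps = pd.DataFrame({
        "rsid": rsids,
        "beta_exp": beta_exp,
        "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (k,)),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (k,)),
        "eaf_exp": np.broadcast_to(np.asarray(0.3 if eaf is None else eaf), (k,)),
    })
    return HarmonizedData(
        exposure_trait="exposure", outcome_trait="outcome", snps=snps,
        dropped=pd.DataFrame(columns=["rsid", "reason"]),
        outcome_trait_type="binary" if binary else "quantitative")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
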