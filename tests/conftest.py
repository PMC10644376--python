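import numpy as np
import pytest

from mrkit.summary_io import HarmonizedPair, SummaryRecord


def make_pair(snp_id="rs1", beta_x=0.2, se_x=0.02, beta_y=0.05, se_y=0.02,
              pval_x=1e-10, pval_y=0.3, **kw):
    return HarmonizedPair(
        snp_id=snp_id, effect_allele=kw.pop("effect_allele", "A"),
        other_allele=kw.pop("other_allele", "G"),
        beta_x=beta_x, se_x=se_x, pval_x=pval_x,
        beta_y=beta_y, se_y=se_y, pval_y=pval_y, **kw)


def make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.1,
                se=0.02, pval=1e-9, **kw):
    return SummaryRecord(snp_id=snp_id, effect_allele=effect_allele,
                         other_allele=other_allele, beta=beta, se=se,
                         pval=pval, **kw)


def random_pairs(rng, j, beta=0.2):
    """Clean instrument pairs around a true ratio ``beta``."""
    bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.03, j)
    sy = rng.uniform(0.05, 0.4, j)
    by = rng.normal(beta * bx, sy)
    return [make_pair(f"rs{k}", bx[k], sx[k], by[k], sy[k]) for k in range(j)]


class ArrayInstruments:
    """Minimal instruments adapter over plain arrays (fast replicate studies)."""

    def __init__(self, beta_x, se_x, beta_y, se_y):
        self._a = (np.asarray(beta_x, float), np.asarray(se_x, float),
                   np.asarray(beta_y, float), np.asarray(se_y, float))
        self.snp_ids = [f"s{i}" for i in range(len(self._a[0]))]

    def __len__(self):
        return len(self._a[0])

    def arrays(self):
        return self._a

    @classmethod
    def from_sim(cls, arrays_dict):
        return cls(arrays_dict["beta_x"], arrays_dict["se_x"],
                   arrays_dict["beta_y"], arrays_dict["se_y"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
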