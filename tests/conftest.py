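import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixedstock import BaselineTable, HaplotypeRecord, MixedStockTable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, length))


@pytest.fixture
def toy_tables():
    """Three rookeries, four haplotypes, two mixed stocks, full covariates."""
    baseline = BaselineTable(
        rookery_codes=["AAA", "BBB", "CCC"],
        haplotype_names=["h1", "h2", "h3", "h4"],
        X=np.array([[12, 3, 0, 0], [0, 8, 7, 0], [1, 0, 2, 9]]),
        N=np.array([1200.0, 300.0, 5000.0]),
        p=np.array([[0.2, 0.1], [0.0, 0.4], [0.3, 0.3]]),
        p_stocks=["N", "E"],
    )
    mixed = MixedStockTable(
        stock_codes=["N", "E"],
        haplotype_names=["h1", "h2", "h3", "h4"],
        Y=np.array([[9, 5, 4, 2], [1, 2, 3, 4]]),
    )
    return baseline, mixed


@pytest.fixture
def eia_family():
    """Synthetic stand-ins for the EiA23 short-fragment family.

    Seven long-fragment hawksbill haplotypes that are literally identical over
    the first 490 positions and differ only beyond it, plus two haplotypes
    that differ inside the window.  These are generated sequences (the real
    ones are not redistributable here); only the collapse structure matters.
    """
    rng = np.random.default_rng(20221030)
    base = random_sequence(rng, 820)
    family_names = ["EiA23", "EiA24", "EiA39", "EiA41", "EiA42", "EiA43", "EiA83"]
    records = []
    for i, name in enumerate(family_names):
        seq = list(base)
        if i > 0:  # EiA23 is the reference itself; others differ beyond the window
            pos = 500 + 7 * i
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        records.append(HaplotypeRecord(name=name, sequence="".join(seq), species="Ei",
                                       fragment_class="long"))
    for name, pos in [("EiA1", 101), ("EiA9", 222)]:
        seq = list(base)
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        records.append(HaplotypeRecord(name=name, sequence="".join(seq), species="Ei",
                                       fragment_class="long"))
    return records
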