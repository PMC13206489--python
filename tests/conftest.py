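import numpy as np
import pytest

from dynlr.bn_model import ThetaModel
from dynlr.frequencies import (
    AlleleFrequencyTable,
    LocusFrequencies,
    apply_pmin,
)
from dynlr.popsim import synthetic_frequency_table


def make_table(spec: dict[str, tuple[tuple[str, ...], tuple[float, ...]]],
               n_typed: int = 100000) -> AlleleFrequencyTable:
    """Hand-build a corrected table; huge N keeps p_min from biting."""
    loci_data = {
        name: LocusFrequencies(
            name=name, ladder=ladder, frequencies=np.array(freqs),
            n_typed=n_typed,
        )
        for name, (ladder, freqs) in spec.items()
    }
    return apply_pmin(AlleleFrequencyTable(loci_data=loci_data))


@pytest.fixture(scope="session")
def toy_table() -> AlleleFrequencyTable:
    """Small exactly-known loci: a 2-allele coin locus and two 3-allele loci."""
    return make_table(
        {
            "COIN": (("10", "11"), (0.5, 0.5)),
            "TRI": (("7", "8", "9"), (0.1, 0.2, 0.7)),
            "SKEW": (("12", "13", "14"), (0.05, 0.15, 0.8)),
        }
    )


@pytest.fixture(scope="session")
def table6() -> AlleleFrequencyTable:
    """6-locus synthetic fixture used for the convolution oracle checks."""
    return synthetic_frequency_table(6, seed=1)


@pytest.fixture(scope="session")
def table10() -> AlleleFrequencyTable:
    """10-locus synthetic fixture used for the study-scale analyses."""
    return synthetic_frequency_table(10, seed=7)


@pytest.fixture(scope="session")
def model() -> ThetaModel:
    return ThetaModel(0.01)


@pytest.fixture(scope="session")
def model_hwe() -> ThetaModel:
    return ThetaModel(0.0)
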