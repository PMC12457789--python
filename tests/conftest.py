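import numpy as np
import pytest
from hypothesis import settings

from rutinseq.simulate import AseSimSpec, random_sequences
from rutinseq.types import LineSpec, LocusInfo, RunConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_lines():
    return [
        LineSpec("HI", "SI", "mixed", 0.60, 0.10),
        LineSpec("LO", "SC", "long_homostyle", 0.10, 0.03),
    ]


@pytest.fixture
def hom_alt_locus():
    """One 62-bp locus where every position is maternal hom-alt.

    After the default 6-bp end trimming, 50 ratio-informative (pattern II)
    positions remain.
    """
    loci = [LocusInfo("L1", "PAL", 62)]
    sequences = random_sequences({"L1": 62}, seed=11)
    return loci, sequences


def make_ase_spec(loci, sequences, pi=0.3, depth=200.0, eps=0.0, seed=5, **kw):
    defaults = dict(
        maternal_het_rate=0.0, maternal_hom_alt_rate=1.0,
        multiallelic_rate=0.0,
    )
    defaults.update(kw)
    return AseSimSpec(
        loci=loci, sequences=sequences, true_pollen_fraction=pi,
        mean_depth=depth, base_error=eps, rng_seed=seed, **defaults,
    )


@pytest.fixture
def noise_free_config():
    """Analysis thresholds matched to an error-free simulation.

    With zero sequencing error every observed base is a real allele, so
    allele-presence filtering is unnecessary and would otherwise truncate
    low pollen-fraction sites.
    """
    return RunConfig(min_allele_count=1, min_allele_fraction=0.0)
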