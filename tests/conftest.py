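import numpy as np
import pytest

from polycapture import SimulationConfig, simulate_world
from polycapture.variant_caller import GenotypeCall, RawSnp


@pytest.fixture(scope="session")
def small_world():
    """A 2x50 kb A/C world with targets and planted truth, shared by
    read-level tests."""
    cfg = SimulationConfig(seed=7, chrom_length=50_000)
    bundle, truth = simulate_world(cfg)
    return cfg, bundle, truth


def make_call(
    lid, genotype, alt=None, depth=20, alt_fraction=0.0, biased=False
) -> GenotypeCall:
    return GenotypeCall(
        line_id=lid,
        genotype=genotype,
        alt_allele=alt,
        depth=depth,
        alt_fraction=alt_fraction,
        biased=biased,
    )


def make_snp(seq="A1", pos=1000, ref="A", alts=("G",), calls=None) -> RawSnp:
    """RawSnp factory; ``calls`` maps line id to a GenotypeCall or a
    shorthand genotype string."""
    if calls is None:
        calls = {"line_0": "hom_alt"}
    vector = {}
    for lid, c in calls.items():
        if isinstance(c, str):
            alt = sorted(alts)[0] if c in ("hom_alt", "het") else None
            af = {"hom_alt": 1.0, "het": 0.5}.get(c, 0.0)
            c = make_call(lid, c, alt=alt, alt_fraction=af)
        vector[lid] = c
    return RawSnp(
        seq_name=seq,
        position=pos,
        ref_allele=ref,
        alt_alleles=set(alts),
        calls=vector,
    )
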