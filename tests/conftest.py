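import numpy as np
import pytest

import capture3c as c3


@pytest.fixture(scope="session")
def toy_map():
    """Two small chromosomes with hand-placed cut sites."""
    return c3.RestrictionMap(
        chrom_sites={"chrA": np.array([1000, 5000, 9000]),
                     "chrB": np.array([2000, 4000])},
        chrom_lengths={"chrA": 12000, "chrB": 8000})


@pytest.fixture(scope="session")
def toy_design(toy_map):
    """One locus spanning all chrA cut sites, flank 250."""
    loci = [c3.TargetLocus(name="locus1", chrom="chrA", start=750, end=9250,
                           prefix="")]
    baits = c3.design_baits(toy_map, loci, flank=250)
    return toy_map, loci, baits


@pytest.fixture(scope="session")
def default_library():
    """One simulated library at the default (study-like) composition."""
    return c3.simulate_library(c3.SimConfig(seed=20160316))


@pytest.fixture(scope="session")
def default_contact_table(default_library):
    from capture3c.pipeline import extract_stage

    lib = default_library
    classified, table = extract_stage(lib["rmap"], lib["baits"], lib["loci"],
                                      lib["pairs"], 250)
    return classified, table
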