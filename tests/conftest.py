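import numpy as np
import pytest

import casim


@pytest.fixture(scope="session")
def fixture_karyotype():
    return casim.Karyotype.uniform_fixture(4, 10_000_000)


@pytest.fixture(scope="session")
def small_nucleus():
    return casim.NucleusGeometry.sphere(2.0)


@pytest.fixture(scope="session")
def small_genome(small_nucleus, fixture_karyotype):
    return casim.build_genome(small_nucleus, fixture_karyotype, seed=11)


@pytest.fixture(scope="session")
def small_genome_constrained(small_nucleus, fixture_karyotype):
    return casim.build_genome(small_nucleus, fixture_karyotype, seed=11,
                              intermingle=False)


def make_dsbs(karyotype, placements, complexity="complex"):
    """Hand-built break list: placements = [(chrom_index, bp, xyz_um), ...]."""
    dsbs = []
    for i, item in enumerate(placements):
        ci, bp = item[0], item[1]
        pos = np.asarray(item[2], dtype=float) if len(item) > 2 \
            else np.zeros(3)
        chrom = karyotype.chromosomes[ci]
        dsbs.append(casim.DSBRecord(
            id=i, chromosome=chrom.id, chromosome_index=ci,
            monomer=0, genomic_bp=bp, position_um=pos,
            voxel_energy_ev=1000.0 if complexity == "complex" else 0.0,
            complexity=complexity))
    return dsbs


def make_events(pairs, dsbs, t0=1.0):
    """Junction log from end-id pairs; kind derived from cognate relation."""
    events = []
    for k, (a, b) in enumerate(pairs):
        kind = "proper" if a ^ 1 == b else "improper"
        events.append(casim.RejoinEvent(t0 + k, a, b, kind))
    return events
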