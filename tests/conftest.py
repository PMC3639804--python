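import pytest

from hfrscan import SimConfig, simulate_cluster


@pytest.fixture(scope="session")
def sim_dataset():
    """One synthetic cluster under the default study conditions (seed 0)."""
    return simulate_cluster(SimConfig(seed=0))


def make_track(nlrs, chrom="chrT", start=0, step=50, length=60, antibody="panH3"):
    """A contiguous overlapping-tiled probe track from a list of NLRs."""
    from hfrscan import Probe, ProbeTrack

    probes = [
        Probe(chrom, start + i * step, start + i * step + length, float(v))
        for i, v in enumerate(nlrs)
    ]
    return ProbeTrack(probes, antibody=antibody)
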