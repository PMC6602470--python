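import pytest

from amplimeth.simulate import SimulationSpec, build_panel, simulate_reads
from amplimeth.targets import TargetRegion, locate_primers


@pytest.fixture
def micro_target() -> TargetRegion:
    """The 5 nt worked example: S="AACGT", one CpG at position 2, no primers."""
    return locate_primers(
        TargetRegion(target_id="micro", chrom="micro", start=0, end=5,
                     sequence="AACGT")
    )


@pytest.fixture(scope="session")
def clean_panel():
    """Error-free two-pattern panel shared across tests: 70% fully
    methylated / 30% unmethylated molecules, conversion 1.0, no errors."""
    spec = SimulationSpec(
        n_targets=3,
        n_cpgs_per_target=4,
        mixtures=None,
        conversion_efficiency=1.0,
        sequencing_error_rate=0.0,
        reads_per_sample_per_target=150,
        samples=("s1", "s2"),
        rng_seed=11,
    )
    contig, targets, _ = build_panel(spec)
    mixtures = {t.target_id: [("MMMM", 0.7), ("UUUU", 0.3)] for t in targets}
    spec = SimulationSpec(
        n_targets=3,
        n_cpgs_per_target=4,
        mixtures=mixtures,
        conversion_efficiency=1.0,
        sequencing_error_rate=0.0,
        reads_per_sample_per_target=150,
        samples=("s1", "s2"),
        rng_seed=11,
    )
    reads, truth = simulate_reads(spec, targets)
    return spec, targets, reads, truth
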