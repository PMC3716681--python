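"""Shared small-genome configuration for I/O and CLI tests."""

from rdcnv.simulate import ChromSpec, GenomeConfig


def small_config() -> GenomeConfig:
    return GenomeConfig(
        chromosomes=(
            ChromSpec("chr1", 2_000_000),
            ChromSpec("chrX", 1_000_000, is_x=True),
        ),
        n_genes=40,
        n_sds=10,
        n_event_sites=8,
        par=(0, 100_000),
    )
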