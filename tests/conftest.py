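import numpy as np
import pandas as pd
import pytest

from rdcnv.cn import CnTrack
from rdcnv.evaluate import RECOVERY_CNV_PARAMS, run_cohort_pipeline
from rdcnv.grid import BinGrid
from rdcnv.simulate import (
    CnvParams,
    GenomeConfig,
    build_genome,
    default_cohort,
    simulate_truth,
)


def make_uniform_grid(
    n_bins: int = 100,
    bin_size: int = 1000,
    gc: float = 0.42,
    chrom: str = "chr1",
    masked=None,
) -> BinGrid:
    """A single-chromosome grid with constant GC, for constructed tracks."""
    masked_arr = np.zeros(n_bins) if masked is None else np.asarray(masked, dtype=float)
    return BinGrid(
        chromosomes=((chrom, n_bins * bin_size),),
        bin_size=bin_size,
        gc=np.full(n_bins, gc),
        masked_frac=masked_arr,
        is_x=(False,),
    )


def make_cn_track(values, individual="ind", excluded=None) -> CnTrack:
    values = np.asarray(values, dtype=float)
    if excluded is None:
        excluded = np.isnan(values)
    return CnTrack(individual, values, np.asarray(excluded, dtype=bool))


@pytest.fixture(scope="session")
def toy_grid():
    return make_uniform_grid(n_bins=100)


@pytest.fixture(scope="session")
def default_genome():
    return build_genome(GenomeConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort():
    return default_cohort()


@pytest.fixture(scope="session")
def sim_run(default_genome, cohort):
    """One full simulated-cohort pipeline run shared across tests.

    Returns a dict with the genome, truth profiles, CN tracks, MCRs, merged
    regions, called CNVRs and the per-individual estimation by-products.
    """
    truth = simulate_truth(default_genome, cohort, RECOVERY_CNV_PARAMS, seed=11)
    cnvrs, cn_tracks, mcrs, extras = run_cohort_pipeline(
        default_genome, cohort, truth, seed=11
    )
    return {
        "genome": default_genome,
        "truth": truth,
        "cnvrs": cnvrs,
        "cn_tracks": cn_tracks,
        "mcrs": mcrs,
        **extras,
    }


def regions_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
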