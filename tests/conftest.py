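import numpy as np
import pytest

from chromatlas import pipeline, simulate
from chromatlas.genomic import GenomeLayout, GenomicInterval


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout.from_dict({"chr1": 100_000, "chr2": 50_000})


def random_intervals(rng, layout, n, max_len=500):
    out = []
    for _ in range(n):
        chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, layout.length_of(chrom) - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_overlap(q: GenomicInterval, subjects) -> bool:
    return any(q.overlaps(s) for s in subjects)


SMALL_COHORT = dict(
    seed=7, n_genes=60, n_enhancers=60, n_specific_pa=6, n_specific_gb=6,
    n_linked=5, n_decoy_loops=20, library_size=20_000,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A scaled-down cohort for fast pipeline-level tests."""
    d = tmp_path_factory.mktemp("small_cohort")
    cohort = simulate.generate(simulate.CohortConfig(**SMALL_COHORT), d)
    return cohort


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The full default cohort (24 samples, default noise), pipeline run
    end to end.  Shared by the planted-recovery checks."""
    cdir = tmp_path_factory.mktemp("default_cohort")
    odir = tmp_path_factory.mktemp("default_results")
    cohort = simulate.generate(simulate.CohortConfig(seed=1), cdir)
    stages = [s for s in pipeline.STAGES if s != "generate"]
    pipeline.run(cdir, odir, stages=stages)
    return cohort, odir


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory):
    """Default-size cohort with zero peak noise (exact-recovery regime)."""
    cdir = tmp_path_factory.mktemp("clean_cohort")
    odir = tmp_path_factory.mktemp("clean_results")
    cohort = simulate.generate(
        simulate.CohortConfig(seed=2, dropout=0.0, spurious=0.0), cdir
    )
    pipeline.run(cdir, odir, stages=["atlas", "report"])
    return cohort, odir
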