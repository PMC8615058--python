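import numpy as np
import pandas as pd
import pytest

from methdiff.io_formats import assemble_matrix
from methdiff.pipeline import run_pipeline
from methdiff.preprocess import PipelineConfig, compute_ratios, correct_batch, filter_sites
from methdiff.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (seed 1): 6 controls, 7+7 cases, ~20k CpGs."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full pipeline run on the default cohort."""
    return run_pipeline(
        default_cohort.tables,
        default_cohort.sheet,
        comparisons=("MD_vs_control", "MDH_vs_control", "MDL_vs_control"),
        genes=default_cohort.genes,
        islands=default_cohort.islands,
    )


@pytest.fixture(scope="session")
def default_ratios(default_cohort):
    matrix = assemble_matrix(default_cohort.tables, default_cohort.sheet)
    cfg = PipelineConfig()
    return correct_batch(compute_ratios(filter_sites(matrix, cfg)), clip=cfg.logit_clip)


def toy_matrix(meth, total, groups=None, batches=None, chroms=None, positions=None):
    """Small MethylomeMatrix from explicit arrays (sites x samples)."""
    from methdiff.io_formats import MethylomeMatrix

    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n_sites, n_samples = meth.shape
    samples = [f"S{i}" for i in range(n_samples)]
    groups = groups or (["control"] * (n_samples // 2) + ["MDH"] * (n_samples - n_samples // 2))
    batches = batches or ["batch0"] * n_samples
    sites = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * n_sites,
            "pos": positions if positions is not None else np.arange(n_sites) * 100,
        }
    )
    return MethylomeMatrix(
        sites=sites,
        meth=meth,
        total=total,
        samples=samples,
        group=pd.Series(groups, index=samples),
        batch=pd.Series(batches, index=samples),
    )
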