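import numpy as np
import pandas as pd
import pytest

from dwmeta import decontam, simulate, workflow


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (6 systems, 18 samples)."""
    return simulate.generate_study(simulate.StudyConfig(seed=7))


@pytest.fixture(scope="session")
def analysis(study):
    return workflow.analyze_study(study, seed=7)


@pytest.fixture
def small_table():
    """Hand-built two-system scaffold table with known coverage statistics."""
    meta = pd.DataFrame(
        {
            "system": ["S1", "S1", "S1", "S2", "S2"],
            "length": [1000, 2000, 499, 500, 3000],
            "gc": [0.5, 0.6, 0.4, 0.55, 0.45],
        },
        index=pd.Index(["a", "b", "c", "d", "e"], name="scaffold_id"),
    )
    samples = ["s1", "s2"]
    controls = ["nc1"]
    cov = pd.DataFrame(
        [[4.0, 2.0], [1.0, 3.0], [2.0, 2.0], [5.0, 0.0], [0.0, 1.0]],
        index=meta.index,
        columns=samples,
    )
    cov_sd = cov * 0.25
    contam = pd.DataFrame([[0.0], [0.0], [0.0], [2.0], [0.0]], index=meta.index, columns=controls)
    nc = contam * 1.25
    return decontam.ScaffoldTable(
        meta=meta,
        cov=cov,
        cov_sd=cov_sd,
        contam_cov=contam,
        contam_cov_sd=contam * 0.5,
        nc_cov=nc,
        sample_systems={"s1": "S1", "s2": "S1"},
    )
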