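import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture()
def worked_example():
    """The 21 published multi-omics records re-encoded as integration inputs."""
    from triomix.datasets import il6_kidney_inputs

    return il6_kidney_inputs()


@pytest.fixture()
def small_counts():
    """A 3-feature, 2+2-sample count matrix."""
    from triomix import CountMatrix

    values = pd.DataFrame(
        {"c1": [10, 100, 40], "c2": [12, 90, 38], "t1": [11, 95, 41], "t2": [9, 105, 37]},
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
    )
    groups = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
    return CountMatrix(values, groups)


@pytest.fixture()
def meth_table():
    """Two-region methylation table with 2 samples per group."""
    from triomix import MethylRegionTable

    idx = pd.Index(["r1", "r2"], name="region_id")
    regions = pd.DataFrame(
        [("chr1", 0, 100, "CpG"), ("chr1", 500, 600, "CHH")],
        index=idx, columns=["chrom", "start", "end", "context"],
    )
    meth = pd.DataFrame([[5, 5, 25, 25], [10, 12, 9, 11]], index=idx,
                        columns=["c1", "c2", "t1", "t2"])
    unmeth = pd.DataFrame([[45, 45, 25, 25], [20, 18, 21, 19]], index=idx,
                          columns=["c1", "c2", "t1", "t2"])
    groups = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
    return MethylRegionTable(regions, meth, unmeth, groups)
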