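import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hemomir.cq_data import CqTable, SampleSheet
from hemomir.synth import generate_paired_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cq_table(values: dict, mirs: list[str]) -> CqTable:
    """values: {(sample, replicate): [cq per mir]} with None = undetected."""
    cols = pd.MultiIndex.from_tuples(list(values), names=["sample_id", "replicate"])
    data = np.array(
        [[np.nan if v is None else float(v) for v in values[c]] for c in values]
    ).T
    return CqTable(pd.DataFrame(data, index=mirs, columns=cols))


def make_pair_sheet(pair_a414: dict[str, tuple[float, float]], rbc: bool = True) -> SampleSheet:
    """pair_a414: {pair_id: (a414_nonhemolyzed, a414_hemolyzed)}."""
    rows = []
    for i, (pid, (a_nh, a_h)) in enumerate(pair_a414.items(), start=1):
        rows.append(dict(sample_id=f"{pid}_NH", subject_id=f"S{i}",
                         condition="non_hemolyzed", pair_id=pid, a414=a_nh,
                         rbc_fraction=np.nan))
        rows.append(dict(sample_id=f"{pid}_H", subject_id=f"S{i}",
                         condition="hemolyzed", pair_id=pid, a414=a_h,
                         rbc_fraction=np.nan))
    if rbc:
        rows.append(dict(sample_id="RBC", subject_id="donor", condition="rbc",
                         pair_id="", a414=np.nan, rbc_fraction=np.nan))
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def paired_study():
    """Default noisy synthetic paired study shared across tests."""
    return generate_paired_study(seed=20260921)


@pytest.fixture(scope="session")
def noise_free_study():
    return generate_paired_study(seed=7, n_mirs=60, noise_sd=0.0)
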