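import pytest

from tma_concord import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-case default-parameter cohort shared across tests."""
    return simulate_cohort(SimulationConfig(n_cases=300, seed=11))


@pytest.fixture()
def core_csv(tmp_path):
    path = tmp_path / "cores.csv"
    path.write_text(
        "case_id,core_id,marker,percent_positive,pct_01,pct_2,pct_3,tumor_nuclei\n"
        "c1,k1,ER,12.5,,,,800\n"
        "c1,k2,ER,0.4,,,,600\n"
        "c2,k1,HER2,,55,30,15,900\n"
        "c2,k2,HER2,,90,8,2,400\n"
        "c3,k1,PR,5.0,,,,40\n"
        "c3,k2,PR,6.0,,,,700\n"
        "c3,k3,PR,7.0,,,,700\n"
    )
    return path


@pytest.fixture()
def clinical_csv(tmp_path):
    path = tmp_path / "clinical.csv"
    path.write_text(
        "case_id,er_status,pr_status,her2_status\n"
        "c1,positive,negative,negative\n"
        "c2,negative,negative,positive\n"
        "c3,positive,positive,negative\n"
    )
    return path
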