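import pytest

from polydose import (
    AllelicConfiguration,
    AssayPanel,
    CalibratorSpec,
    NoiseModel,
    allele_signals,
    simulate_plate,
)


@pytest.fixture(scope="session")
def panel() -> AssayPanel:
    return AssayPanel()


@pytest.fixture(scope="session")
def het_calibrator() -> CalibratorSpec:
    return CalibratorSpec.heterozygous_diploid()


def dosage_for_fraction(p, ct_sd=0.0, seed=0, replicates=3):
    """Simulate one sample at allele-A fraction p and analyse it."""
    panel = AssayPanel()
    cal = CalibratorSpec.heterozygous_diploid()
    records = simulate_plate(
        p, NoiseModel(ct_sd=ct_sd, seed=seed), panel, replicates=replicates,
        sample_id="s", calibrator=cal,
    )
    cal_cts = [r for r in records if r.sample_id == cal.sample_id]
    s_cts = [r for r in records if r.sample_id == "s"]
    return allele_signals(s_cts, cal, cal_cts, panel)


@pytest.fixture(scope="session")
def measure_b():
    return dosage_for_fraction
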