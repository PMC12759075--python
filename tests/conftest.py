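import pandas as pd
import pytest
from hypothesis import settings

from lipdiff.differential import ThresholdConfig
from lipdiff.synthetic_data import SimConfig, SimDataset, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_dataset() -> SimDataset:
    """A small simulated experiment with perturbed proteins, abundance
    shifts and a planted cofactor association."""
    cfg = SimConfig(n_proteins=60, frac_perturbed_proteins=0.15, seed=42)
    return simulate_dataset(cfg, planted_cofactor="heme")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_dataset) -> "pytest.TempPathFactory":
    """The small dataset written to disk as a complete fixture."""
    from lipdiff.synthetic_data import write_fixture

    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, directory)
    return directory


def make_ion_frame(rows, sample_cols):
    """Build an ion table from (protein_id, peptide, charge, mod, start, end,
    intensities...) tuples; None intensities become NaN."""
    records = []
    for row in rows:
        rec = dict(zip(["protein_id", "peptide", "charge", "mod_key",
                        "start", "end"], row[:6]))
        for col, val in zip(sample_cols, row[6:]):
            rec[col] = float("nan") if val is None else float(val)
        records.append(rec)
    frame = pd.DataFrame(records)
    frame["ion_key"] = (frame["peptide"] + "/" + frame["charge"].astype(str)
                        + "/" + frame["mod_key"])
    return frame
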