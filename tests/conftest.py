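import numpy as np
import pandas as pd
import pytest

from pdbq import SyntheticConfig, generate_deposits
from pdbq.ingest import clean_journal_names


@pytest.fixture(scope="session")
def small_synthetic():
    """2 000 deposits with default study conditions; session-cached."""
    return generate_deposits(SyntheticConfig(n_deposits=2000, seed=42))


@pytest.fixture(scope="session")
def medium_synthetic():
    """10 000 deposits with default study conditions; session-cached."""
    return generate_deposits(SyntheticConfig(n_deposits=10_000, seed=7))


@pytest.fixture(scope="session")
def cleaned_medium(medium_synthetic):
    return clean_journal_names(medium_synthetic)


@pytest.fixture
def deposit_csv(tmp_path):
    """Write a 3-row deposit table fixture, one RSRZ value missing."""
    path = tmp_path / "deposits.csv"
    path.write_text(
        "pdb_id,deposition_date,resolution,molecule_class,journal_raw,"
        "clashscore,rama_outliers,rota_outliers,rsrz_outliers,r_free,r_work\n"
        "1ABC,1995-03-02,1.8,protein,FEBS J.,5.0,0.2,2.1,3.0,21.5,18.0\n"
        "2DEF,2001-07-15,2.4,protein,Febs J,12.0,1.0,4.0,,25.0,20.5\n"
        "3GHI,2010-11-30,2.0,nucleic_acid,Nature,7.5,,,5.5,23.0,19.5\n"
    )
    return path
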