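import numpy as np
import pytest

from fossilbridge.pbdb_io import BinnedCounts


@pytest.fixture
def occurrence_csv(tmp_path):
    """Small PBDB-style export: 8 rows, 2 families, one trace fossil,
    one row without species, one without family, one over-wide age range."""
    path = tmp_path / "occ.csv"
    path.write_text(
        "accepted_name,family,collection_no,max_ma,min_ma,pres_mode\n"
        "Alpha primus,Alphidae,1,66.0,60.0,body\n"
        "Alpha primus,Alphidae,1,66.0,60.0,body\n"
        "Alpha secundus,Alphidae,2,45.0,40.0,body\n"
        "Beta tertius,Betidae,3,30.0,28.0,body\n"
        "Beta tertius,Betidae,4,12.0,10.0,body\n"
        ",Alphidae,5,50.0,44.0,body\n"
        "Gamma quartus,,6,33.0,30.0,body\n"
        "Delta footprint,Betidae,7,20.0,18.0,trace\n"
    )
    return path


@pytest.fixture
def extinct_counts():
    """Extinct toy family: fossils in bins 3..6, nothing younger or older."""
    counts = np.zeros(8, dtype=int)
    counts[3] = 2
    counts[4] = 1
    counts[6] = 1
    return BinnedCounts(family="Toyidae", counts=counts, n_extant=0)


@pytest.fixture
def extant_counts():
    counts = np.zeros(5, dtype=int)
    counts[1] = 1
    counts[2] = 1
    return BinnedCounts(family="Livingidae", counts=counts, n_extant=2)
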