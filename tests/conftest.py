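import numpy as np
import pytest

from protstab import ProteinRecord, SyntheticConfig, generate_benchmark

#: The 50-residue example protein used throughout the descriptor literature,
#: whose hydrophobicity CTD values are known exactly.
WORKED_SEQUENCE = "MSDKPDMAEIEKFSKETIEQEKQAGESTQEKNPLPMLLPATDKSKLKKTE"
WORKED_CODED = "HNPPNPHNPHPPHNPPNHPPPPPNNPNNPPPPNHNHHHNNNPPNPHPPNP"


@pytest.fixture(scope="session")
def worked_record() -> ProteinRecord:
    return ProteinRecord(id="worked", sequence=WORKED_SEQUENCE)


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact synthetic benchmark reused across integration tests."""
    cfg = SyntheticConfig(n=60, seed=7, length_range=(50, 300))
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def small_feature_matrix(small_benchmark):
    from protstab.pipeline import build_feature_matrix
    import pandas as pd
    from protstab.io import _KEGG_COLS, _LOC_COLS

    b = small_benchmark
    meta = pd.concat(
        [
            pd.DataFrame({"id": b.ids, "psi": b.psi}),
            pd.DataFrame(b.location_flags, columns=_LOC_COLS),
            pd.DataFrame(b.kegg_scores, columns=_KEGG_COLS),
            pd.DataFrame({"complex_count": b.complex_counts}),
        ],
        axis=1,
    ).set_index("id", drop=False)
    ids, matrix = build_feature_matrix(b.records, meta)
    return ids, matrix, np.asarray(b.classes)
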