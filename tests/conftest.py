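import numpy as np
import pandas as pd
import pytest

from protscape import (
    AssayAnnotation,
    GeneratorConfig,
    IntensityMatrix,
    generate_multistudy,
)


def make_annotation(rows):
    """rows: list of (assay, study, sample, stype, lineage, enzyme)."""
    df = pd.DataFrame(
        [
            {
                "assay_id": a,
                "study_id": st,
                "sample_id": sa,
                "sample_type": ty,
                "lineage": li,
                "replicate_group": sa,
                "enzyme": en,
            }
            for a, st, sa, ty, li, en in rows
        ]
    ).set_index("assay_id")
    return AssayAnnotation(df)


@pytest.fixture
def small_annotation():
    return make_annotation(
        [
            ("a1", "s1", "c1", "cell_line", "breast", "trypsin"),
            ("a2", "s1", "c2", "cell_line", "breast", "trypsin"),
            ("a3", "s2", "t1", "tumour", "colorectal", "trypsin"),
            ("a4", "s2", "t2", "tumour", "colorectal", "gluc"),
        ]
    )


@pytest.fixture
def small_matrix():
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0], [2.0, np.nan, 1.0, 2.0]],
        index=["P1", "P2", "P3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return IntensityMatrix(values=vals, stage="raw_ibaq")


@pytest.fixture(scope="session")
def default_generated():
    cfg = GeneratorConfig(n_proteins=300, seed=11)
    return cfg, generate_multistudy(cfg)
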