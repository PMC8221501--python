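import numpy as np
import pandas as pd
import pytest

from nrnet.preprocess import ExpressionMatrix, SampleAnnotation, Subtype


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, fixed values."""
    frame = pd.DataFrame(
        [[1.0, 2.0, 10.0, 4.0], [5.0, np.nan, 7.0, 6.0], [0.0, 0.0, 0.0, 1.0]],
        index=pd.Index(["FOS", "STAT1", "JUN"], name="gene"),
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(values=frame)


@pytest.fixture
def expression_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "Hugo_Symbol\tEntrez_Gene_Id\tS1\tS2\tS3\tS4\n"
        "FOS\t2353\t1\t2\t10\t4\n"
        "STAT1\t6772\t5\tNA\t7\t6\n"
        "JUN\t3725\t0\t0\t0\t1\n"
    )
    return path


@pytest.fixture
def clinical_tsv(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "#comment line\n"
        "PATIENT_ID\tCLAUDIN_SUBTYPE\n"
        "S1\tBasal\nS2\tLumA\nS3\tclaudin-low\nS4\tHer2\n"
    )
    return path


def annotate(sample_ids, subtypes) -> list[SampleAnnotation]:
    return [
        SampleAnnotation(s, Subtype(t) if isinstance(t, str) else t)
        for s, t in zip(sample_ids, subtypes)
    ]


@pytest.fixture
def matrix_from_array():
    """Build an ExpressionMatrix from a genes x samples ndarray."""

    def build(arr, gene_prefix="G", sample_prefix="S", centred=False):
        arr = np.asarray(arr, dtype=float)
        frame = pd.DataFrame(
            arr,
            index=[f"{gene_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
        )
        return ExpressionMatrix(values=frame, centred=centred)

    return build
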