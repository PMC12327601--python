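import pandas as pd
import pytest

from pathseer.fixtures import generate_toy_dataset
from pathseer.pipeline import RunConfig, run_pipeline

TOY_SEED = 1


@pytest.fixture(scope="session")
def toy():
    """The default synthetic paired-omics dataset with a planted 3-step chain."""
    return generate_toy_dataset(seed=TOY_SEED)


@pytest.fixture(scope="session")
def toy_result(toy):
    """Full pipeline run on the toy dataset with default parameters."""
    return run_pipeline(
        toy.features,
        toy.expression,
        toy.rules,
        toy.adducts,
        toy.metabolite_db,
        toy.annotations,
        RunConfig(),
    )


@pytest.fixture()
def feature_csv(tmp_path):
    """A 3-feature x 4-sample toy feature table on disk."""
    path = tmp_path / "features.csv"
    pd.DataFrame(
        {
            "feature_id": ["M100T10", "M200T20", "M316T772"],
            "mz": [100.5, 200.25, 316.1],
            "rt": [10.0, 20.0, 772.0],
            "s1": [1.0, 0.0, 5.5],
            "s2": [2.0, 1.0, 5.0],
            "s3": [3.0, 2.0, 4.5],
            "s4": [4.0, 3.0, 4.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture()
def expression_csv(tmp_path):
    """A 5-transcript x 6-sample toy expression matrix on disk."""
    path = tmp_path / "expression.csv"
    df = pd.DataFrame(
        [[float(i * 6 + j) for j in range(6)] for i in range(5)],
        index=[f"t{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(6)],
    )
    df.rename_axis("transcript_id").to_csv(path)
    return path
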