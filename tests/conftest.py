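import numpy as np
import pytest

from rots import ExpressionMatrix, GroupAssignment, ROTS, SyntheticSpec, generate
from rots.synthetic import groups_for

# the published example excerpt of a label-free proteomics expression
# matrix: log-scale abundances, 3 + 3 replicates of two sample groups
TABLE1_IDS = ["1", "2", "3", "4"]
TABLE1_SAMPLES = ["A1", "A2", "A3", "B1", "B2", "B3"]
TABLE1_VALUES = np.array(
    [
        [19.263, 19.213, 19.151, 19.138, 19.168, 19.328],
        [25.950, 25.935, 25.950, 24.040, 24.058, 24.078],
        [21.077, 20.982, 21.101, 21.255, 21.263, 21.328],
        [20.691, 20.531, 20.470, 20.921, 20.902, 20.911],
    ]
)


@pytest.fixture
def table1_matrix():
    return ExpressionMatrix(TABLE1_IDS, TABLE1_SAMPLES, TABLE1_VALUES.copy())


@pytest.fixture
def table1_groups():
    return GroupAssignment(["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def table1_tsv(tmp_path):
    path = tmp_path / "table1.tsv"
    lines = ["Feature\t" + "\t".join(TABLE1_SAMPLES)]
    for fid, row in zip(TABLE1_IDS, TABLE1_VALUES):
        lines.append(fid + "\t" + "\t".join(f"{v:.3f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_fit():
    """A quick fitted result on synthetic data with clear signal."""
    spec = SyntheticSpec(G=60, n1=4, n2=4, pi_de=0.2, effect=4.0, seed=11)
    m, truth = generate(spec)
    res = ROTS(m, groups_for(spec)).fit(B=50, K=30, seed=7)
    return m, truth, res


@pytest.fixture(scope="session")
def null_fit():
    """A fitted result on data with no true group differences."""
    spec = SyntheticSpec(G=500, n1=5, n2=5, pi_de=0.0, effect=0.0, seed=5)
    m, truth = generate(spec)
    res = ROTS(m, groups_for(spec)).fit(B=50, K=100, seed=5)
    return m, truth, res
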