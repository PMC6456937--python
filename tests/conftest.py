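import numpy as np
import pytest

from ela.normalize import rank_normal_transform


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def abundance_file(tmp_path):
    """Factory writing a small tab-delimited abundance matrix."""

    def _write(rows, header=("t1", "t2", "t3"), name="abundance.tsv"):
        path = tmp_path / name
        lines = ["id\t" + "\t".join(header)]
        for fid, vals in rows:
            lines.append(fid + "\t" + "\t".join(str(v) for v in vals))
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return _write


def normalized_pair(n, rng):
    """A null pair of rank-normalized series of length n."""
    zx = rank_normal_transform(rng.standard_normal(n), "x")
    zy = rank_normal_transform(rng.standard_normal(n), "y")
    return zx, zy


@pytest.fixture
def null_pair(rng):
    return lambda n: normalized_pair(n, rng)
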