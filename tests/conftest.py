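import numpy as np
import pytest

import cnidapep as cp

NEURONAL = {"N1", "N2", "N3", "N4"}


def profiles_from_benchmark(bench):
    return [
        cp.ExpressionProfile(str(g), {c: float(v) for c, v in row.items()}, set(NEURONAL))
        for g, row in bench.expression.iterrows()
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """A 50-precursor / 90-decoy benchmark shared across tests."""
    return cp.make_benchmark(n_precursors=50, n_decoys=90, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
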