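import numpy as np
import pytest

import pcasite as p


@pytest.fixture(scope="session")
def tables():
    return p.load_property_tables()


@pytest.fixture(scope="session")
def schema10():
    return p.build_schema(10)


@pytest.fixture(scope="session")
def planted_matrix():
    """Small planted-signal matrix for ranking/classifier tests."""
    spec = p.SyntheticSpec(
        n_positive=60,
        neg_ratio=2,
        informative_columns=tuple(range(5)),
        effect_size=3.0,
        seed=11,
        n_features=30,
    )
    return p.generate_matrix(spec)


@pytest.fixture()
def fixture_dir(tmp_path):
    """On-disk synthetic fixture: FASTA, sites, PSSMs and tracks."""
    spec = p.SyntheticSpec(n_positive=12, neg_ratio=3, seed=7)
    return p.write_fixture_files(spec, tmp_path / "fx", protein_length=150)
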