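import numpy as np
import pytest

from venomont.synthetic import ReadSimSpec, gen_paralog_family, gen_reads


@pytest.fixture(scope="session")
def paralog_pair():
    """Two ~2%-diverged 1000-nt paralogs from a shared ancestor.

    The seed is chosen so that every 120-nt window contains at least one
    diagnostic site: windows without one make reads from the two paralogs
    intrinsically indistinguishable under the exact-overlap rule, and the
    assertion below documents that precondition.
    """
    fam = gen_paralog_family(1000, 2, 0.01, seed=19)
    a, b = fam[0][1], fam[1][1]
    div = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    edges = [-1] + div + [len(a)]
    assert max(e2 - e1 - 1 for e1, e2 in zip(edges, edges[1:])) < 120
    return fam


@pytest.fixture(scope="session")
def transcript_reads(paralog_pair):
    """Error-free 150-nt merged reads at 40x over the first paralog."""
    return gen_reads(
        ReadSimSpec(transcripts=[paralog_pair[0]], mean_depth=40, read_length=150, seed=12)
    )


@pytest.fixture(scope="session")
def both_paralog_reads(paralog_pair):
    return gen_reads(
        ReadSimSpec(transcripts=paralog_pair, mean_depth=40, read_length=150, seed=13)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
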