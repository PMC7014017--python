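import numpy as np
import pytest

from cypcensus.datasets import load_bgc_p450_report, load_comparative_counts
from cypcensus.synthetic_data import default_bundle, make_reference_db


@pytest.fixture(scope="session")
def bgc_report():
    """The packaged 27-row P450-in-BGC worked-example table."""
    return load_bgc_p450_report()


@pytest.fixture(scope="session")
def comparative_counts():
    return load_comparative_counts()


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic study (3 species, 4 families, 30 planted P450s)."""
    return default_bundle(seed=17)


@pytest.fixture(scope="session")
def small_refdb():
    """Small reference set: 3 families x 2 subfamily exemplars, 350 aa."""
    return make_reference_db(n_families=3, subfamilies_per_family=2, seed=5)


def gapless_variant(ref: str, n_subs: int, seed: int = 0) -> str:
    """Substitute exactly n_subs positions (outside the first/last 5 residues)
    so the optimal global alignment stays gapless and identity is exact."""
    rng = np.random.default_rng(seed)
    amino = "ACDEFGHIKLMNPQRSTVWY"
    positions = rng.choice(np.arange(5, len(ref) - 5), size=n_subs, replace=False)
    out = list(ref)
    for p in positions:
        out[p] = next(a for a in amino if a != ref[p])
    return "".join(out)
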