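import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def itgb1_run():
    """One full fixture screen: simulate, score, permutation scan (B=300).

    Session-scoped because several tests interrogate different facets of
    the same run (recovery, track properties, determinism of pieces).
    """
    import tilescan as ts

    fx = ts.make_itgb1_like_fixture(1)
    counts = ts.simulate_screen(fx.library, fx.truth, n_replicates=2)
    scores = ts.score_guides(counts, fx.library)
    track = ts.permutation_null(
        scores, fx.library, B=300, seed=1,
        protein_length=fx.truth.protein_length,
    )
    calls = ts.call_regions(track)
    return {
        "fixture": fx,
        "counts": counts,
        "scores": scores,
        "track": track,
        "calls": calls,
    }
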