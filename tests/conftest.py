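"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_optimal_threshold(saliency: np.ndarray, mask: np.ndarray):
    """Exhaustive search over all distinct saliency values.

    Independent of the package's sorted-sweep path: evaluates the Dice score of
    {s >= tau} for every distinct value tau and returns (tau, dsc) with ties in
    dsc broken toward the largest tau.
    """
    mask = mask.astype(bool)
    nb = int(mask.sum())
    best = None
    for tau in np.unique(saliency):
        a = saliency >= tau
        na = int(a.sum())
        d = 2.0 * int((a & mask).sum()) / (na + nb)
        if best is None or d > best[1] or (d == best[1] and tau > best[0]):
            best = (float(tau), d)
    return best


def random_instance(rng, shape=(16, 16), tie_prone=False):
    """Random saliency with a random nonempty mask; tie_prone quantizes values."""
    if tie_prone:
        s = rng.integers(0, 8, size=shape) / 7.0
    else:
        s = rng.random(shape)
    mask = np.zeros(shape, bool)
    k = int(rng.integers(1, shape[0] * shape[1] // 2))
    idx = rng.choice(shape[0] * shape[1], size=k, replace=False)
    mask.ravel()[idx] = True
    return s, mask


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic dataset with two contrasting systems."""
    import salovlap as sv

    root = tmp_path_factory.mktemp("ds") / "data"
    info = sv.make_dataset(
        root,
        {
            "localized": sv.SystemSpec(localization=1.0, effect_mu=0.25),
            "diffuse": sv.SystemSpec(localization=0.0, effect_mu=0.74),
        },
        n_cases=20,
        n_controls=20,
        n_missing_masks=2,
        seed=20150,
    )
    return info
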