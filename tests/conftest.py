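import numpy as np
import pytest

from elpgv.ensemble import DEGENERATE_FITNESS, BasePredictionSet


class FixedRng:
    """Stand-in RNG delivering scripted draws, for arithmetic-level tests."""

    def __init__(self, choices=None, uniforms=None):
        self._choices = list(choices or [])
        self._uniforms = list(uniforms or [])

    def choice(self, a, size=None, replace=True):
        out = self._choices.pop(0)
        return np.asarray(out)

    def uniform(self, low=0.0, high=1.0, size=None):
        out = self._uniforms.pop(0)
        if size is None:
            return out
        return np.asarray(out).reshape(size if np.ndim(size) == 0 else size)


def grid_search_best_fitness(predictions: BasePredictionSet, target, step=0.005):
    """Exhaustive-grid oracle for 2-method problems: best Pearson fitness over
    (w1, w2) in [0, 1]^2 at the given step."""
    assert predictions.n_methods == 2
    w = np.arange(0.0, 1.0 + step / 2, step)
    W = np.array(np.meshgrid(w, w)).reshape(2, -1).T     # G x 2
    preds = predictions.values @ W.T                      # n x G
    t = np.asarray(target, float)
    tc = t - t.mean()
    pc = preds - preds.mean(axis=0)
    denom = np.sqrt(tc @ tc) * np.sqrt(np.einsum("ij,ij->j", pc, pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc @ pc) / denom
    r[(denom == 0) | ~np.isfinite(r)] = DEGENERATE_FITNESS
    return float(r.max())


def toy_two_method_problem(seed, n=20):
    """Seeded 2-method toy: noisy views of a common signal plus a target."""
    rng = np.random.default_rng(seed)
    signal = rng.normal(size=n)
    p1 = signal + rng.normal(0, 0.5, n)
    p2 = -0.5 * signal + rng.normal(0, 0.8, n)
    target = signal + rng.normal(0, 0.4, n)
    preds = BasePredictionSet(
        np.array([f"i{i}" for i in range(n)]), ["m1", "m2"],
        np.column_stack([p1, p2]),
    )
    return preds, target


@pytest.fixture
def four_method_predictions():
    """Noisy views of one genetic signal from four synthetic methods."""
    rng = np.random.default_rng(42)
    n = 80
    g = rng.normal(size=n)
    values = np.column_stack([g + rng.normal(0, s, n) for s in (0.3, 0.5, 0.7, 1.0)])
    preds = BasePredictionSet(
        np.array([f"ind{i}" for i in range(n)]),
        ["BayesA", "BayesB", "BayesCpi", "GBLUP"],
        values,
    )
    return preds, g
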