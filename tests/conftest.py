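import numpy as np
import pytest

from agekin.curves import LabelingCurve


def exp_curve(lam: float, t_max: float, n: int, species: str = "exp") -> LabelingCurve:
    """Single-exponential wash-out curve e^{-lam t} on a uniform grid."""
    t = np.linspace(0.0, t_max, n)
    return LabelingCurve(species, t, np.exp(-lam * t))


def mixture_curve(weights, rates, t_max, n, species="mix") -> LabelingCurve:
    """Convex mixture of exponentials: f = sum w_i e^{-r_i t}."""
    t = np.linspace(0.0, t_max, n)
    w = np.asarray(weights, dtype=float)
    r = np.asarray(rates, dtype=float)
    v = (w[None, :] * np.exp(-np.outer(t, r))).sum(axis=1)
    return LabelingCurve(species, t, v)


@pytest.fixture
def dense_exp_min():
    """e^{-0.01 t} sampled every 10 min out to 2000 min (minutes scale)."""
    return exp_curve(0.01, 2000.0, 201)


@pytest.fixture
def delayed_curve_h():
    """2 e^{-t} - e^{-2t} (hours): serial 2-step chain output, flat initial slope."""
    t = np.linspace(0.0, 12.0, 601)
    return LabelingCurve("delayed", t, 2 * np.exp(-t) - np.exp(-2 * t))
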