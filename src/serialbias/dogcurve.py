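"""The derivative-of-Gaussian (DoG) serial-dependence curve.

``dog(x; alpha, w) = x * alpha * w * c * exp(-(w*x)^2)`` with
``c = sqrt(2) * exp(0.5)``, the unique constant for which ``alpha`` equals
the curve's peak (and valley) height, reached at ``x = +-1/(w*sqrt(2))``.
``x`` is the wrapped previous-minus-present difference in degrees, ``alpha``
the bias amplitude in degrees, and ``w`` the inverse width in 1/degrees.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

DOG_NORM_C = np.sqrt(2.0) * np.exp(0.5)


def dog(x, alpha, w):
    x = np.asarray(x, dtype=float)
    return x * alpha * w * DOG_NORM_C * np.exp(-((w * x) ** 2))


def dog_basis(x, w):
    """The curve at unit amplitude; the model is linear in alpha given w."""
    x = np.asarray(x, dtype=float)
    return x * w * DOG_NORM_C * np.exp(-((w * x) ** 2))


def dog_peak_location(w):
    """Predictor value at which the curve peaks: 1/(w*sqrt(2))."""
    return 1.0 / (w * np.sqrt(2.0))


def fit_dog_curve(x, y, w_bounds=(0.008, 0.15)):
    """Single-level least-squares DoG fit (pooled data, no random effects).

    Profiles the amplitude (closed form, the model is linear in alpha) over
    a bounded 1-D search on w.  Returns ``(alpha, w)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite observations")

    def alpha_hat(w):
        f = dog_basis(x, w)
        denom = f @ f
        return (f @ y) / denom if denom > 0 else 0.0

    def sse(w):
        return float(np.sum((y - dog(x, alpha_hat(w), w)) ** 2))

    res = minimize_scalar(sse, bounds=w_bounds, method="bounded",
                          options={"xatol": 1e-6})
    w = float(res.x)
    return float(alpha_hat(w)), w
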