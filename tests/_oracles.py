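"""Independent reference implementations used to cross-check the package.

These deliberately take the slow, exhaustive route (per-candidate
np.corrcoef loops, coarse grid search + local polish) so that agreement
with the package's vectorized / Levenberg-Marquardt implementations is
a meaningful check rather than a tautology.
"""

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize

from stretchplate.dose_response import logistic_eval


def mct_oracle(image, mask, sigma=1.0, bins=256):
    """Exhaustive maximum-correlation threshold search."""
    img = np.asarray(image, dtype=float)
    smooth = ndi.gaussian_filter(img, sigma) if sigma > 0 else img
    values = smooth[mask]
    lo, hi = values.min(), values.max()
    idx = np.minimum(((values - lo) / (hi - lo) * bins).astype(int), bins - 1)
    best_c, best_corr = None, -np.inf
    for c in np.unique(idx):
        fg = idx > c
        if not fg.any() or fg.all():
            continue
        corr = np.corrcoef(values, fg.astype(float))[0, 1]
        if corr > best_corr:
            best_c, best_corr = c, corr
    out = np.zeros(image.shape, dtype=bool)
    out[mask] = idx > best_c
    return out


def grid_polish_sse(strain, value):
    """Best achievable sum of squared residuals for the four-parameter
    logistic, found by a coarse (k, E_t) grid with linear solves for the
    asymptotes, followed by a Nelder-Mead polish."""
    strain = np.asarray(strain, float)
    value = np.asarray(value, float)

    def sse(theta):
        return float(np.sum((value - logistic_eval(theta, strain)) ** 2))

    best = None
    for k in np.linspace(2, 40, 39):
        for et in np.linspace(0.05, 0.55, 51):
            w = 1.0 / (1.0 + np.exp(np.clip(k * (strain - et), -700, 700)))
            A = np.column_stack([w, 1.0 - w])
            coef, *_ = np.linalg.lstsq(A, value, rcond=None)
            theta = (coef[0], coef[1], k, et)
            if best is None or sse(theta) < sse(best):
                best = theta
    polished = minimize(
        sse,
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    return polished.fun
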