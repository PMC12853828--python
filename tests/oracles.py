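"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: controlled rounding
is checked by exhaustive enumeration over all feasible integer vectors, and
the weighted logistic fit by direct numerical maximisation of the weighted
log-likelihood.
"""

import itertools
import math

import numpy as np
from scipy import optimize


def brute_force_controlled_round(values, total):
    """Enumerate every integer vector within the floor/ceil bounds summing to
    ``total``; pick the one bumping the set of entries with the largest
    fractional parts (ties resolved towards lower indices by lexicographic
    enumeration order)."""
    values = [float(v) for v in values]
    floors = [math.floor(v + 1e-9) for v in values]
    fracs = [round(v - f, 9) for v, f in zip(values, floors)]
    bumpable = [i for i, f in enumerate(fracs) if f > 1e-9]
    rem = total - sum(floors)
    if rem < 0 or rem > len(bumpable):
        raise ValueError("infeasible")
    best, best_score = None, -1.0
    for subset in itertools.combinations(bumpable, rem):
        score = sum(fracs[i] for i in subset)
        if score > best_score + 1e-12:
            best_score, best = score, subset
    out = list(floors)
    for i in best:
        out[i] += 1
    return out


def direct_weighted_logit(X, y, w):
    """Maximise the weighted Bernoulli log-likelihood directly (BFGS with an
    analytic gradient); returns the coefficient vector."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)

    def negll(beta):
        eta = X @ beta
        # log(1 + e^eta) computed stably
        return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return -(X.T @ (w * (y - p)))

    res = optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad,
                            method="BFGS", options={"gtol": 1e-12, "maxiter": 500})
    return res.x
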