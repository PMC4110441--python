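"""Independent reference implementations used as test oracles.

These deliberately take the slow, obviously-correct route (full stacked
covariance matrices, closed-form textbook estimators) and share no code
with the package's structured likelihood.
"""

import numpy as np
from scipy.stats import multivariate_normal


def dense_loglik(data, moments):
    """Joint normal log-density via the full stacked covariance per school.

    Each school's observation vector has covariance
    kron(ones, Sigma_3) + kron(same_class, Sigma_2) + kron(I, Sigma_1).
    """
    p = data.p
    L = len(moments.sigma_by_level)
    S1 = np.asarray(moments.sigma_by_level[0])
    S2 = np.asarray(moments.sigma_by_level[1]) if L >= 2 else np.zeros((p, p))
    S3 = np.asarray(moments.sigma_by_level[2]) if L == 3 else np.zeros((p, p))
    if L == 3 and data.school_id is not None:
        groups = data.school_id
    else:
        # independent blocks are classes (or, for L == 1, single rows)
        groups = data.class_id if L >= 2 else np.arange(data.n)
    ll = 0.0
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        cls = data.class_id[rows]
        n = len(rows)
        same_class = (cls[:, None] == cls[None, :]).astype(float)
        cov = (
            np.kron(np.ones((n, n)), S3)
            + np.kron(same_class, np.ones((p, p))) * np.tile(S2, (n, n))
            + np.kron(np.eye(n), S1)
        )
        y = data.indicators[rows].ravel()
        ll += multivariate_normal.logpdf(y, np.tile(moments.mu, n), cov)
    return float(ll)


def anova_ml_variance_components(y, group):
    """Closed-form ML estimators for the balanced one-way random-effects model.

    y_ij = mu + b_j + e_ij with b ~ N(0, sb2), e ~ N(0, se2), C groups of
    equal size n.  ML (not REML): mu_hat = grand mean,
    se2_hat = SSW / (N - C), lambda2_hat = n * sum((ybar_j - ybar)^2) / C,
    sb2_hat = (lambda2_hat - se2_hat) / n (truncated at 0).
    """
    y = np.asarray(y, dtype=float)
    groups, codes = np.unique(group, return_inverse=True)
    C = len(groups)
    counts = np.bincount(codes).astype(float)
    assert np.all(counts == counts[0]), "oracle requires a balanced design"
    n = counts[0]
    N = len(y)
    gbar = np.zeros(C)
    np.add.at(gbar, codes, y)
    gbar /= n
    mu = y.mean()
    ssw = float(np.sum((y - gbar[codes]) ** 2))
    se2 = ssw / (N - C)
    lam2 = float(n * np.sum((gbar - mu) ** 2) / C)
    sb2 = max((lam2 - se2) / n, 0.0)
    return mu, se2, sb2
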