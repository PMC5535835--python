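"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths of the package: SIMPLS instead of
NIPALS, explicit loops instead of vectorised updates, closed-form textbook
formulas instead of library calls.
"""

import numpy as np


def simpls1_predictor(X, y, n_components):
    """de Jong's SIMPLS for a single response; returns a prediction function."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    p = X.shape[1]
    s = Xc.T @ yc
    R = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    V = np.zeros((p, n_components))
    for a in range(n_components):
        r = s.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t)
        t /= t_norm
        r /= t_norm
        pa = Xc.T @ t
        Q[a] = float(yc @ t)
        v = pa.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pa)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
    b = R @ Q
    return lambda Xn: (np.asarray(Xn, dtype=float) - x_mean) @ b + y_mean


def centered_ols_fitted(X, y):
    """Least-squares fitted values of the mean-centered regression."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
    return Xc @ beta + y.mean()


def ols_line(x, y):
    """Closed-form simple-regression slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    return slope, y.mean() - slope * x.mean()


def rmse_r2(y_true, y_pred, ref_mean=None):
    """Textbook RMSE (divisor n) and determination coefficient."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = float(np.sqrt(np.sum((y_true - y_pred) ** 2) / len(y_true)))
    ref = y_true.mean() if ref_mean is None else ref_mean
    det = 1.0 - np.sum((y_true - y_pred) ** 2) / np.sum((y_true - ref) ** 2)
    return err, float(det)


def kennard_stone_steps(X, n_pick):
    """Step-by-step max-min selection with explicit loops (exhaustive checks)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best[0]:
                best = (d[i, j], (i, j))
    picked = list(best[1])
    while len(picked) < n_pick:
        cand_best = (-1.0, None)
        for c in range(n):
            if c in picked:
                continue
            m = min(d[c, q] for q in picked)
            if m > cand_best[0]:
                cand_best = (m, c)
        picked.append(cand_best[1])
    return picked


def manual_kfold_rmsecv(X, y, labels, n_components, fit, predict):
    """Pooled RMSECV by refitting per fold with caller-supplied fit/predict."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sq = 0.0
    for fold in np.unique(labels):
        test = labels == fold
        model = fit(X[~test], y[~test], n_components)
        sq += float(np.sum((y[test] - predict(model, X[test])) ** 2))
    return float(np.sqrt(sq / len(y)))
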