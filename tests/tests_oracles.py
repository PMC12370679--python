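"""Independent numerical oracles shared by the test suite.

These deliberately avoid the package's linear algebra: plain loops and
dense Gauss-Hermite rules, usable only at tiny problem sizes.
"""

import numpy as np


def gh_amplitude_loglik(df, a, b, c, d, s2, n_nodes=80):
    """Marginal log-likelihood of a one-random-amplitude curve model by
    adaptive Gauss-Hermite quadrature, one group at a time."""
    zs, ws = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for _, sub in df.groupby("branch_id"):
        x = sub["SDINC"].to_numpy()
        y = sub["SBL"].to_numpy()
        g = x**b * np.exp(-c * x)
        prec = g @ g / s2 + 1.0 / d
        mode = (g @ (y - a * g) / s2) / prec
        sd = 1.0 / np.sqrt(prec)
        u = mode + np.sqrt(2.0) * sd * zs
        resid = y[None, :] - (a + u[:, None]) * g[None, :]
        logf = (-0.5 * np.sum(resid**2, axis=1) / s2
                - 0.5 * len(y) * np.log(2 * np.pi * s2)
                - 0.5 * u**2 / d - 0.5 * np.log(2 * np.pi * d))
        vals = np.log(ws) + zs**2 + logf
        m = vals.max()
        total += m + np.log(np.sum(np.exp(vals - m))) \
            + 0.5 * np.log(2.0) + np.log(sd)
    return total
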