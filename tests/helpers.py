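"""Shared numerical utilities for the test suite."""

import numpy as np


def observed_info_se(negloglik, theta_hat, rel_step=1e-4):
    """Standard errors from the observed information: central finite
    differences of the negative log-likelihood Hessian at the optimum."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    p = len(theta_hat)
    h = rel_step * (1.0 + np.abs(theta_hat))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            tpp = theta_hat.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta_hat.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta_hat.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta_hat.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                negloglik(tpp) - negloglik(tpm) - negloglik(tmp) + negloglik(tmm)
            ) / (4.0 * h[i] * h[j])
    cov = np.linalg.inv(H)
    return np.sqrt(np.diag(cov))
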