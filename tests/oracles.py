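"""Independent brute-force oracles used to cross-check the fitted models."""

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients straight from the normal equations."""
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


def press_leave_one_out(X: np.ndarray, y: np.ndarray) -> float:
    """PRESS by explicitly refitting with each observation deleted."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        beta = ols_normal_equations(X[keep], y[keep])
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    return press
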