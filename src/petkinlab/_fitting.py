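"""Shared helpers for the nonlinear least-squares fits."""

from __future__ import annotations

import numpy as np


def rsquared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    A perfectly reproduced constant series (SS_tot == 0, SS_res == 0) is
    reported as 1.0; an imperfect fit of a constant series as 0.0.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def covariance_from_jacobian(jac: np.ndarray, residuals: np.ndarray,
                             n_params: int) -> np.ndarray:
    """Parameter covariance at the optimum from the Jacobian.

    Uses the standard Gauss-Newton approximation cov = (J^T J)^-1 * s^2 with
    s^2 the residual variance on n - p degrees of freedom.  Singular J^T J
    (flat directions) yields inf on the affected diagonal entries.
    """
    n = residuals.size
    dof = max(n - n_params, 1)
    s2 = float(np.sum(residuals ** 2)) / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.full((n_params, n_params), np.inf)
    return cov


def format_summary(title: str, rows: list[tuple[str, str]],
                   param_rows: list[tuple[str, float, float]] | None = None) -> str:
    """Plain-text summary table in the style of statsmodels results."""
    width = 62
    lines = [title.center(width), "=" * width]
    for key, val in rows:
        lines.append(f"{key:<30}{val:>32}")
    if param_rows:
        lines.append("-" * width)
        lines.append(f"{'parameter':<18}{'estimate':>16}{'std err':>16}")
        lines.append("-" * width)
        for name, est, se in param_rows:
            se_str = f"{se:.4g}" if np.isfinite(se) else "nan"
            lines.append(f"{name:<18}{est:>16.6g}{se_str:>16}")
    lines.append("=" * width)
    return "\n".join(lines)
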