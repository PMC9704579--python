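"""Delayed transfer-function fitting over a structure and delay grid.

For every candidate structure (2-4 poles, 1-4 zeros, with strictly proper
or biproper forms allowed), both delay structures (pure delay e^{-s tau} and
its first-order linear approximation), and every delay on a 1 ms grid over
[0, 200] ms, the delay factor is divided out of the measured response and
the rational coefficients are fitted by complex linear least squares in
equation-error form, with one Sanathanan-Koerner reweighting pass to de-bias
the denominator weighting.  Candidates are scored by the summed absolute
response mismatch (the grid-search objective), a normalized fit percentage,
time-domain MSE from simulating the candidate on the stimulus record, and an
ARX-based final prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._dsp import filter_continuous, fractional_delay
from .models import DELAY_LINEAR, DELAY_PURE, FitReport, TransferFunctionModel
from .spectra import FrequencyResponse

__all__ = [
    "fit_transfer_function",
    "select_best_model",
    "default_structures",
    "default_delay_grid",
    "arx_fpe",
    "ModelSelection",
]


def default_structures() -> list[tuple[int, int]]:
    """(pole, zero) grid: 2-4 poles, 1-4 zeros, zeros <= poles."""
    return [(p, z) for p in (2, 3, 4) for z in (1, 2, 3, 4) if z <= p]


def default_delay_grid(step_ms: float = 1.0, max_ms: float = 200.0) -> np.ndarray:
    """Delay grid in seconds: 1 ms steps over [0, 200] ms by default."""
    return np.arange(0.0, max_ms + step_ms / 2, step_ms) * 1e-3


def _inverse_delay_factor(
    H: np.ndarray, omega: np.ndarray, tau: float, structure: str
) -> np.ndarray:
    """Divide the delay factor out of the measured response."""
    if structure == DELAY_PURE:
        return H * np.exp(1j * omega * tau)
    return H * (1.0 + 1j * omega * tau)


def _rational_lsq(
    omega: np.ndarray,
    target: np.ndarray,
    n_poles: int,
    n_zeros: int,
    n_sk_iter: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Equation-error complex LS fit of target ~ N(s)/D(s), D monic.

    Returns (num, den, coefficient standard errors) or None when the normal
    equations are singular/ill-conditioned.
    """
    s = 1j * omega
    m = len(omega)
    pow_num = np.column_stack([s**k for k in range(n_zeros + 1)])
    pow_den = np.column_stack([s**k for k in range(n_poles)])
    weights = np.ones(m)

    theta = None
    for _ in range(max(1, n_sk_iter + 1)):
        A = np.hstack([pow_num, -target[:, None] * pow_den]) * weights[:, None]
        rhs = (target * s**n_poles) * weights
        Ar = np.vstack([A.real, A.imag])
        br = np.concatenate([rhs.real, rhs.imag])
        # rank-deficient systems (e.g. a degenerate candidate on degenerate
        # data) take the minimum-norm solution; it is only rejected below if
        # it yields an unusable model
        theta, _, _, _ = np.linalg.lstsq(Ar, br, rcond=None)
        if not np.all(np.isfinite(theta)):
            return None
        den = np.concatenate([theta[n_zeros + 1 :], [1.0]])
        dvals = np.polynomial.polynomial.polyval(s, den)
        if np.any(np.abs(dvals) < 1e-12):
            return None
        weights = 1.0 / np.abs(dvals)

    num = theta[: n_zeros + 1]
    den = np.concatenate([theta[n_zeros + 1 :], [1.0]])

    # one-sigma standard errors from the final weighted normal equations
    resid = Ar @ theta - br
    dof = max(1, len(br) - len(theta))
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(Ar.T @ Ar)
    stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return num, den, stderr


def _freq_fit_pct(y: np.ndarray, ym: np.ndarray) -> float:
    """Normalized fit percentage 100*(1 - ||y-ym|| / ||y-mean(y)||).

    A constant response has zero variance; the residual is then normalized
    by ||y|| instead so that only a genuinely exact model scores 100.
    """
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        denom = np.linalg.norm(y)
        if denom == 0:
            return 100.0 if np.allclose(y, ym) else -np.inf
    return 100.0 * (1.0 - np.linalg.norm(y - ym) / denom)


def simulate_model_output(
    model: TransferFunctionModel, stimulus: np.ndarray, dt: float
) -> np.ndarray:
    """Time-domain response of a candidate model to the stimulus record."""
    if model.delay_structure == DELAY_LINEAR:
        den = np.polynomial.polynomial.polymul(model.den, [1.0, model.delay])
        return filter_continuous(model.num, den, dt, stimulus)
    y = filter_continuous(model.num, model.den, dt, stimulus)
    if model.delay > 0:
        y = fractional_delay(y, model.delay / dt)
    return y


def arx_fpe(
    y: np.ndarray, u: np.ndarray, n_a: int, n_b: int
) -> float:
    """Final prediction error of an ARX(n_a, n_b) surrogate fitted by LS.

    y(t) + a_1 y(t-1) + ... = b_1 u(t-1) + ... + e(t); the FPE multiplies
    the residual variance by (1 + d/L)/(1 - d/L) with d = n_a + n_b
    estimated parameters over L regression rows.
    """
    y = np.asarray(y, dtype=float)
    u = np.asarray(u, dtype=float)
    lag = max(n_a, n_b)
    L = len(y) - lag
    d = n_a + n_b
    if L <= d:
        return np.nan
    cols = [-y[lag - k : lag - k + L] for k in range(1, n_a + 1)]
    cols += [u[lag - k : lag - k + L] for k in range(1, n_b + 1)]
    phi = np.column_stack(cols)
    target = y[lag : lag + L]
    theta, *_ = np.linalg.lstsq(phi, target, rcond=None)
    e = target - phi @ theta
    return float(np.mean(e**2) * (1.0 + d / L) / (1.0 - d / L))


def fit_transfer_function(
    H: FrequencyResponse,
    band: tuple[float, float] | None = None,
    structures: list[tuple[int, int]] | None = None,
    delay_grid: np.ndarray | None = None,
    delay_structures: tuple[str, ...] = (DELAY_PURE, DELAY_LINEAR),
    time_data: tuple[np.ndarray, np.ndarray, float] | None = None,
    min_points: int = 8,
) -> list[tuple[TransferFunctionModel, FitReport]]:
    """Grid-search delayed transfer-function models against a measured response.

    Parameters
    ----------
    H : FrequencyResponse
        Measured response samples (typically the stimulus/animal spectral
        ratio at excited frequencies).
    band : (f_lo, f_hi), optional
        Restrict the fit to this frequency interval.
    structures, delay_grid, delay_structures
        Candidate (pole, zero) pairs, delay values in seconds, and delay
        model forms; defaults cover 2-4 poles, 1-4 zeros, 1 ms steps over
        [0, 200] ms, and both delay forms.
    time_data : (stimulus, animal, dt), optional
        Concatenated tracking records; enables time-domain FIT/MSE and the
        ARX-based FPE in each report.

    Returns one (model, report) per structure/delay-form combination, each
    at its best grid delay.
    """
    structures = default_structures() if structures is None else structures
    delay_grid = default_delay_grid() if delay_grid is None else np.asarray(delay_grid)

    freqs = H.freqs
    values = H.values
    if band is not None:
        f_lo, f_hi = band
        keep = (freqs >= f_lo) & (freqs <= f_hi)
        freqs, values = freqs[keep], values[keep]
    if len(freqs) < min_points:
        raise ValueError(
            f"only {len(freqs)} response points in the fit band; need >= {min_points}"
        )
    omega = 2.0 * np.pi * freqs

    results: list[tuple[TransferFunctionModel, FitReport]] = []
    # a later grid delay must improve the objective by more than numerical
    # noise to displace an earlier (smaller) delay
    improve_tol = 1e-9 * float(np.sum(np.abs(values)))
    for n_poles, n_zeros in structures:
        for dstruct in delay_structures:
            best = None
            for tau in delay_grid:
                target = _inverse_delay_factor(values, omega, tau, dstruct)
                sol = _rational_lsq(omega, target, n_poles, n_zeros)
                if sol is None:
                    continue
                num, den, stderr = sol
                # poles far outside the analysis band are unidentifiable:
                # the candidate is then a degenerate (lower-order) model in
                # disguise and is skipped
                poles = np.roots(den[::-1])
                if len(poles) and np.abs(poles).max() > 10.0 * omega.max():
                    continue
                model = TransferFunctionModel(
                    num=num,
                    den=den,
                    delay=float(tau),
                    delay_structure=dstruct,
                    uncertainties=stderr,
                )
                resid = model.freq_response(freqs) - values
                objective = float(np.sum(np.abs(resid)))
                if best is None or objective < best[1] - improve_tol:
                    best = (model, objective)
            if best is None:
                continue  # singular for every delay; candidate skipped
            model, objective = best
            ym = model.freq_response(freqs)
            report = FitReport(
                fit_pct=_freq_fit_pct(values, ym), objective=objective
            )
            if time_data is not None:
                d1, d2, dt = time_data
                with np.errstate(over="ignore", invalid="ignore"):
                    sim = simulate_model_output(model, d1, dt)
                    if np.all(np.isfinite(sim)):
                        report.mse = float(np.mean((d2 - sim) ** 2))
                        denom = np.linalg.norm(d2 - d2.mean())
                        if denom > 0:
                            report.fit_time_pct = 100.0 * (
                                1.0 - np.linalg.norm(d2 - sim) / denom
                            )
                    else:  # discretized candidate is unstable
                        report.mse = np.inf
                        report.fit_time_pct = -np.inf
                report.fpe = arx_fpe(d2, d1, n_a=n_poles, n_b=n_zeros + 1)
            results.append((model, report))
    return results


@dataclass
class ModelSelection:
    """Outcome of model selection across the candidate grid."""

    model: TransferFunctionModel
    report: FitReport
    criteria_disagree: bool


def select_best_model(
    candidates: list[tuple[TransferFunctionModel, FitReport]],
    tie_tol_pct: float = 0.5,
) -> ModelSelection:
    """Pick the best candidate by maximum fit percentage.

    Candidates whose fit lies within ``tie_tol_pct`` of the best are treated
    as tied, and the tie is broken by fewer parameters, then smaller delay —
    parsimony first.  The selection also flags whether the three criteria
    (max FIT, min MSE, min FPE) would disagree on the winner.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    best_fit = max(r.fit_pct for _, r in candidates)
    tied = [
        (m, r) for m, r in candidates if r.fit_pct >= best_fit - tie_tol_pct
    ]
    # a numerically perfect fit beats approximate ones regardless of size;
    # within that, parsimony, then fit, then the smaller delay
    model, report = min(
        tied,
        key=lambda mr: (
            mr[1].fit_pct < 100.0 - 1e-6,
            mr[0].n_parameters,
            -mr[1].fit_pct,
            mr[0].delay,
        ),
    )

    def _argbest(key, reverse=False):
        vals = [key(r) for _, r in candidates]
        vals = [v if np.isfinite(v) else (-np.inf if reverse else np.inf) for v in vals]
        return int(np.argmax(vals) if reverse else np.argmin(vals))

    i_fit = _argbest(lambda r: r.fit_pct, reverse=True)
    disagree = False
    if all(np.isfinite(r.mse) for _, r in candidates):
        disagree |= _argbest(lambda r: r.mse) != i_fit
    if all(np.isfinite(r.fpe) for _, r in candidates):
        disagree |= _argbest(lambda r: r.fpe) != i_fit
    return ModelSelection(model=model, report=report, criteria_disagree=disagree)
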