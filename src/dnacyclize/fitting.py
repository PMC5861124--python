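"""Periodic profile fitting, knob regressions, degenerate families, calibration.

A cyclization profile -- log10 J versus basepair count N -- oscillates with
the helical repeat on top of a slow drift.  It is summarized by five numbers
through the piecewise-quadratic periodic form

    y(N) = a + b (N - phi) + c [f(N, phi, p)]^2,
    f(N, phi, p) = mod(N - phi + p/2, p) - p/2,

where ``phi`` is the location of the first peak after N = 145, ``p`` the
oscillation period (close to the helical repeat), ``a`` the peak height in
log10 nM, ``b`` the per-bp drift and ``c`` (negative) the curvature that
sets the peak-to-trough difference ``-c (p/2)^2``.

Sweeping one model knob at a time and regressing the fitted parameters
against the knob yields simple response relations (the module constants
below).  Combining them exposes degeneracies -- one-parameter families of
molecules with very different mechanics but nearly identical profiles --
and, run backwards, calibrates any profile down to the two intuitive
stiffness parameters ``beta`` and ``K3/K1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .elastic import MoleculeSpec, StiffnessSet

__all__ = [
    "f_periodic",
    "FitParams",
    "PeriodicProfileModel",
    "PeriodicProfileResults",
    "fit_profile",
    "KnobRegression",
    "knob_regression",
    "degenerate_family",
    "CalibrationResult",
    "calibrate_simple_model",
    "A_PER_BEND_DEG",
    "A_PER_BETA",
    "A_BASELINE_COMBINED",
    "PHI_PER_REPEAT",
    "PHI_PER_PITCH_RATIO",
    "A_PER_ABS_PITCH_RATIO",
    "C_PER_K3_RATIO",
    "C_AT_REFERENCE",
    "A_PER_K3_RATIO",
    "BEND_PER_BETA",
    "PITCH_RATIO_PER_REPEAT",
    "BEND_PER_ABS_PITCH_RATIO",
]

# --- knob-response relations, anchored at the reference molecule -----------
# (90-degree planar bend over 63 bp, helical repeat 10.5, K3/K1 = 1.5,
# beta = 1).  Slopes come from ordinary least squares on the reference
# tables in :mod:`dnacyclize.reference`, quoted at the precision at which
# they are used downstream.

#: d(a)/d(bend angle), per degree, valid for bends of 60-120 degrees.
A_PER_BEND_DEG = 0.021
#: d(a)/d(beta) for the overall stiffness scale (persistence 40.3-52.3 nm).
A_PER_BETA = -4.45
#: Combined-baseline peak height at (bend 90, beta 1).
A_BASELINE_COMBINED = 1.325
#: d(phi)/d(helical repeat), bp per bp-per-turn.
PHI_PER_REPEAT = 14.3
#: d(phi)/d(pitch/circumference), handedness-averaged.
PHI_PER_PITCH_RATIO = 2.45
#: d(a)/d|pitch/circumference|, handedness-averaged.
A_PER_ABS_PITCH_RATIO = -0.3
#: d(c)/d(K3/K1) and the reference value of c at K3/K1 = 1.5.
C_PER_K3_RATIO = -0.077
C_AT_REFERENCE = -0.114
#: d(a)/d(K3/K1).
A_PER_K3_RATIO = 0.30

# tradeoff coefficients of the degenerate families
#: Bend angle (degrees) compensating a unit change of beta.
BEND_PER_BETA = 212.0
#: Pitch/circumference compensating a unit change of helical repeat.
PITCH_RATIO_PER_REPEAT = -5.84
#: Bend angle (degrees) compensating a unit of |pitch/circumference|.
BEND_PER_ABS_PITCH_RATIO = 14.3

#: Window anchor: phi is reported as the first peak after this length.
PHASE_ANCHOR = 145.0


def f_periodic(N, phi, p):
    """Sawtooth phase coordinate: mod(N - phi + p/2, p) - p/2 in [-p/2, p/2).

    Zero exactly at N = phi + k p, so the quadratic term vanishes at peaks.
    """
    if np.any(np.asarray(p) <= 0):
        raise ValueError("period p must be positive")
    return np.mod(np.asarray(N, dtype=float) - phi + p / 2.0, p) - p / 2.0


class FitParams(NamedTuple):
    """The five profile parameters plus the residual sum of squares."""

    phi: float
    p: float
    a: float
    b: float
    c: float
    rss: float = float("nan")


def _design(N, phi, p):
    f = f_periodic(N, phi, p)
    return np.stack([np.ones_like(N, dtype=float), N - phi, f * f], axis=-1)


def _solve_linear(N, y, w, phi, p):
    X = _design(N, phi, p)
    Xw = X * w[:, None]
    G = X.T @ Xw
    h = Xw.T @ y
    try:
        beta = np.linalg.solve(G, h)
    except np.linalg.LinAlgError:
        return None, np.inf
    r = y - X @ beta
    return beta, float(np.sum(w * r * r))


class PeriodicProfileModel:
    """Least-squares model of a cyclization profile.

    Parameters
    ----------
    N, y : array-like
        Basepair counts and log10 J values (at least 10 points spanning at
        least 1.5 periods).
    weights : array-like, optional
        Relative weights; pass ``1/stderr**2`` to weight by counting error.
        Default is unweighted.
    """

    def __init__(self, N, y, weights=None):
        self.N = np.asarray(N, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.N.ndim != 1 or self.N.shape != self.y.shape:
            raise ValueError("N and y must be matching 1-d arrays")
        if not (np.all(np.isfinite(self.N)) and np.all(np.isfinite(self.y))):
            raise ValueError("N and y must be finite (drop censored points)")
        self.weights = (
            np.ones_like(self.y)
            if weights is None
            else np.asarray(weights, dtype=float)
        )
        if self.weights.shape != self.y.shape or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per point")
        if self.N.size < 10:
            raise ValueError("need at least 10 profile points")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, weight_by_stderr: bool = False):
        df = df[np.isfinite(df["log10J"])]
        w = None
        if weight_by_stderr and "stderr" in df:
            w = 1.0 / df["stderr"].to_numpy() ** 2
        return cls(df["N"].to_numpy(), df["log10J"].to_numpy(), w)

    def fit(
        self,
        p_bounds: tuple[float, float] = (9.5, 11.5),
        p_step: float = 0.01,
        phi_step: float = 0.02,
        anchor: float = PHASE_ANCHOR,
        polish: bool = True,
    ) -> "PeriodicProfileResults":
        """Dense (phi, p) grid search with exact linear subproblem, then polish.

        For fixed (phi, p) the model is linear in (a, b, c) and solved in
        closed form; the outer search is an exhaustive grid (the objective
        is only piecewise smooth in phi and p, so gradient methods are
        unreliable), refined by a derivative-free local polish.
        """
        N, y, w = self.N, self.y, self.weights
        span = N.max() - N.min()
        if span < 1.5 * p_bounds[0]:
            raise ValueError("profile must span at least 1.5 periods")
        best = (np.inf, None)
        for p in np.arange(p_bounds[0], p_bounds[1] + p_step / 2, p_step):
            phis = anchor + np.arange(phi_step, p + phi_step / 2, phi_step)
            F = f_periodic(N[None, :], phis[:, None], p)
            X = np.stack(
                [np.broadcast_to(np.ones_like(N), F.shape), N[None, :] - phis[:, None], F * F],
                axis=-1,
            )
            Xw = X * w[None, :, None]
            G = np.einsum("knj,knl->kjl", X, Xw)
            h = np.einsum("knj,n->kj", Xw, y)
            ok = np.abs(np.linalg.det(G)) > 1e-12
            if not np.any(ok):
                continue
            beta = np.linalg.solve(G[ok], h[ok][..., None])[..., 0]
            r = y[None, :] - np.einsum("knj,kj->kn", X[ok], beta)
            rss = np.einsum("kn,n,kn->k", r, w, r)
            k = int(np.argmin(rss))
            if rss[k] < best[0]:
                best = (float(rss[k]), (float(phis[ok][k]), float(p)))
        if best[1] is None:
            raise ValueError("degenerate design: all lengths at the same phase")
        phi0, p0 = best[1]
        if polish:
            res = minimize(
                lambda v: _solve_linear(N, y, w, v[0], v[1])[1]
                if p_bounds[0] <= v[1] <= p_bounds[1]
                else np.inf,
                x0=[phi0, p0],
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 2000},
            )
            if res.fun <= best[0]:
                phi0, p0 = float(res.x[0]), float(res.x[1])
        # report phi as the first peak after the anchor: phi in (anchor, anchor+p]
        r = math.fmod(phi0 - anchor, p0)
        if r < 0:
            r += p0
        phi0 = anchor + (r if r > 0 else p0)
        beta, rss = _solve_linear(N, y, w, phi0, p0)
        if beta is None:
            raise ValueError("degenerate design: all lengths at the same phase")
        return PeriodicProfileResults(self, phi0, p0, beta, rss)


class PeriodicProfileResults:
    """Fit results; exposes parameters, diagnostics and a summary table."""

    def __init__(self, model, phi, p, linear, rss):
        self.model = model
        self.phi = float(phi)
        self.p = float(p)
        self.a, self.b, self.c = (float(v) for v in linear)
        self.rss = float(rss)
        self.nobs = model.N.size
        self.df_resid = self.nobs - 5

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            [self.phi, self.p, self.a, self.b, self.c],
            index=["phi", "p", "a", "b", "c"],
        )

    @property
    def fitparams(self) -> FitParams:
        return FitParams(self.phi, self.p, self.a, self.b, self.c, self.rss)

    def predict(self, N) -> np.ndarray:
        N = np.asarray(N, dtype=float)
        return self.a + self.b * (N - self.phi) + self.c * f_periodic(
            N, self.phi, self.p
        ) ** 2

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.N)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def peak_to_trough(self) -> float:
        """Oscillation amplitude of the fitted curve, -c (p/2)^2."""
        return -self.c * (self.p / 2.0) ** 2

    @property
    def bse(self) -> pd.Series:
        """Approximate standard errors from the local Jacobian."""
        theta = self.params.to_numpy()

        def f(v):
            return v[2] + v[3] * (self.model.N - v[0]) + v[4] * f_periodic(
                self.model.N, v[0], v[1]
            ) ** 2

        J = np.empty((self.nobs, 5))
        h = 1e-6
        for j in range(5):
            dv = np.zeros(5)
            dv[j] = h
            J[:, j] = (f(theta + dv) - f(theta - dv)) / (2 * h)
        sigma2 = self.rss / max(self.df_resid, 1)
        try:
            cov = sigma2 * np.linalg.inv(J.T @ (J * self.model.weights[:, None]))
        except np.linalg.LinAlgError:
            return pd.Series(np.nan, index=self.params.index)
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def summary(self) -> str:
        lines = [
            "Periodic cyclization-profile fit",
            "=" * 48,
            f"nobs: {self.nobs}    rss: {self.rss:.6g}    "
            f"peak-to-trough: {self.peak_to_trough:.3f}",
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        bse = self.bse
        for name, val in self.params.items():
            lines.append(f"{name:>6} {val:12.4f} {bse[name]:12.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve on a dense length grid (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.N, self.model.y, "o", label="profile")
        grid = np.linspace(self.model.N.min(), self.model.N.max(), 400)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("N (bp)")
        ax.set_ylabel("log10 J (nM)")
        ax.legend()
        return ax


def fit_profile(N, y=None, weights=None, **fit_kwargs) -> PeriodicProfileResults:
    """Fit a profile given arrays (N, y) or a DataFrame with N / log10J."""
    if y is None:
        return PeriodicProfileModel.from_dataframe(N).fit(**fit_kwargs)
    return PeriodicProfileModel(N, y, weights).fit(**fit_kwargs)


@dataclass(frozen=True)
class KnobRegression:
    """Ordinary least-squares response of one fit parameter to one knob."""

    knob_name: str
    param_name: str
    slope: float
    intercept: float
    reference: float

    def predict(self, knob):
        return self.intercept + self.slope * (np.asarray(knob, float) - self.reference)


def knob_regression(
    knob_values: Sequence[float],
    param_values: Sequence[float],
    reference: float = 0.0,
    knob_name: str = "knob",
    param_name: str = "param",
) -> KnobRegression:
    """OLS fit of a profile parameter against a model knob.

    The intercept is reported at ``knob = reference`` (e.g. bend 90 degrees,
    beta = 1, K3/K1 = 1.5), matching how the response relations are quoted.
    """
    x = np.asarray(knob_values, dtype=float) - reference
    y = np.asarray(param_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a knob regression")
    slope, intercept = np.polyfit(x, y, 1)
    return KnobRegression(knob_name, param_name, float(slope), float(intercept), reference)


def degenerate_family(
    kind: str,
    knob_values: Sequence[float],
    N: int = 147,
    bend_bp: int = 63,
) -> list[MoleculeSpec]:
    """Construct molecules predicted to share one cyclization profile.

    ``kind = "bend-stiffness"``: knobs are overall stiffness scales beta;
    each beta is paired with the compensating planar bend
    ``90 + 212 (beta - 1)`` degrees so the predicted peak height is constant.

    ``kind = "twist-helicity-bend"``: knobs are helical repeats; each repeat
    gets the pitch/circumference ``-5.84 (repeat - 10.5)`` that cancels the
    phase shift, and the bend ``90 + 14.3 |pitch/circumf|`` that restores
    the peak height.  Valid for |pitch/circumference| <= 1 (the peak-height
    response is no longer linear beyond that) and bends of 60-120 degrees.
    """
    specs = []
    if kind == "bend-stiffness":
        for beta in knob_values:
            bend = 90.0 + BEND_PER_BETA * (beta - 1.0)
            if not 60.0 <= bend <= 120.0:
                raise ValueError(
                    f"beta = {beta} needs a compensating bend of {bend:.1f} deg, "
                    "outside the validated 60-120 degree range"
                )
            specs.append(
                MoleculeSpec.single_bend(
                    bend, N, bend_bp, stiffness=StiffnessSet.baseline(scale_beta=beta)
                )
            )
    elif kind == "twist-helicity-bend":
        for repeat in knob_values:
            ratio = PITCH_RATIO_PER_REPEAT * (repeat - 10.5)
            if abs(ratio) > 1.0:
                raise ValueError(
                    f"helical repeat {repeat} needs |pitch/circumference| = "
                    f"{abs(ratio):.3f} > 1, beyond the validated range"
                )
            bend = 90.0 + BEND_PER_ABS_PITCH_RATIO * abs(ratio)
            specs.append(
                MoleculeSpec.single_bend(
                    bend, N, bend_bp, pitch_over_circumf=ratio, helical_repeat=repeat
                )
            )
    else:
        raise ValueError(f"unknown family kind {kind!r}")
    return specs


@dataclass(frozen=True)
class CalibrationResult:
    """Two-parameter summary of an arbitrary profile: (K3/K1, beta)."""

    k3_over_k1: float
    beta: float
    refined: bool
    extrapolated: bool


def calibrate_simple_model(
    a_fit: float,
    c_fit: float,
    bend_estimate_deg: float,
    refine: bool = False,
) -> CalibrationResult:
    """Condense a fitted profile to the two stiffness parameters.

    ``K3/K1`` follows from the curvature response
    ``c = -0.114 - 0.077 (K3/K1 - 1.5)``; ``beta`` then follows from the
    peak-height response ``a = 1.325 + 0.021 (bend - 90) - 4.45 (beta - 1)``
    given an independently estimated intrinsic bend.  With ``refine=True``
    the peak-height baseline is first shifted by ``0.30 (K3/K1 - 1.5)`` to
    account for the peak-height response to K3/K1 itself.
    """
    k3 = 1.5 + (c_fit - C_AT_REFERENCE) / C_PER_K3_RATIO
    baseline = A_BASELINE_COMBINED
    if refine:
        baseline = baseline + A_PER_K3_RATIO * (k3 - 1.5)
    beta = 1.0 + (
        baseline + A_PER_BEND_DEG * (bend_estimate_deg - 90.0) - a_fit
    ) / (-A_PER_BETA)
    extrapolated = not (
        60.0 <= bend_estimate_deg <= 120.0
        and 0.5 <= k3 <= 1.5
        and 0.87 <= beta <= 1.13
    )
    return CalibrationResult(float(k3), float(beta), refine, extrapolated)
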