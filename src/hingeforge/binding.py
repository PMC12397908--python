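"""Equilibrium binding models: quadratic titration and one-set-of-sites ITC.

Two fitters used to extract dissociation constants from solution binding
experiments on protein–ligand and protein–protein systems where ligand
depletion cannot be neglected:

* **Quadratic (ligand-depletion) titration model.**  For 1:1 binding of a
  fluorophore L (total concentration ``L_total``, held fixed) to a protein P
  titrated over a dilution series, the bound fraction is the exact root of
  the binding quadratic::

      f = [(P + L + Kd) − √((P + L + Kd)² − 4·P·L)] / (2·L)

  and the observed signal interpolates between ``F_free`` and ``F_bound``.
  This reduces to the hyperbola P/(P + Kd) when L ≪ Kd.

* **One-set-of-sites ITC model (Wiseman isotherm).**  For a cell species M
  (concentration ``M_t``) with ``n`` identical independent sites titrated by
  syringe species X, the cumulative heat after reaching total concentrations
  (M_t, X_t) in the cell is::

      Q = (n·M_t·ΔH·V0 / 2) · [1 + X_t/(n·M_t) + Kd/(n·M_t)
          − √((1 + X_t/(n·M_t) + Kd/(n·M_t))² − 4·X_t/(n·M_t))]

  Per-injection heats difference consecutive Q values with the displacement
  correction for an overfilled cell.  The c-value c = n·M_t/Kd governs how
  well Kd is determined; outside roughly 1–1000 the isotherm carries little
  information about Kd.

Units: concentrations in μM, volumes in μl, ΔH in kcal/mol, heats in μcal.
Both fitters are trust-region bounded least squares with a multi-start over
log-spaced Kd guesses to avoid local minima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: μcal per (μM · μl · kcal/mol): 1e-6 mol/l · 1e-6 l · 1e9 μcal/kcal
_HEAT_UNIT = 1e-3


class BindingError(Exception):
    pass


class FitError(BindingError):
    """Nonlinear fit failed to converge or is unidentifiable."""


@dataclass
class TitrationCurve:
    """A fluorescence dilution titration: signal vs. titrated protein."""

    P_total: np.ndarray  # μM, varied
    L_total: float  # μM, fixed fluorophore
    signal: np.ndarray  # a.u.
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.P_total = np.asarray(self.P_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.P_total.shape != self.signal.shape:
            raise BindingError("P_total and signal lengths differ")
        if np.any(self.P_total <= 0) or self.L_total <= 0:
            raise BindingError("concentrations must be positive")


@dataclass
class QuadraticFit:
    Kd: float  # μM
    F_free: float
    F_bound: float
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = 0.0
    at_bound: bool = False


@dataclass
class ItcExperiment:
    """Injection schedule and measured (or simulated) per-injection heats."""

    cell_conc: float  # M_t at start, μM
    syringe_conc: float  # μM
    injection_volumes: np.ndarray  # μl
    cell_volume: float  # V0, μl
    heats: np.ndarray | None = None  # μcal, one per injection

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise BindingError("concentrations and volumes must be positive")
        if np.any(self.injection_volumes <= 0):
            raise BindingError("injection volumes must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise BindingError("heats length must equal injections length")

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Post-injection total cell concentrations (M_t, X_t) in μM.

        Each injection of dV displaces cell content, diluting what was in
        the cell by the factor (1 − dV/V0), applied cumulatively, while
        delivering X_syr·dV/V0 of titrant.
        """
        m = np.empty_like(self.injection_volumes)
        x = np.empty_like(self.injection_volumes)
        mt, xt = self.cell_conc, 0.0
        for i, dv in enumerate(self.injection_volumes):
            dil = 1.0 - dv / self.cell_volume
            mt = mt * dil
            xt = xt * dil + self.syringe_conc * dv / self.cell_volume
            m[i], x[i] = mt, xt
        return m, x


@dataclass
class ItcFit:
    Kd: float  # μM
    n: float  # stoichiometry
    dH: float  # kcal/mol
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = 0.0
    c_value: float = 0.0


def quadratic_signal(
    P: np.ndarray | float,
    L_total: float,
    Kd: float,
    F_free: float,
    F_bound: float,
) -> np.ndarray | float:
    """Signal of the quadratic 1:1 binding model at protein concentration P."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0) or L_total <= 0 or Kd <= 0:
        raise BindingError("P, L_total and Kd must be positive")
    s = P + L_total + Kd
    disc = s * s - 4.0 * P * L_total
    if np.any(disc < -1e-9 * np.max(s) ** 2):
        raise BindingError("negative discriminant: invalid inputs")
    f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * L_total)
    f = np.clip(f, 0.0, 1.0)
    out = F_free + (F_bound - F_free) * f
    return float(out) if out.ndim == 0 else out


def fit_quadratic(
    curve: TitrationCurve,
    initial: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
) -> QuadraticFit:
    """Fit (Kd, F_free, F_bound) to a titration curve by least squares.

    Initial guesses default to data-driven heuristics; ``n_starts``
    log-spaced Kd starting points bracket the guess to avoid local minima.
    Standard errors come from the Jacobian-based covariance at the optimum.
    """
    P = curve.P_total
    y = curve.signal
    if P.size < 4:
        raise FitError("need at least 4 titration points")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        raise FitError("signal is constant: Kd is unidentifiable")

    guess = {
        "Kd": float(np.median(P)),
        "F_free": float(y[np.argmin(P)]),
        "F_bound": float(y[np.argmax(P)]),
    }
    if initial:
        guess.update(initial)
    lo_kd, hi_kd = (bounds or {}).get("Kd", (1e-6, 1e6))

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, ff, fb = theta
        return quadratic_signal(P, curve.L_total, kd, ff, fb) - y

    best = None
    for kd0 in np.geomspace(
        max(guess["Kd"] / 100, lo_kd * 10), min(guess["Kd"] * 100, hi_kd / 10), n_starts
    ):
        theta0 = np.array([kd0, guess["F_free"], guess["F_bound"]])
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=([lo_kd, -np.inf, -np.inf], [hi_kd, np.inf, np.inf]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # singular Jacobian etc.
            continue
        # status 0 (max evaluations) in a flat basin still yields a usable
        # optimum; keep the lowest-cost finite candidate
        if np.isfinite(res.cost) and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("quadratic fit did not converge from any start")
    kd, ff, fb = best.x
    at_bound = bool(np.isclose(kd, lo_kd) or np.isclose(kd, hi_kd))
    if at_bound:
        logger.warning("fitted Kd sits at a bound (%.3g μM): unidentifiable", kd)
    stderr = _stderr_from_jacobian(best.jac, best.fun, ["Kd", "F_free", "F_bound"])
    return QuadraticFit(
        Kd=float(kd),
        F_free=float(ff),
        F_bound=float(fb),
        stderr=stderr,
        rss=float(2 * best.cost),
        at_bound=at_bound,
    )


def itc_heats(
    Kd: float,
    n: float,
    dH: float,
    exp: ItcExperiment,
) -> np.ndarray:
    """Per-injection heats (μcal) of the one-set-of-sites model.

    Cumulative heats Q(i) follow the Wiseman isotherm at the post-injection
    cell concentrations; per-injection heats are

        ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V0)·(Q(i) + Q(i−1))/2

    where the last term accounts for heat carried out with the displaced
    cell volume.
    """
    if Kd <= 0 or n <= 0:
        raise BindingError("Kd and n must be positive")
    m, x = exp.concentrations()
    q = _cumulative_heat(Kd, n, dH, m, x, exp.cell_volume)
    dq = np.empty_like(q)
    v0 = exp.cell_volume
    q_prev = 0.0
    for i, dv in enumerate(exp.injection_volumes):
        dq[i] = q[i] - q_prev + (dv / v0) * (q[i] + q_prev) / 2.0
        q_prev = q[i]
    return dq


def _cumulative_heat(
    Kd: float, n: float, dH: float, m: np.ndarray, x: np.ndarray, v0: float
) -> np.ndarray:
    r = x / (n * m)
    kdt = Kd / (n * m)
    disc = (1.0 + r + kdt) ** 2 - 4.0 * r
    if np.any(disc < -1e-12):
        raise BindingError("negative discriminant in ITC isotherm")
    root = np.sqrt(np.maximum(disc, 0.0))
    return (n * m * dH * v0 / 2.0) * (1.0 + r + kdt - root) * _HEAT_UNIT


def fit_itc(
    exp: ItcExperiment,
    initial: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    skip_first: bool = False,
    n_starts: int = 5,
) -> ItcFit:
    """Fit (Kd, n, ΔH) to per-injection heats by bounded least squares.

    ``skip_first`` drops the first injection from the residuals (the usual
    treatment of a small test injection whose heat is corrupted by diffusion
    from the syringe tip).  A c-value outside [1, 1000] triggers a warning:
    Kd is then weakly determined by the isotherm shape.
    """
    if exp.heats is None:
        raise FitError("experiment carries no measured heats")
    n_inj = exp.injection_volumes.size
    n_used = n_inj - (1 if skip_first else 0)
    if n_used < 8:
        raise FitError("need at least 8 informative injections")
    y = exp.heats
    mask = np.ones(n_inj, dtype=bool)
    if skip_first:
        mask[0] = False

    scale = float(np.max(np.abs(y[mask])))
    if scale <= 0:
        raise FitError("all heats are zero: Kd and n are unidentifiable")

    guess = {"Kd": 1.0, "n": 1.0, "dH": None}
    if initial:
        guess.update(initial)
    if guess["dH"] is None:
        # total heat ≈ n·M_t·V0·ΔH at saturation
        total = float(np.sum(y))
        guess["dH"] = total / (exp.cell_conc * exp.cell_volume * _HEAT_UNIT)
        if guess["dH"] == 0:
            guess["dH"] = 1.0
    lo_kd, hi_kd = (bounds or {}).get("Kd", (1e-6, 1e5))
    lo_n, hi_n = (bounds or {}).get("n", (1e-3, 100.0))

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, nn, dh = theta
        model = itc_heats(kd, nn, dh, exp)
        return (model - y)[mask]

    best = None
    for kd0 in np.geomspace(
        max(guess["Kd"] / 100, lo_kd * 10), min(guess["Kd"] * 100, hi_kd / 10), n_starts
    ):
        theta0 = np.array([kd0, guess["n"], guess["dH"]])
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=([lo_kd, lo_n, -np.inf], [hi_kd, hi_n, np.inf]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if np.isfinite(res.cost) and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("ITC fit did not converge from any start")
    kd, nn, dh = best.x
    c_value = nn * exp.cell_conc / kd
    if not (1.0 <= c_value <= 1000.0):
        warnings.warn(
            f"c-value {c_value:.3g} outside [1, 1000]: Kd weakly determined",
            stacklevel=2,
        )
    stderr = _stderr_from_jacobian(best.jac, best.fun, ["Kd", "n", "dH"])
    return ItcFit(
        Kd=float(kd),
        n=float(nn),
        dH=float(dh),
        stderr=stderr,
        rss=float(2 * best.cost),
        c_value=float(c_value),
    )


def _stderr_from_jacobian(
    jac: np.ndarray, residuals: np.ndarray, names: list[str]
) -> dict[str, float]:
    m, p = jac.shape
    dof = max(m - p, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))
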