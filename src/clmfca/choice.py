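"""Conditional logit hospital-choice model: utilities, probabilities, MLE.

The model assigns each (demand point i, hospital j) pair a linear utility

    V_ij = b_LvH * 1[level=High] + b_City * 1[urb=City] + b_Rural * 1[urb=Rural]
           + b_Num * n_specialists_j + b_tau * tau_ij

with "Low" tier and "Metro" urbanization as reference levels, and converts
utilities into choice probabilities by a softmax over each patient's option
set (McFadden's conditional logit). The packaged default coefficients come
from a published preference analysis of obstetric patients:
(-1.072, -0.174, -0.862, +0.151, -0.064).

Everyone located at the same demand point shares one probability row: the
population at a centroid is assumed homogeneous in preference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geo import CatchmentStructure, DemandPoint, Hospital, TravelTimeMatrix

COEFFICIENT_NAMES = ("lvh_high", "urb_city", "urb_rural", "num_specialists", "travel_time")

CHOICE_SET_CONVENTIONS = ("catchment", "global")


class FitConvergenceError(RuntimeError):
    """Raised when the likelihood maximisation hits the iteration cap."""


@dataclass(frozen=True)
class ChoiceModelSpec:
    """Coefficient vector of the linear utility V_ij.

    Defaults are the published conditional-logit estimates for obstetric
    hospital choice; units are utility per unit covariate (per minute for
    ``beta_tau``, per specialist for ``beta_num``).
    """

    beta_lvh_high: float = -1.072
    beta_urb_city: float = -0.174
    beta_urb_rural: float = -0.862
    beta_num: float = 0.151
    beta_tau: float = -0.064

    def __post_init__(self) -> None:
        if not all(math.isfinite(b) for b in self.as_array()):
            raise ValueError("all coefficients must be finite")

    def as_array(self) -> np.ndarray:
        """Coefficients in ``COEFFICIENT_NAMES`` order."""
        return np.array(
            [self.beta_lvh_high, self.beta_urb_city, self.beta_urb_rural,
             self.beta_num, self.beta_tau],
            dtype=float,
        )

    @classmethod
    def from_array(cls, beta: Sequence[float]) -> "ChoiceModelSpec":
        b = np.asarray(beta, dtype=float)
        if b.shape != (5,):
            raise ValueError("expected 5 coefficients")
        return cls(*b.tolist())


DEFAULT_SPEC = ChoiceModelSpec()


def hospital_features(hospitals: Sequence[Hospital]) -> np.ndarray:
    """(n_hospitals, 4) design matrix: [is_High, is_City, is_Rural, n_specialists]."""
    return np.array(
        [
            [
                1.0 if h.level == "High" else 0.0,
                1.0 if h.urbanization == "City" else 0.0,
                1.0 if h.urbanization == "Rural" else 0.0,
                float(h.n_specialists),
            ]
            for h in hospitals
        ],
        dtype=float,
    ).reshape(len(hospitals), 4)


def utility(hospital: Hospital, tau_min: float, spec: ChoiceModelSpec = DEFAULT_SPEC) -> float:
    """Evaluate V_ij for one hospital at travel time ``tau_min`` minutes."""
    if tau_min < 0 or not math.isfinite(tau_min):
        raise ValueError("tau_min must be finite and >= 0")
    x = hospital_features([hospital])[0]
    return float(x @ spec.as_array()[:4] + spec.beta_tau * tau_min)


def utility_matrix(
    hospitals: Sequence[Hospital], tt: TravelTimeMatrix, spec: ChoiceModelSpec = DEFAULT_SPEC
) -> np.ndarray:
    """V_ij for every demand-hospital pair, shape (|I|, |J|)."""
    x = hospital_features(hospitals)
    return x @ spec.as_array()[:4] + spec.beta_tau * tt.times


def odds_ratio(coefficient: float) -> float:
    """Multiplier on the choice odds per unit covariate change: exp(beta)."""
    if not math.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return math.exp(coefficient)


@dataclass(frozen=True)
class ChoiceProbabilityMatrix:
    """Choice probabilities P_ij with the utilities and option sets behind them.

    Under the ``"catchment"`` convention each row is a softmax over the
    demand point's catchment J_i (zeros elsewhere, zero row if J_i is empty);
    under ``"global"`` the softmax runs over every hospital.
    """

    probs: np.ndarray
    utilities: np.ndarray
    catchments: CatchmentStructure
    choice_set: str = "catchment"

    @property
    def demand_ids(self) -> tuple[str, ...]:
        return self.catchments.demand_ids

    @property
    def hospital_ids(self) -> tuple[str, ...]:
        return self.catchments.hospital_ids


def _masked_softmax(util: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax restricted to mask; all-False rows give zero rows."""
    v = np.where(mask, util, -np.inf)
    with np.errstate(invalid="ignore"):
        vmax = np.max(v, axis=1, keepdims=True)
    vmax = np.where(np.isfinite(vmax), vmax, 0.0)  # empty rows
    e = np.exp(v - vmax)
    e[~mask] = 0.0
    denom = e.sum(axis=1, keepdims=True)
    out = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    return out


def choice_probabilities(
    demand: Sequence[DemandPoint],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
    catchments: CatchmentStructure,
    spec: ChoiceModelSpec = DEFAULT_SPEC,
    choice_set: str = "catchment",
) -> ChoiceProbabilityMatrix:
    """Softmax choice probabilities for every demand point.

    The softmax is computed with max-subtraction, so overflow cannot occur
    regardless of coefficient magnitudes. ``choice_set="catchment"``
    renormalises within each J_i (the default: patients choose among
    reachable hospitals, which makes the accessibility decomposition a
    proper mixture); ``"global"`` uses every hospital as the option set.
    """
    if choice_set not in CHOICE_SET_CONVENTIONS:
        raise ValueError(f"choice_set must be one of {CHOICE_SET_CONVENTIONS}")
    if tt.demand_ids != tuple(p.id for p in demand):
        raise ValueError("demand ordering inconsistent with travel-time matrix")
    if tt.hospital_ids != tuple(h.id for h in hospitals):
        raise ValueError("hospital ordering inconsistent with travel-time matrix")
    if catchments.demand_ids != tt.demand_ids or catchments.hospital_ids != tt.hospital_ids:
        raise ValueError("catchment structure inconsistent with travel-time matrix")

    util = utility_matrix(hospitals, tt, spec)
    mask = catchments.within if choice_set == "catchment" else np.ones_like(util, dtype=bool)
    probs = _masked_softmax(util, mask)
    return ChoiceProbabilityMatrix(
        probs=probs, utilities=util, catchments=catchments, choice_set=choice_set
    )


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed choice: the option set offered and the hospital taken."""

    demand_id: str
    chosen_hospital_id: str
    option_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "option_ids", tuple(self.option_ids))
        if self.chosen_hospital_id not in self.option_ids:
            raise ValueError(
                f"record for {self.demand_id!r}: chosen hospital "
                f"{self.chosen_hospital_id!r} not in its option set"
            )


@dataclass(frozen=True)
class ChoiceModelFit:
    """Maximum-likelihood estimates with asymptotic inference."""

    spec: ChoiceModelSpec
    standard_errors: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    unstable: bool = False

    def summary(self) -> str:
        lines = [f"conditional logit fit: loglik={self.log_likelihood:.4f}, "
                 f"iterations={self.n_iterations}"]
        for name, b, se in zip(COEFFICIENT_NAMES, self.spec.as_array(), self.standard_errors):
            lines.append(f"  {name:>16s}  {b:+.4f}  (se {se:.4f})")
        return "\n".join(lines)


def _stack_records(
    records: Sequence[ChoiceRecord],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad option sets to a rectangular (n, K, 5) covariate array.

    Returns (Z, mask, chosen_pos): covariates per alternative, validity mask,
    and the chosen alternative's position within each option set.
    """
    x = hospital_features(hospitals)
    h_index = {h: k for k, h in enumerate(tt.hospital_ids)}
    d_index = {d: i for i, d in enumerate(tt.demand_ids)}

    sizes = [len(r.option_ids) for r in records]
    if min(sizes) < 2:
        raise ValueError("every option set must contain at least 2 alternatives")
    kmax = max(sizes)
    n = len(records)

    z = np.zeros((n, kmax, 5), dtype=float)
    mask = np.zeros((n, kmax), dtype=bool)
    chosen_pos = np.zeros(n, dtype=int)
    for r_i, rec in enumerate(records):
        i = d_index[rec.demand_id]
        cols = [h_index[h] for h in rec.option_ids]
        m = len(cols)
        z[r_i, :m, :4] = x[cols]
        z[r_i, :m, 4] = tt.times[i, cols]
        mask[r_i, :m] = True
        chosen_pos[r_i] = rec.option_ids.index(rec.chosen_hospital_id)
    return z, mask, chosen_pos


def _loglik_grad_hess(beta, z, mask, chosen_pos):
    n = z.shape[0]
    v = z @ beta
    v[~mask] = -np.inf
    vmax = v.max(axis=1, keepdims=True)
    e = np.exp(v - vmax)
    e[~mask] = 0.0
    s = e.sum(axis=1)
    p = e / s[:, None]
    rows = np.arange(n)
    ll = float(np.sum(v[rows, chosen_pos] - vmax[:, 0] - np.log(s)))
    xbar = np.einsum("nk,nkp->np", p, z)
    grad = (z[rows, chosen_pos] - xbar).sum(axis=0)
    # observed information: sum_n [ E_p[zz'] - xbar xbar' ]
    ezz = np.einsum("nk,nkp,nkq->pq", p, z, z)
    hess = -(ezz - xbar.T @ xbar)
    return ll, grad, hess


def fit(
    records: Sequence[ChoiceRecord],
    hospitals: Sequence[Hospital],
    tt: TravelTimeMatrix,
    *,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> ChoiceModelFit:
    """Maximum-likelihood conditional-logit fit of the five utility coefficients.

    Newton's method from a zero start, with step halving on any likelihood
    decrease; the log-likelihood is globally concave so this converges to
    the unique maximum whenever one exists. Standard errors come from the
    inverse observed information at the optimum. Convergence is declared at
    gradient norm < ``gtol``; hitting ``max_iter`` raises
    :class:`FitConvergenceError`. Near-separated data (a covariate that
    perfectly predicts the choice) produce divergent estimates and are
    flagged ``unstable`` with a warning rather than an error.
    """
    if len(records) == 0:
        raise ValueError("at least one choice record is required")
    z, mask, chosen_pos = _stack_records(records, hospitals, tt)

    # a covariate constant within every option set is unidentifiable
    zm = np.where(mask[:, :, None], z, np.nan)
    spread = np.nanmax(zm, axis=1) - np.nanmin(zm, axis=1)
    if np.any(np.max(spread, axis=0) == 0):
        raise ValueError("a covariate is constant within every option set; model unidentifiable")

    beta = np.zeros(5)
    ll, grad, hess = _loglik_grad_hess(beta, z, mask, chosen_pos)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad) < gtol:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # Newton ascent: hess is negative (semi)definite
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(cand, z, mask, chosen_pos)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        raise FitConvergenceError(
            f"conditional-logit fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(5, np.nan)

    unstable = bool(np.any(np.abs(beta) > 25.0) or np.any(~np.isfinite(se)) or np.any(se > 50.0))
    if unstable:
        warnings.warn(
            "conditional-logit estimates look unstable (possible separation); "
            "interpret coefficients and standard errors with caution",
            RuntimeWarning,
            stacklevel=2,
        )
    return ChoiceModelFit(
        spec=ChoiceModelSpec.from_array(beta),
        standard_errors=se,
        log_likelihood=ll,
        n_iterations=n_iter,
        converged=converged,
        unstable=unstable,
    )
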