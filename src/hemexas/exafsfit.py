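"""Constrained multi-shell EXAFS refinement in k-space.

The model/results pair follows the fitting idiom of statistical-modelling
packages: :class:`EXAFSModel` binds a measured (or synthetic) chi(k)
spectrum to a :class:`~hemexas.shellmodel.ShellModel` hypothesis and a set
of scattering functions; :meth:`EXAFSModel.fit` refines the free
parameters and returns an :class:`EXAFSResults` carrying the refined
model, per-parameter uncertainties, goodness metrics, residuals and a
``summary()`` table.

The refinement minimizes the k-weighted squared residual

    A(theta) = sum_i [ k_i^w (chi_obs(k_i) - chi_model(k_i; theta)) ]^2

over the free shell parameters (subject to bounds), with an optional
multi-start against local minima.  Goodness metrics:

    chi2_nu = A / (sigma_w^2 (n - p))      reduced chi-square
    R^2     = A / sum_i [k_i^w chi_obs]^2  squared-residual fraction

where sigma_w is the statistical noise mapped to weighted units.
Asymmetric parameter uncertainties come from profile scans of the
unreduced chi-square to its Delta chi^2 = 1 crossings, re-minimizing all
other free parameters at each scan point - the classic MINOS construction
that honors parameter correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_K_MAX, DEFAULT_K_MIN
from .forward import simulate_chi
from .scattering import default_scattering_map
from .shellmodel import ShellModel

__all__ = [
    "EXAFSModel",
    "EXAFSResults",
    "fit_shells",
    "model_chi",
    "profile_uncertainty",
    "compare_models",
]

#: forward model, shared verbatim with the synthetic generator
model_chi = simulate_chi

_DEFAULT_BOUNDS = {
    "N": (0.05, 20.0),
    "r": (1.0, 6.0),
    "sigma2": (0.0, 0.1),
    "s02": (0.1, 1.2),
    "delta_e": (-15.0, 15.0),
}


@dataclass(frozen=True)
class _Param:
    """One free parameter: its location in the model and its bounds."""

    name: str  # e.g. "I Fe-N.r" or "s02"
    shell: str | None
    attr: str
    lo: float
    hi: float

    def get(self, model):
        if self.shell is None:
            return getattr(model, self.attr)
        return getattr(model[self.shell], self.attr)


def free_parameters(model):
    """Ordered list of free parameters of a ShellModel."""
    params = []
    for shell in model.shells:
        for attr in ("N", "r", "sigma2"):
            if not shell.free(attr):
                continue
            if attr == "sigma2" and shell.sigma2_tied_to is not None:
                continue
            lo, hi = shell.bounds.get(attr, _DEFAULT_BOUNDS[attr])
            params.append(_Param(f"{shell.label}.{attr}", shell.label, attr, lo, hi))
    if model.s02_free:
        lo, hi = _DEFAULT_BOUNDS["s02"]
        params.append(_Param("s02", None, "s02", lo, hi))
    if model.delta_e_free:
        lo, hi = _DEFAULT_BOUNDS["delta_e"]
        params.append(_Param("delta_e", None, "delta_e", lo, hi))
    return params


def _apply_vector(model, params, theta):
    shells = list(model.shells)
    for p, value in zip(params, theta):
        if p.shell is None:
            model = replace(model, **{p.attr: float(value)})
        else:
            shells = [
                replace(s, **{p.attr: float(value)}) if s.label == p.shell else s
                for s in shells
            ]
    return replace(model, shells=tuple(shells))


class EXAFSModel:
    """k-space shell refinement bound to one chi(k) spectrum.

    Parameters
    ----------
    chi : ChiSpectrum
        Observed spectrum; cropped to ``k_range`` for fitting.
    shell_model : ShellModel
        Structural hypothesis; its free flags/bounds define the parameter
        space and its current values the default starting point.
    funcs : dict, optional
        element -> ScatteringFunctions (defaults to the packaged set).
    k_range : (float, float)
    kweight : int
        w in the k^w residual weighting.
    noise : float, optional
        Statistical noise of chi per point (edge-step units).  When
        omitted it is taken from ``chi.noise_k`` or, failing that,
        estimated from the best-fit residual (which pins chi2_nu at 1).
    """

    def __init__(
        self,
        chi,
        shell_model,
        funcs=None,
        k_range=(DEFAULT_K_MIN, DEFAULT_K_MAX),
        kweight=1,
        noise=None,
    ):
        self.chi = chi.crop(*k_range)
        self.shell_model = shell_model
        self.funcs = funcs if funcs is not None else default_scattering_map()
        self.k_range = tuple(k_range)
        self.kweight = int(kweight)
        self.noise = noise if noise is not None else chi.noise_k
        self.params = free_parameters(shell_model)
        if not self.params:
            raise ValueError("shell model has no free parameters")
        if len(self.params) >= self.chi.k.size:
            raise ValueError(
                f"{len(self.params)} free parameters >= {self.chi.k.size} "
                "data points"
            )

    # -- objective ---------------------------------------------------------

    def _residual(self, theta):
        model = _apply_vector(self.shell_model, self.params, theta)
        pred = simulate_chi(model, self.funcs, self.chi.k).chi
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError(
                f"non-finite model for parameter vector {list(theta)}"
            )
        return self.chi.k**self.kweight * (self.chi.chi - pred)

    def objective(self, theta):
        """A(theta): k-weighted sum of squared residuals."""
        r = self._residual(theta)
        return float(r @ r)

    # -- fitting -----------------------------------------------------------

    def fit(self, start=None, multistart=3, seed=0, jitter=0.02):
        """Refine the free parameters; returns :class:`EXAFSResults`.

        ``start`` overrides the starting vector (default: the shell
        model's current values).  ``multistart`` runs the optimizer from
        the nominal start plus seeded, relatively jittered copies and
        keeps the lowest objective; the whole procedure is deterministic
        given ``seed``.
        """
        lo = np.array([p.lo for p in self.params])
        hi = np.array([p.hi for p in self.params])
        x0 = np.array(
            [p.get(self.shell_model) for p in self.params]
            if start is None
            else start,
            dtype=float,
        )
        x0 = np.clip(x0, lo, hi)
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(0, multistart - 1)):
            scale = np.where(np.abs(x0) > 1e-12, np.abs(x0), hi - lo)
            starts.append(np.clip(x0 + rng.normal(0, jitter) * scale, lo, hi))
        best = None
        for s in starts:
            sol = least_squares(
                self._residual,
                s,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        theta = best.x
        # snap to bounds and record pinned parameters
        at_bound = set()
        span = hi - lo
        for j, p in enumerate(self.params):
            if theta[j] - lo[j] < 1e-8 * span[j]:
                theta[j] = lo[j]
                at_bound.add(p.name)
            elif hi[j] - theta[j] < 1e-8 * span[j]:
                theta[j] = hi[j]
                at_bound.add(p.name)
        return self._build_results(theta, best, at_bound)

    def _build_results(self, theta, sol, at_bound):
        n, p = self.chi.k.size, len(self.params)
        resid = self._residual(theta)
        a_min = float(resid @ resid)
        kw = self.chi.k**self.kweight
        noise_given = self.noise is not None and np.isfinite(self.noise)
        if noise_given:
            sigma_w2 = float(self.noise**2 * np.mean(kw**2))
        else:
            sigma_w2 = a_min / max(n - p, 1) if a_min > 0 else np.nan
        chi2_red = a_min / (sigma_w2 * (n - p)) if sigma_w2 > 0 else 0.0
        r2 = a_min / float((kw * self.chi.chi) @ (kw * self.chi.chi))

        jac = sol.jac
        try:
            cov = sigma_w2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        sigma = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sigma, sigma)

        refined = _apply_vector(self.shell_model, self.params, theta)
        uncertainties = {
            p_.name: (float(s), float(s)) for p_, s in zip(self.params, sigma)
        }
        return EXAFSResults(
            model=refined,
            endog_model=self,
            theta=np.asarray(theta, float),
            uncertainties=uncertainties,
            chi2_reduced=float(chi2_red),
            r_squared=float(r2),
            residual=resid,
            correlations=corr,
            covariance=cov,
            at_bound=frozenset(at_bound),
            n_data=n,
            n_free=p,
            objective_min=a_min,
            sigma_w2=float(sigma_w2),
            noise_given=noise_given,
        )


@dataclass
class EXAFSResults:
    """Outcome of a k-space shell refinement."""

    model: ShellModel
    endog_model: EXAFSModel
    theta: np.ndarray
    uncertainties: dict
    chi2_reduced: float
    r_squared: float
    residual: np.ndarray
    correlations: np.ndarray
    covariance: np.ndarray
    at_bound: frozenset
    n_data: int
    n_free: int
    objective_min: float
    sigma_w2: float
    noise_given: bool
    profiled: dict = field(default_factory=dict)

    @property
    def param_names(self):
        return [p.name for p in self.endog_model.params]

    def best_fit_chi(self):
        """Model chi(k) at the refined parameters, on the fit grid."""
        return simulate_chi(
            self.model, self.endog_model.funcs, self.endog_model.chi.k
        )

    def conf_interval(self, name):
        """MINOS-style asymmetric (low, high) distances for one parameter
        (cached); see :func:`profile_uncertainty`."""
        if name not in self.profiled:
            self.profiled[name] = profile_uncertainty(self, name)
        return self.profiled[name]

    def plot(self, ax=None):
        """k-weighted data, best fit and residual on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        chi = self.endog_model.chi
        kw = chi.k**self.endog_model.kweight
        ax.plot(chi.k, kw * chi.chi, ".", ms=3, label="data")
        ax.plot(chi.k, kw * self.best_fit_chi().chi, "-", label="best fit")
        offset = 1.2 * np.abs(kw * chi.chi).max()
        ax.plot(chi.k, self.residual - offset, "-", lw=0.8, label="residual")
        ax.set_xlabel(r"k [$\AA^{-1}$]")
        ax.set_ylabel(r"$k^w\,\chi(k)$")
        ax.legend()
        return ax

    def summary(self):
        lines = [
            "EXAFS k-space shell refinement",
            f"  k-range {self.endog_model.k_range}  kweight {self.endog_model.kweight}"
            f"  n_data {self.n_data}  n_free {self.n_free}",
            f"  chi2_reduced {self.chi2_reduced:.4g}"
            + ("" if self.noise_given else " (noise scaled from residual)"),
            f"  R^2 {self.r_squared:.4g}",
            "",
            f"  {'shell':<12s}{'el':<4s}{'N':>7s}{'r [A]':>9s}{'sigma2 [A^2]':>14s}",
        ]
        from .forward import resolve_sigma2

        s2 = resolve_sigma2(self.model)
        for s in self.model.shells:
            tied = " (tied)" if s.sigma2_tied_to else ""
            lines.append(
                f"  {s.label:<12s}{s.element:<4s}{s.N:>7.2f}{s.r:>9.3f}"
                f"{s2[s.label]:>14.2e}{tied}"
            )
        lines.append(
            f"  S0^2 {self.model.s02:.3f}   dE {self.model.delta_e:.2f} eV"
        )
        lines.append("")
        lines.append("  free parameter        value     +/- (1 sigma)")
        for name, sig in self.uncertainties.items():
            j = self.param_names.index(name)
            pin = "  [at bound]" if name in self.at_bound else ""
            lines.append(
                f"  {name:<20s}{self.theta[j]:>10.4f}   -{sig[0]:.4f}/+{sig[1]:.4f}{pin}"
            )
        return "\n".join(lines)


def fit_shells(chi, model, funcs=None, k_range=(DEFAULT_K_MIN, DEFAULT_K_MAX),
               kweight=1, noise=None, **fit_kw):
    """Functional wrapper: build an :class:`EXAFSModel` and fit it."""
    return EXAFSModel(
        chi, model, funcs=funcs, k_range=k_range, kweight=kweight, noise=noise
    ).fit(**fit_kw)


# ---------------------------------------------------------------------------
# profile (MINOS-style) uncertainties


def _conditional_min(exm, fixed_idx, fixed_value, theta0):
    """Minimize the objective over all parameters but one."""
    params = exm.params
    free_idx = [j for j in range(len(params)) if j != fixed_idx]
    if not free_idx:
        theta = np.array(theta0, float)
        theta[fixed_idx] = fixed_value
        return exm.objective(theta)
    lo = np.array([params[j].lo for j in free_idx])
    hi = np.array([params[j].hi for j in free_idx])

    def resid(sub):
        theta = np.array(theta0, float)
        theta[fixed_idx] = fixed_value
        theta[free_idx] = sub
        return exm._residual(theta)

    x0 = np.clip(np.array(theta0, float)[free_idx], lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12)
    return float(2 * sol.cost)


def profile_uncertainty(fit, name, max_steps=60):
    """Asymmetric 1-sigma interval from a Delta chi^2 = 1 profile scan.

    Scans the named parameter away from its best-fit value in both
    directions, re-minimizing every other free parameter at each point,
    until the unreduced chi-square (objective / sigma_w^2) rises one unit
    above its minimum; the crossing is refined by inverse interpolation.
    When a bound is hit first, the distance to the bound is returned and
    flagged.

    Returns a dict: ``low``/``high`` (positive distances), ``at_bound_low``
    / ``at_bound_high``, ``open_low`` / ``open_high`` (crossing not
    bracketed within the scan limits).
    """
    exm = fit.endog_model
    names = fit.param_names
    if name not in names:
        raise KeyError(f"{name!r} is not a free parameter of this fit")
    j = names.index(name)
    p = exm.params[j]
    theta0 = fit.theta
    a_min = fit.objective_min
    sigma_w2 = fit.sigma_w2
    target = 1.0  # Delta chi^2

    cov_sigma = fit.uncertainties[name][0]
    if not np.isfinite(cov_sigma) or cov_sigma == 0:
        cov_sigma = 0.05 * max(abs(theta0[j]), 1e-3)
    step = 0.05 * cov_sigma  # fine scan resolution near the minimum

    out = {}
    for direction, key in ((+1, "high"), (-1, "low")):
        bound = p.hi if direction > 0 else p.lo
        prev_x, prev_d = theta0[j], 0.0
        found = False
        at_bound = False
        x = theta0[j]
        current = step
        for _ in range(max_steps):
            x = theta0[j] + direction * current
            hit = (direction > 0 and x >= bound) or (direction < 0 and x <= bound)
            if hit:
                x = bound
            d = (_conditional_min(exm, j, x, theta0) - a_min) / sigma_w2
            if d >= target:
                from scipy.optimize import brentq

                def excess(xx):
                    return (
                        _conditional_min(exm, j, xx, theta0) - a_min
                    ) / sigma_w2 - target

                if x != prev_x and d > target:
                    xc = brentq(
                        excess, min(prev_x, x), max(prev_x, x),
                        xtol=1e-4 * max(abs(cov_sigma), 1e-9),
                    )
                else:
                    xc = x
                out[key] = abs(xc - theta0[j])
                found = True
                break
            if hit:
                out[key] = abs(bound - theta0[j])
                at_bound = True
                found = True
                break
            prev_x, prev_d = x, d
            current *= 1.6  # accelerate outward
        out[f"at_bound_{key}"] = at_bound
        out[f"open_{key}"] = not found
        if not found:
            out[key] = abs(x - theta0[j])
    return out


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    delta_chi2_reduced: float
    delta_r_squared: float
    delta_n_free: int
    a_at_bound: frozenset
    b_at_bound: frozenset
    preferred: str  # "a", "b" or "none"
    verdict: str


def compare_models(fit_a, fit_b, r2_improvement=0.20):
    """Compare two fits of the same data (e.g. 4+1 vs 5+1 coordination).

    ``fit_b`` (the richer model) is preferred iff it lowers the squared
    residual R^2 by at least ``r2_improvement`` (fractional) without any
    of its parameters pinning at a bound.  Anything less keeps the
    simpler model - adding a shell must pay for itself.
    """
    ka, kb = fit_a.endog_model.chi, fit_b.endog_model.chi
    if ka.k.shape != kb.k.shape or not np.allclose(ka.k, kb.k):
        raise ValueError("fits are not on the same k grid")
    if not np.allclose(ka.chi, kb.chi):
        raise ValueError("fits are not of the same data")
    d_chi2 = fit_b.chi2_reduced - fit_a.chi2_reduced
    d_r2 = fit_b.r_squared - fit_a.r_squared
    d_free = fit_b.n_free - fit_a.n_free
    improves = (
        fit_b.r_squared <= (1.0 - r2_improvement) * fit_a.r_squared
        and fit_a.r_squared - fit_b.r_squared > 1e-9
    )
    clean = not fit_b.at_bound
    if improves and clean:
        preferred = "b"
        verdict = (
            f"model b preferred: R^2 improves {fit_a.r_squared:.3g} -> "
            f"{fit_b.r_squared:.3g} (>= {r2_improvement:.0%}) with no "
            "bound-pinned parameters; the additional shell is supported."
        )
    else:
        preferred = "none" if not fit_a.at_bound else "none"
        reason = []
        if not improves:
            reason.append(
                f"R^2 gain {fit_a.r_squared:.3g} -> {fit_b.r_squared:.3g} "
                f"below the {r2_improvement:.0%} threshold"
            )
        if not clean:
            reason.append(
                f"parameters at bounds in model b: {sorted(fit_b.at_bound)}"
            )
        verdict = "model b not preferred: " + "; ".join(reason)
        if fit_a.at_bound:
            verdict += (
                f" (note: model a pins {sorted(fit_a.at_bound)} at bounds, "
                "suggesting it is itself misspecified)"
            )
    return ModelComparison(
        delta_chi2_reduced=float(d_chi2),
        delta_r_squared=float(d_r2),
        delta_n_free=int(d_free),
        a_at_bound=fit_a.at_bound,
        b_at_bound=fit_b.at_bound,
        preferred=preferred,
        verdict=verdict,
    )
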