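"""Equilibrium speciation for 1:1-type and competitive binding models.

A binding model is a set of components (ligand, cations) and complex species
with cumulative stability constants on a log10 scale (concentration
quotients, mol dm^-3 standard state; activity coefficients are not applied).
Speciation along a titration is obtained by solving the component mass
balances in log-free-concentration space with a damped Newton iteration;
pure 1:1 models short-circuit to the numerically stable closed-form
quadratic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "BindingModel",
    "TitrationSeries",
    "SpeciationResult",
    "SpeciationError",
    "build_titration_series",
    "solve_speciation",
    "detect_equivalence_break",
    "BreakpointResult",
]


class SpeciationError(RuntimeError):
    """Raised when the mass-balance iteration fails to converge."""


@dataclass(frozen=True)
class Species:
    """A complex species: stoichiometry over the model's components and
    its cumulative formation constant log10(beta)."""

    name: str
    stoich: dict[str, int]
    log_beta: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.stoich or all(v == 0 for v in self.stoich.values()):
            raise ValueError(f"species {self.name!r}: stoichiometry vector is zero")
        if any(v < 0 or v != int(v) for v in self.stoich.values()):
            raise ValueError(f"species {self.name!r}: stoichiometries must be small non-negative integers")
        if not math.isfinite(self.log_beta):
            raise ValueError(f"species {self.name!r}: logBeta must be finite")


@dataclass
class BindingModel:
    """Components plus complex species with log10 cumulative constants."""

    components: list[str]
    species: list[Species] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component required")
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate component names")
        for sp in self.species:
            unknown = set(sp.stoich) - set(self.components)
            if unknown:
                raise ValueError(f"species {sp.name!r} references undeclared components {sorted(unknown)}")

    @property
    def stoich_matrix(self) -> np.ndarray:
        """(n_species, n_components) integer stoichiometry matrix."""
        return np.array(
            [[sp.stoich.get(c, 0) for c in self.components] for sp in self.species],
            dtype=float,
        )

    @property
    def log_betas(self) -> np.ndarray:
        return np.array([sp.log_beta for sp in self.species], dtype=float)

    def free_species(self) -> list[Species]:
        return [sp for sp in self.species if not sp.fixed]

    def with_log_beta(self, name: str, log_beta: float) -> "BindingModel":
        """Copy of the model with one species' constant replaced."""
        new = [
            Species(sp.name, dict(sp.stoich), log_beta if sp.name == name else sp.log_beta, sp.fixed)
            for sp in self.species
        ]
        return BindingModel(list(self.components), new)

    def is_pure_1to1(self) -> bool:
        """One species, binding exactly one unit of each of two components."""
        if len(self.species) != 1 or len(self.components) != 2:
            return False
        sp = self.species[0]
        return sorted(sp.stoich.get(c, 0) for c in self.components) == [1, 1]


@dataclass
class TitrationSeries:
    """Analytical (total) concentrations per component along a titration.

    ``totals`` has shape (n_points, n_components); ``volumes`` are cumulative
    titrant volumes in cm^3 (0 for the initial point in cuvette mode).
    """

    components: list[str]
    totals: np.ndarray
    volumes: np.ndarray
    v0: float
    mode: str = "cuvette"

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.totals.shape != (len(self.volumes), len(self.components)):
            raise ValueError("totals shape inconsistent with volumes/components")
        if np.any(self.totals < 0):
            raise ValueError("negative total concentration")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("volumes must be strictly increasing")
        if self.v0 <= 0:
            raise ValueError("V0 must be positive")

    @property
    def n_points(self) -> int:
        return len(self.volumes)

    def total(self, component: str) -> np.ndarray:
        return self.totals[:, self.components.index(component)]


def build_titration_series(
    cell_conc: dict[str, float],
    v0: float,
    titrant_conc: dict[str, float],
    added_volumes: "list[float] | np.ndarray",
    mode: str = "cuvette",
) -> TitrationSeries:
    """Total concentrations after a volume schedule.

    ``cuvette`` mode dilutes by simple mixing into the growing volume
    V0 + V_i.  ``itc_displacement`` mode models a fixed-volume perfusion
    cell: each injection of volume v expels an equal volume of cell
    solution, so c <- c*(1 - v/V0) + c_tit*(v/V0) for components in the
    syringe and c <- c*(1 - v/V0) for cell-only components.

    Parameters are in mol dm^-3 and cm^3; volumes are cumulative in
    cuvette mode and per-injection in itc_displacement mode.
    """
    if mode not in ("cuvette", "itc_displacement"):
        raise ValueError(f"unknown mode {mode!r}")
    vols = np.asarray(added_volumes, dtype=float)
    if np.any(vols < 0):
        raise ValueError("negative volume")
    components = sorted(set(cell_conc) | set(titrant_conc))
    c_cell = np.array([cell_conc.get(c, 0.0) for c in components])
    c_tit = np.array([titrant_conc.get(c, 0.0) for c in components])

    if mode == "cuvette":
        cum = vols
        totals = (c_cell[None, :] * v0 + c_tit[None, :] * cum[:, None]) / (v0 + cum)[:, None]
        if cum[0] != 0:  # prepend the initial (pre-titration) point
            cum = np.concatenate([[0.0], cum])
            totals = np.vstack([c_cell, totals])
        # strictly-increasing volume grid is enforced by TitrationSeries
        return TitrationSeries(components, totals, cum, v0, mode)

    # displacement: vols are per-injection volumes
    c = c_cell.copy()
    rows, cum_rows = [], []
    cum = 0.0
    for v in vols:
        if v <= 0:
            raise ValueError("injection volumes must be positive")
        f = v / v0
        c = c * (1.0 - f) + c_tit * f
        cum += v
        rows.append(c.copy())
        cum_rows.append(cum)
    return TitrationSeries(components, np.array(rows), np.array(cum_rows), v0, mode)


@dataclass
class SpeciationResult:
    """Free and species concentrations satisfying the mass balances."""

    components: list[str]
    free: np.ndarray
    species_names: list[str]
    species_conc: np.ndarray
    residual: np.ndarray

    def free_of(self, component: str) -> float:
        return float(self.free[self.components.index(component)])

    def conc_of(self, species: str) -> float:
        return float(self.species_conc[self.species_names.index(species)])


def _solve_1to1_quadratic(k: float, total_l: float, total_m: float) -> float:
    """[ML] for L + M <-> ML, numerically stable for K up to ~1e14.

    Root of K(T_L - x)(T_M - x) = x written to avoid cancellation:
    x = 2 T_L T_M / (b + sqrt(b^2 - 4 T_L T_M)), b = T_L + T_M + 1/K.
    """
    if k <= 0 or total_l == 0 or total_m == 0:
        return 0.0
    b = total_l + total_m + 1.0 / k
    # expanded discriminant: b^2 - 4 T_L T_M computed directly cancels
    # catastrophically when K(T_L + T_M) >> 1
    disc = (total_l - total_m) ** 2 + (2.0 / k) * (total_l + total_m) + 1.0 / (k * k)
    return 2.0 * total_l * total_m / (b + math.sqrt(disc))


def solve_speciation(
    model: BindingModel,
    totals: dict[str, float],
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Solve component mass balances for free and species concentrations.

    Works in log-free-concentration space (positivity by construction) with
    a damped Newton iteration on the residuals

        R_j = f_j + sum_s nu_sj * 10^logbeta_s * prod_k f_k^nu_sk - T_j.

    Components with zero analytical total are eliminated (their free
    concentration and every species containing them are zero).  Pure 1:1
    models bypass Newton via the closed-form quadratic.

    ``tol`` is a relative mass-balance residual (relative to each total).
    """
    t = np.array([totals.get(c, 0.0) for c in model.components], dtype=float)
    if np.any(t < 0):
        raise ValueError("negative total concentration")

    n_comp = len(model.components)
    n_spec = len(model.species)
    free = np.zeros(n_comp)
    spec_conc = np.zeros(n_spec)

    active = t > 0
    nu_full = model.stoich_matrix
    # species are live only if every component they bind is present
    live = np.array([not np.any(nu_full[s, ~active] > 0) for s in range(n_spec)]) if n_spec else np.array([], bool)

    if model.is_pure_1to1() and active.all() and live.all():
        sp = model.species[0]
        i_l, i_m = 0, 1
        x = _solve_1to1_quadratic(10.0 ** sp.log_beta, t[i_l], t[i_m])
        free = t - x
        spec_conc = np.array([x])
    elif not active.any() or not live.any():
        free[active] = t[active]
    else:
        idx = np.where(active)[0]
        sidx = np.where(live)[0]
        nu = nu_full[np.ix_(sidx, idx)]
        lb = model.log_betas[sidx]
        ta = t[idx]
        x = np.log(ta)  # start at free = total
        ln10 = math.log(10.0)
        scale = np.maximum(ta, 1e-300)

        def residual(xv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            f = np.exp(xv)
            cs = np.exp(lb * ln10 + nu @ xv)
            return f + cs @ nu - ta, cs

        r, cs = residual(x)
        best = np.max(np.abs(r) / scale)
        for _ in range(max_iter):
            if best < tol:
                break
            # Jacobian wrt ln f: diag(f) + nu^T diag(c_s) nu
            f = np.exp(x)
            jac = np.diag(f) + nu.T @ (cs[:, None] * nu)
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -r, rcond=None)[0]
            # damp: cap the log step, then backtrack on the residual norm
            mx = np.max(np.abs(step))
            if mx > 3.0:
                step *= 3.0 / mx
            lam = 1.0
            for _ in range(40):
                r_new, cs_new = residual(x + lam * step)
                if np.max(np.abs(r_new) / scale) < best:
                    break
                lam *= 0.5
            x = x + lam * step
            r, cs = residual(x)
            best = np.max(np.abs(r) / scale)
        else:
            raise SpeciationError(f"speciation did not converge: worst relative residual {best:.3e}")
        free[idx] = np.exp(x)
        spec_conc[sidx] = cs

    resid = free + (spec_conc @ nu_full if n_spec else 0.0) - t
    return SpeciationResult(
        list(model.components),
        free,
        [sp.name for sp in model.species],
        spec_conc,
        resid,
    )


def speciation_profile(model: BindingModel, series: TitrationSeries, tol: float = 1e-12) -> np.ndarray:
    """Species concentrations at every titration point.

    Returns an (n_points, n_components + n_species) array: free component
    concentrations followed by species concentrations, in model order.
    """
    out = np.empty((series.n_points, len(model.components) + len(model.species)))
    for i in range(series.n_points):
        totals = {c: series.totals[i, series.components.index(c)] for c in series.components if c in model.components}
        res = solve_speciation(model, totals, tol=tol)
        out[i] = np.concatenate([res.free, res.species_conc])
    return out


@dataclass
class BreakpointResult:
    """Two-segment piecewise-linear breakpoint with a bootstrap CI."""

    breakpoint: float | None
    ci_low: float | None
    ci_high: float | None
    has_break: bool
    weak: bool
    message: str = ""


def _piecewise_ssq(x: np.ndarray, y: np.ndarray, b: float) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.clip(x - b, 0.0, None)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def detect_equivalence_break(
    response: np.ndarray,
    ratio: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    f_alpha: float = 0.01,
) -> BreakpointResult:
    """Locate the break in a linear-then-plateau titration curve.

    Fits a continuous two-segment piecewise-linear model by least squares
    over candidate break positions; a break is reported only when the
    two-segment fit beats a single line by an F-test at ``f_alpha``.  The
    confidence interval comes from residual-bootstrap refits; an interval
    wider than 0.2 in molar ratio flags the break as weak.  Ties between
    equally good break positions resolve toward ratio 1.
    """
    from scipy import stats

    x = np.asarray(ratio, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) < 6 or x.min() >= 1.0 or x.max() <= 1.0:
        raise ValueError("need >= 6 points spanning molar ratios below and above 1")
    order = np.argsort(x)
    x, y = x[order], y[order]

    def best_break(yv: np.ndarray) -> tuple[float, float]:
        candidates = np.linspace(x[1], x[-2], 201)
        ssqs = np.array([_piecewise_ssq(x, yv, b)[0] for b in candidates])
        # tie-break: among near-minimal SSQ, prefer the break nearest ratio 1
        near = ssqs <= ssqs.min() * (1.0 + 1e-9) + 1e-30
        cand = candidates[near]
        b0 = cand[np.argmin(np.abs(cand - 1.0))]
        from scipy.optimize import minimize_scalar

        lo = max(x[1], b0 - 0.05 * (x[-1] - x[0]))
        hi = min(x[-2], b0 + 0.05 * (x[-1] - x[0]))
        res = minimize_scalar(lambda b: _piecewise_ssq(x, yv, b)[0], bounds=(lo, hi), method="bounded")
        return float(res.x), float(res.fun)

    b_hat, ssq2 = best_break(y)
    # single-line comparison
    d1 = np.column_stack([np.ones_like(x), x])
    c1, *_ = np.linalg.lstsq(d1, y, rcond=None)
    ssq1 = float(np.sum((y - d1 @ c1) ** 2))
    n = len(x)
    tss = float(np.sum((y - y.mean()) ** 2))
    if ssq1 <= 1e-16 * max(tss, 1e-300):
        # a single line already explains the data to machine precision
        return BreakpointResult(None, None, None, False, False, "no break: single line not rejected")
    df2 = n - 4  # intercept, 2 slopes, break
    fstat = ((ssq1 - ssq2) / 2.0) / max(ssq2 / max(df2, 1), 1e-300)
    p = float(stats.f.sf(fstat, 2, max(df2, 1)))
    if p > f_alpha:
        return BreakpointResult(None, None, None, False, False, "no break: single line not rejected")

    # pairs (case-resampling) bootstrap: robust to systematic lack of fit
    # of the two-segment model, which residual resampling would hide
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = np.sort(rng.choice(n, size=n, replace=True))
        xb, yb = x[idx], y[idx]
        if xb[1] >= xb[-2]:
            continue
        candidates = np.linspace(xb[1], xb[-2], 101)
        ssqs = [_piecewise_ssq(xb, yb, b)[0] for b in candidates]
        boots.append(candidates[int(np.argmin(ssqs))])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    weak = (hi - lo) > 0.2
    return BreakpointResult(b_hat, float(lo), float(hi), True, weak, "weak break: wide CI" if weak else "")
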