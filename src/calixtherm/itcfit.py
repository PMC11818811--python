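"""Isothermal titration calorimetry: forward model and fitting.

The instrument is a fixed-volume perfusion cell: each injection expels an
equal volume of cell solution, so analytical totals follow the
displacement update c <- c(1 - v/V0) + c_syr(v/V0).  The heat of injection
i is the enthalpy-weighted change in moles of every complex in the cell,

    q_i = V0 * sum_s dH_s * ([s]_i - [s]_{i-1}(1 - v_i/V0)) + offset,

with the (1 - v/V0) factor accounting for complex expelled with the
displaced volume.  Heats are mJ internally; enthalpies kJ mol^-1; volumes
cm^3 (cell) and mm^3 (injections).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from calixtherm.equilibria import BindingModel, solve_speciation

__all__ = [
    "ITCExperiment",
    "ITCFitResult",
    "simulate_itc",
    "expected_heats",
    "fit_itc_1to1",
    "fit_enthalpy_only",
    "correct_dilution",
    "fit_competitive_itc",
]

C_VALUE_UNIDENTIFIABLE = 1e4


@dataclass
class ITCExperiment:
    """Per-injection integrated heats with cell/syringe metadata.

    ``cell_volume`` in cm^3, ``injection_volumes`` in mm^3 (uL), ``heats``
    in mJ, concentrations in mol dm^-3, temperature in K.
    """

    cell_volume: float
    injection_volumes: np.ndarray
    heats: np.ndarray
    cell_conc: dict[str, float]
    syringe_conc: dict[str, float]
    temperature: float = 298.15
    discard_first: bool = True
    dilution_corrected: bool = False

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection volume and heat counts differ")

    @property
    def n_injections(self) -> int:
        return len(self.heats)

    def used(self) -> np.ndarray:
        """Boolean mask of injections entering fits (first-injection discard)."""
        mask = np.ones(self.n_injections, dtype=bool)
        if self.discard_first and self.n_injections > 1:
            mask[0] = False
        return mask


def _totals_along(
    cell_conc: dict[str, float],
    syringe_conc: dict[str, float],
    v0_cm3: float,
    inj_mm3: np.ndarray,
    components: list[str],
) -> np.ndarray:
    """(n_inj + 1, n_comp) totals: initial cell plus after each injection."""
    c = np.array([cell_conc.get(k, 0.0) for k in components])
    tit = np.array([syringe_conc.get(k, 0.0) for k in components])
    rows = [c.copy()]
    for v in inj_mm3:
        f = (v / 1000.0) / v0_cm3
        c = c * (1.0 - f) + tit * f
        rows.append(c.copy())
    return np.array(rows)


def expected_heats(
    model: BindingModel,
    experiment: ITCExperiment,
    delta_h: dict[str, float],
    offset: float = 0.0,
) -> np.ndarray:
    """Forward model: per-injection heats (mJ) for given constants and
    species formation enthalpies (kJ mol^-1)."""
    unknown = set(delta_h) - {sp.name for sp in model.species}
    if unknown:
        raise ValueError(f"unknown species in enthalpy map: {sorted(unknown)}")
    comps = list(model.components)
    totals = _totals_along(
        experiment.cell_conc, experiment.syringe_conc, experiment.cell_volume,
        experiment.injection_volumes, comps,
    )
    dh = np.array([delta_h.get(sp.name, 0.0) for sp in model.species])
    conc = np.array([
        solve_speciation(model, dict(zip(comps, row))).species_conc for row in totals
    ])
    v0_dm3 = experiment.cell_volume / 1000.0
    q = np.empty(experiment.n_injections)
    for i in range(experiment.n_injections):
        f = (experiment.injection_volumes[i] / 1000.0) / experiment.cell_volume
        dn = (conc[i + 1] - conc[i] * (1.0 - f)) * v0_dm3  # mol
        q[i] = float(dn @ dh) * 1e6 + offset  # kJ -> mJ
    return q


def simulate_itc(
    model: BindingModel,
    experiment: ITCExperiment,
    delta_h: dict[str, float],
    offset: float = 0.0,
    noise_sd: float = 0.0,
    noise_relative: float = 0.0,
    seed: int | None = None,
) -> ITCExperiment:
    """Populate an experiment's heats from the forward model plus noise.

    ``offset`` is a constant per-injection dilution heat (mJ);
    ``noise_sd`` an additive Gaussian standard deviation (mJ);
    ``noise_relative`` a multiplicative Gaussian fraction of each
    injection's heat.
    """
    q = expected_heats(model, experiment, delta_h, offset)
    if noise_sd < 0 or noise_relative < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if noise_sd > 0 or noise_relative > 0:
        rng = np.random.default_rng(seed)
        if noise_sd > 0:
            q = q + rng.normal(0.0, noise_sd, size=q.shape)
        if noise_relative > 0:
            q = q * (1.0 + rng.normal(0.0, noise_relative, size=q.shape))
    return replace(experiment, heats=q)


def cumulative_ratio(experiment: ITCExperiment, titrant: str, ligand: str) -> np.ndarray:
    """Cation-to-ligand molar ratio in the cell after each injection."""
    comps = sorted(set(experiment.cell_conc) | set(experiment.syringe_conc))
    totals = _totals_along(
        experiment.cell_conc, experiment.syringe_conc, experiment.cell_volume,
        experiment.injection_volumes, comps,
    )[1:]
    it, il = comps.index(titrant), comps.index(ligand)
    return totals[:, it] / totals[:, il]


@dataclass
class ITCFitResult:
    log_k: float
    log_k_se: float
    delta_h: float  # kJ mol^-1
    delta_h_se: float
    offset: float  # mJ per injection
    n_sites: float
    c_value: float
    residuals: np.ndarray
    k_unidentifiable: bool
    degenerate: bool = False
    message: str = ""
    extra: dict = field(default_factory=dict)


def _fit_heats(
    experiment: ITCExperiment,
    build_model,
    ligand: str,
    titrant: str,
    x0: np.ndarray,
    bounds: tuple,
    float_n: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared nonlinear LSQ over (logK, dH, offset[, n])."""
    mask = experiment.used()
    q_obs = experiment.heats[mask]
    if not np.any(np.abs(q_obs) > 0):
        raise ValueError("all heats are zero: nothing to fit")

    def resid(x):
        model, dh_map, off = build_model(x)
        exp_n = experiment
        if float_n:
            cell = dict(experiment.cell_conc)
            cell[ligand] = experiment.cell_conc[ligand] * x[-1]
            exp_n = replace(experiment, cell_conc=cell)
        q = expected_heats(model, exp_n, dh_map, off)
        return q[mask] - q_obs

    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ITC fit did not converge: {sol.message}")
    # covariance from J^T J
    m, p = sol.jac.shape
    dof = max(m - p, 1)
    sigma2 = 2.0 * sol.cost / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return sol.x, se, sol.fun


def fit_itc_1to1(
    experiment: ITCExperiment,
    ligand: str = "L",
    titrant: str = "M",
    float_n: bool = False,
) -> ITCFitResult:
    """Fit (log K, dH, offset[, n]) of a 1:1 binding isotherm.

    K is flagged unidentifiable when the Wiseman c-value (K * cell
    concentration * n) exceeds 1e4: the isotherm is then a step function
    whose shape no longer constrains K, although dH (the step height)
    remains well determined.
    """
    if int(experiment.used().sum()) < 8:
        raise ValueError("need at least 8 informative injections")
    from calixtherm.equilibria import Species

    def build_model(x):
        model = BindingModel(
            [ligand, titrant],
            [Species("complex", {ligand: 1, titrant: 1}, float(x[0]))],
        )
        return model, {"complex": float(x[1])}, float(x[2])

    q = experiment.heats[experiment.used()]
    dh0 = np.sum(q) * 1e-6 / (experiment.cell_conc[ligand] * experiment.cell_volume / 1000.0)
    x0 = [5.0, np.clip(dh0, -200, 200), 0.0]
    lo, hi = [-2.0, -500.0, -50.0], [16.0, 500.0, 50.0]
    if float_n:
        x0.append(1.0)
        lo.append(0.2)
        hi.append(5.0)
    x, se, res = _fit_heats(
        experiment, build_model, ligand, titrant, np.array(x0), (lo, hi), float_n
    )
    n = float(x[3]) if float_n else 1.0
    c_value = 10.0 ** x[0] * experiment.cell_conc[ligand] * n
    flagged = c_value > C_VALUE_UNIDENTIFIABLE or se[0] > 1.0
    return ITCFitResult(
        log_k=float(x[0]), log_k_se=float(se[0]),
        delta_h=float(x[1]), delta_h_se=float(se[1]),
        offset=float(x[2]), n_sites=n, c_value=float(c_value),
        residuals=res, k_unidentifiable=bool(flagged),
        message="c-value above 1e4: K not identifiable from isotherm shape" if flagged else "",
    )


def fit_enthalpy_only(
    experiment: ITCExperiment,
    ratio_cutoff: float = 0.8,
    ligand: str = "L",
    titrant: str = "M",
    log_k: float | None = None,
) -> tuple[float, float]:
    """dH (kJ mol^-1) from pre-equivalence injections of a steep isotherm.

    Before the equivalence point of an effectively stoichiometric titration
    every mole of delivered titrant binds, so q_i divided by the moles
    delivered estimates dH directly.  Returns (mean, standard error of the
    mean).  If ``log_k`` is supplied and the implied c-value is low, the
    estimate is biased low and a warning is emitted.
    """
    ratios = cumulative_ratio(experiment, titrant, ligand)
    mask = experiment.used() & (ratios <= ratio_cutoff)
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 pre-equivalence injections")
    if log_k is not None:
        c_value = 10.0 ** log_k * experiment.cell_conc[ligand]
        if c_value < 1e3:
            import warnings

            warnings.warn(
                f"c-value {c_value:.3g} < 1e3: binding not stoichiometric before "
                "equivalence, enthalpy-only estimate biased low",
                stacklevel=2,
            )
    c_tit = experiment.syringe_conc[titrant]
    moles = c_tit * experiment.injection_volumes / 1e6  # mm^3 -> dm^3
    per_mol = experiment.heats[mask] * 1e-6 / moles[mask]  # mJ -> kJ
    n = int(mask.sum())
    return float(np.mean(per_mol)), float(np.std(per_mol, ddof=1) / np.sqrt(n))


def correct_dilution(
    experiment: ITCExperiment,
    blank: "ITCExperiment | float",
) -> ITCExperiment:
    """Subtract titrant dilution heats, per-injection or constant (mJ)."""
    if isinstance(blank, ITCExperiment):
        if len(blank.heats) != experiment.n_injections or not np.allclose(
            blank.injection_volumes, experiment.injection_volumes
        ):
            raise ValueError("blank injection schedule does not match the experiment")
        q = experiment.heats - blank.heats
    else:
        q = experiment.heats - float(blank)
    return replace(experiment, heats=q, dilution_corrected=True)


def fit_competitive_itc(
    experiment: ITCExperiment,
    reference_log_k: float | None,
    reference_delta_h: float | None,
    ligand: str = "L",
    titrant: str = "M",
    reference: str = "Na",
) -> ITCFitResult:
    """Fit (log K, dH) of a strong complex by calorimetric displacement.

    The reference complex's constant and enthalpy (from independent work)
    are held fixed; heats are computed from the concentration changes of
    both complexes.  If the reference cation is absent from the cell the
    problem reduces to the direct 1:1 fit.
    """
    if reference_log_k is None or reference_delta_h is None:
        raise ValueError("competitive ITC fit requires reference logK and dH")
    from calixtherm.equilibria import Species

    ref_present = experiment.cell_conc.get(reference, 0.0) > 0 or \
        experiment.syringe_conc.get(reference, 0.0) > 0

    def build_model(x):
        species = [Species("complex", {ligand: 1, titrant: 1}, float(x[0]))]
        comps = [ligand, titrant]
        dh_map = {"complex": float(x[1])}
        if ref_present:
            comps.append(reference)
            species.append(Species("ref_complex", {ligand: 1, reference: 1}, reference_log_k, fixed=True))
            dh_map["ref_complex"] = reference_delta_h
        return BindingModel(comps, species), dh_map, float(x[2])

    x0 = np.array([reference_log_k + 0.5, reference_delta_h, 0.0])
    bounds = ([-2.0, -500.0, -50.0], [16.0, 500.0, 50.0])
    x, se, res = _fit_heats(experiment, build_model, ligand, titrant, x0, bounds, False)
    c_value = 10.0 ** x[0] * experiment.cell_conc[ligand]
    degenerate = (
        ref_present
        and abs(x[0] - reference_log_k) < 0.05
        and abs(x[1] - reference_delta_h) < 0.5
    ) or se[0] > 1.0
    return ITCFitResult(
        log_k=float(x[0]), log_k_se=float(se[0]),
        delta_h=float(x[1]), delta_h_se=float(se[1]),
        offset=float(x[2]), n_sites=1.0, c_value=float(c_value),
        residuals=res, k_unidentifiable=bool(se[0] > 1.0),
        degenerate=bool(degenerate),
        message="degenerate: free and reference parameters indistinguishable" if degenerate else "",
    )
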