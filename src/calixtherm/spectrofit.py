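"""Global fitting of stability constants to multiwavelength titration data.

The engine is variable projection: for a trial value of the free log10
stability constant(s) the species concentrations along the titration follow
from the equilibrium model, the molar responses (Beer-Lambert epsilon for
absorbance, emission coefficients for fluorescence) are the conditionally
optimal linear-least-squares solution, and the outer optimiser minimises
the Frobenius norm of the residual matrix over the constants alone.
Competitive titrations use the same engine with the reference complex's
constant held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar, nnls

from calixtherm.equilibria import BindingModel, TitrationSeries, speciation_profile

__all__ = [
    "SpectralDataset",
    "SpectralFitResult",
    "dilution_correct",
    "fit_direct",
    "fit_competitive",
    "subtract_blank_overlap",
    "UnidentifiableError",
]

LOGK_BOUNDS = (-2.0, 16.0)


class UnidentifiableError(ValueError):
    """Raised when the data carry no information on the free constant."""


@dataclass
class SpectralDataset:
    """A titration's response matrix (points x wavelengths) plus metadata.

    ``kind`` is ``absorbance`` or ``fluorescence``; ``path_length`` (cm)
    applies to absorbance, ``excitation_nm`` to fluorescence.
    """

    kind: str
    wavelengths: np.ndarray
    responses: np.ndarray
    series: TitrationSeries
    path_length: float = 1.0
    excitation_nm: float | None = None
    dilution_corrected: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.kind not in ("absorbance", "fluorescence"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.responses.shape != (self.series.n_points, len(self.wavelengths)):
            raise ValueError(
                f"response matrix shape {self.responses.shape} does not match "
                f"({self.series.n_points}, {len(self.wavelengths)})"
            )
        if self.kind == "absorbance" and self.path_length <= 0:
            raise ValueError("path length must be positive")


def dilution_correct(dataset: SpectralDataset) -> SpectralDataset:
    """Rescale each titration point's responses back to the initial volume.

    Multiplies point i by (V0 + V_i)/V0 so that signal changes reflect
    speciation only.  Idempotent guard: a second call raises.
    """
    if dataset.dilution_corrected:
        raise ValueError("dataset already dilution-corrected")
    factors = (dataset.series.v0 + dataset.series.volumes) / dataset.series.v0
    return replace(
        dataset,
        responses=dataset.responses * factors[:, None],
        dilution_corrected=True,
    )


@dataclass
class SpectralFitResult:
    """Fitted constants, conditionally optimal molar spectra, diagnostics."""

    log_betas: dict[str, float]
    std_errors: dict[str, float]
    species_names: list[str]
    molar_spectra: np.ndarray  # (n_colored_species, n_wavelengths)
    residuals: np.ndarray
    ssq: float
    converged: bool
    unidentifiable: bool
    message: str = ""
    model: BindingModel | None = field(default=None, repr=False)


def _colored_species(model: BindingModel, ligand: str) -> tuple[list[str], np.ndarray]:
    """Names and concentration-column indices of chromophoric states.

    Everything containing the ligand absorbs/emits: the free ligand plus
    every complex with a non-zero ligand stoichiometry.
    """
    names = [ligand]
    cols = [model.components.index(ligand)]
    n_comp = len(model.components)
    for j, sp in enumerate(model.species):
        if sp.stoich.get(ligand, 0) > 0:
            names.append(sp.name)
            cols.append(n_comp + j)
    return names, np.array(cols)


def _project_spectra(
    conc: np.ndarray, data: np.ndarray, scale: float, nonneg: bool
) -> tuple[np.ndarray, float]:
    """Conditionally optimal molar spectra and residual SSQ for fixed
    concentrations (the linear half of variable projection)."""
    c = conc * scale
    if nonneg:
        eps = np.empty((conc.shape[1], data.shape[1]))
        for k in range(data.shape[1]):
            eps[:, k], _ = nnls(c, data[:, k])
    else:
        eps, *_ = np.linalg.lstsq(c, data, rcond=None)
    resid = data - c @ eps
    return eps, float(np.sum(resid * resid))


def _fit_engine(
    dataset: SpectralDataset,
    model: BindingModel,
    ligand: str,
    nonneg: bool,
    fixed_ligand_spectrum: np.ndarray | None,
) -> SpectralFitResult:
    free = model.free_species()
    if not free:
        raise ValueError("model has no free (adjustable) constants")
    names, cols = _colored_species(model, ligand)
    data = dataset.responses
    scale = dataset.path_length if dataset.kind == "absorbance" else 1.0

    if fixed_ligand_spectrum is not None:
        fixed_ligand_spectrum = np.asarray(fixed_ligand_spectrum, dtype=float)
        if fixed_ligand_spectrum.shape != (data.shape[1],):
            raise ValueError("fixed ligand spectrum does not match the wavelength grid")

    def ssq_at(theta: np.ndarray) -> float:
        m = model
        for sp, lb in zip(free, theta):
            m = m.with_log_beta(sp.name, float(lb))
        prof = speciation_profile(m, dataset.series)
        conc = prof[:, cols]
        if fixed_ligand_spectrum is None:
            _, ssq = _project_spectra(conc, data, scale, nonneg)
        else:
            reduced = data - np.outer(conc[:, 0] * scale, fixed_ligand_spectrum)
            _, ssq = _project_spectra(conc[:, 1:], reduced, scale, nonneg)
        return ssq

    if len(free) == 1:
        # coarse grid to bracket the optimum (the profile can be flat over
        # decades in the steep-isotherm regime), then bounded refinement
        grid = np.arange(LOGK_BOUNDS[0], LOGK_BOUNDS[1] + 0.25, 0.5)
        vals = np.array([ssq_at(np.array([g])) for g in grid])
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: ssq_at(np.array([t])), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        theta_hat = np.array([res.x])
        converged = bool(res.success)
    else:
        x0 = np.array([sp.log_beta for sp in free])
        res = minimize(ssq_at, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-14})
        theta_hat = np.clip(res.x, *LOGK_BOUNDS)
        converged = bool(res.success)

    # final linear solve at the optimum
    m_hat = model
    for sp, lb in zip(free, theta_hat):
        m_hat = m_hat.with_log_beta(sp.name, float(lb))
    prof = speciation_profile(m_hat, dataset.series)
    conc = prof[:, cols]
    if fixed_ligand_spectrum is None:
        eps, ssq = _project_spectra(conc, data, scale, nonneg)
    else:
        reduced = data - np.outer(conc[:, 0] * scale, fixed_ligand_spectrum)
        eps_rest, ssq = _project_spectra(conc[:, 1:], reduced, scale, nonneg)
        eps = np.vstack([fixed_ligand_spectrum, eps_rest])
    resid = data - (conc * scale) @ eps

    # SE from the curvature of the SSQ profile in each free constant
    dof = max(data.size - len(free) - eps.size, 1)
    sigma2 = ssq / dof
    ses = {}
    unident = False
    for i, sp in enumerate(free):
        h = 0.05
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i] += h
        tm[i] -= h
        d2 = (ssq_at(tp) - 2.0 * ssq + ssq_at(tm)) / (h * h)
        if d2 <= 0 or not np.isfinite(d2):
            ses[sp.name] = np.inf
            unident = True
        else:
            se = float(np.sqrt(2.0 * sigma2 / d2))
            ses[sp.name] = se
            if se > 1.0:
                unident = True
        # flat-tail profile check: when the SSQ at a search bound is within
        # the 95% likelihood-ratio band of the minimum, the constant is
        # statistically indistinguishable from that bound (steep-isotherm
        # regime) no matter what the local curvature says.
        if sigma2 > 0 and not unident:
            for bound in LOGK_BOUNDS:
                if abs(bound - theta_hat[i]) <= 1.0:
                    continue
                tq = theta_hat.copy()
                tq[i] = bound
                if ssq_at(tq) - ssq < 3.84 * sigma2:
                    unident = True
                    ses[sp.name] = max(ses[sp.name], 1.0 + 1e-9)
                    break

    return SpectralFitResult(
        log_betas={sp.name: float(t) for sp, t in zip(free, theta_hat)},
        std_errors=ses,
        species_names=names,
        molar_spectra=eps,
        residuals=resid,
        ssq=ssq,
        converged=converged,
        unidentifiable=unident,
        message="SE exceeds 1 log unit" if unident else "",
        model=m_hat,
    )


def fit_direct(
    dataset: SpectralDataset,
    model: BindingModel,
    ligand: str = "L",
    nonneg: bool = True,
    fixed_ligand_spectrum: np.ndarray | None = None,
) -> SpectralFitResult:
    """Fit the free stability constant(s) to a direct titration.

    Requires a dilution-corrected dataset.  The identifiability flag is set
    when the profile-curvature standard error of any free constant exceeds
    one log unit — the regime where the titration curve is an
    indistinguishable linear-then-plateau break for all sufficiently large
    constants.
    """
    if not dataset.dilution_corrected:
        raise ValueError("dataset must be dilution-corrected before fitting")
    # ligand-only guard: no complex can form if every species needs an
    # absent partner
    for sp in model.species:
        partners = [c for c in sp.stoich if c != ligand and sp.stoich[c] > 0]
        if partners and any(np.any(dataset.series.total(p) > 0) for p in partners if p in dataset.series.components):
            break
    else:
        raise UnidentifiableError("no complex forms anywhere in the titration")
    return _fit_engine(dataset, model, ligand, nonneg, fixed_ligand_spectrum)


def fit_competitive(
    dataset: SpectralDataset,
    model: BindingModel,
    ligand: str = "L",
    reference_component: str = "Na",
    nonneg: bool = True,
) -> SpectralFitResult:
    """Fit a high constant by displacement of a fixed reference complex.

    The model must mark the reference complex (e.g. the Na+ complex with
    log K = 10.50) as fixed; the competing cation must actually be
    titrated in, otherwise there is no displacement information.
    """
    if not dataset.dilution_corrected:
        raise ValueError("dataset must be dilution-corrected before fitting")
    if not any(sp.fixed for sp in model.species):
        raise ValueError("competitive fit requires a fixed reference constant")
    if reference_component not in dataset.series.components or not np.any(
        dataset.series.total(reference_component) > 0
    ):
        raise ValueError("reference cation absent from the cell solution")
    free = model.free_species()
    competing = {c for sp in free for c in sp.stoich if c not in (ligand, reference_component)}
    if not any(np.any(dataset.series.total(c) > 0) for c in competing if c in dataset.series.components):
        raise UnidentifiableError("titrant contains no competing cation: no information on the free constant")
    return _fit_engine(dataset, model, ligand, nonneg, None)


def subtract_blank_overlap(
    dataset: SpectralDataset,
    blank: np.ndarray,
    window: tuple[float, float] | None = None,
) -> SpectralDataset:
    """Remove a scaled blank/scatter band from fluorescence spectra.

    The blank (e.g. excitation-emission overlap of the free ligand) is
    scaled by least squares against each titration point within the
    declared wavelength window, then subtracted across the full grid.
    """
    blank = np.asarray(blank, dtype=float)
    if blank.shape != (len(dataset.wavelengths),):
        raise ValueError("blank wavelength grid does not match the dataset")
    if window is None:
        mask = np.ones(len(dataset.wavelengths), dtype=bool)
    else:
        mask = (dataset.wavelengths >= window[0]) & (dataset.wavelengths <= window[1])
        if not mask.any():
            raise ValueError("overlap window contains no grid points")
    denom = float(blank[mask] @ blank[mask])
    if denom == 0.0:
        return replace(dataset, responses=dataset.responses.copy())
    scales = dataset.responses[:, mask] @ blank[mask] / denom
    return replace(dataset, responses=dataset.responses - np.outer(scales, blank))
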