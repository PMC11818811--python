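"""Synthetic datasets with known ground truth for every pipeline stage.

The generators emulate the study's experimental conditions: UV titrations
of ~1e-4 mol dm^-3 ligand in a 2.2 cm^3 cuvette whose complex band is
red-shifted and intensified relative to the free ligand (bathochromic +
hyperchromic response), ITC displacement-cell thermograms with constant
dilution offsets and additive noise, and role-labelled trajectories with
prescribed coordination templates and cavity-occupancy schedules.  Every
generator is seeded and serialises its ground truth next to the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from calixtherm.equilibria import (
    BindingModel,
    Species,
    TitrationSeries,
    build_titration_series,
    speciation_profile,
)
from calixtherm.itcfit import ITCExperiment, simulate_itc
from calixtherm.mdcoord import EMPTY, HEAD_IN, TAIL_IN, Frame, LabeledTrajectory
from calixtherm.spectrofit import SpectralDataset

__all__ = [
    "GroundTruth",
    "default_uv_protocol",
    "gen_titration_spectra",
    "gen_itc",
    "gen_trajectory",
]


@dataclass
class GroundTruth:
    """Serialisable record of the parameters a generator drew from."""

    seed: int | None
    log_betas: dict[str, float] = field(default_factory=dict)
    band_params: dict = field(default_factory=dict)
    delta_h: dict[str, float] = field(default_factory=dict)
    offset: float = 0.0
    noise_sd: float = 0.0
    schedule: list = field(default_factory=list)
    exchanges: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def default_uv_protocol(
    c_ligand: float = 1.2e-4,
    c_titrant: float = 1.31e-3,
    v0: float = 2.2,
    n_points: int = 16,
    max_ratio: float = 2.0,
    titrant: str = "M",
    extra_cell: dict[str, float] | None = None,
) -> TitrationSeries:
    """Cuvette titration schedule reaching ``max_ratio`` equivalents.

    Defaults mirror a typical UV experiment: 1.2e-4 mol dm^-3 ligand in
    2.2 cm^3 titrated with a ~10x more concentrated cation solution.
    """
    # choose cumulative volumes giving approximately uniform ratio steps
    n_l0 = c_ligand * v0
    vols = []
    for r in np.linspace(max_ratio / n_points, max_ratio, n_points):
        # r = c_tit*V/(c_L0*V0) (ratio of totals is volume-independent)
        vols.append(r * n_l0 / c_titrant)
    cell = {"L": c_ligand, **(extra_cell or {})}
    return build_titration_series(cell, v0, {titrant: c_titrant}, vols, mode="cuvette")


def _gaussian_bands(grid: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, width, height in bands:
        out = out + height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def gen_titration_spectra(
    model: BindingModel,
    series: TitrationSeries,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wavelengths: np.ndarray | None = None,
    ligand: str = "L",
    band_shift: float = 10.0,
    hyperchromic: float = 1.35,
    kind: str = "absorbance",
    species_response: dict[str, tuple[float, float]] | None = None,
) -> tuple[SpectralDataset, GroundTruth]:
    """Simulate a multiwavelength titration with known constants.

    The free ligand's molar spectrum is a sum of Gaussian bands; each
    complex inherits the same bands red-shifted and intensified
    (bathochromic + hyperchromic response).  By default the first complex
    shifts by ``band_shift`` nm scaled by ``hyperchromic`` and later
    complexes get progressively smaller shifts, so that competing species
    remain spectrally distinguishable (as they must be for a competitive
    determination to work); ``species_response`` overrides the
    ``(shift_nm, intensity_factor)`` pair per species.  Responses follow
    Beer-Lambert from the equilibrium speciation along the series, plus
    homoscedastic Gaussian noise of standard deviation ``noise_sd``
    (absolute response units).
    """
    if noise_sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if wavelengths is None:
        wavelengths = np.arange(300.0, 401.0, 2.0)
    ligand_bands = [(330.0, 12.0, 14000.0), (357.0, 9.0, 9000.0)]

    names = [ligand] + [sp.name for sp in model.species if sp.stoich.get(ligand, 0) > 0]
    response: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(names[1:]):
        fade = 0.55**j  # later complexes: smaller shift, weaker gain
        response[name] = (band_shift * fade, 1.0 + (hyperchromic - 1.0) * fade)
    response.update(species_response or {})

    lo, hi = wavelengths[0], wavelengths[-1]
    for c, _, _ in ligand_bands:
        shifts = [0.0] + [response[n][0] for n in names[1:]]
        if any(not (lo <= c + s <= hi) for s in shifts):
            raise ValueError("spectral bands fall outside the wavelength grid")

    eps = np.zeros((len(names), len(wavelengths)))
    eps[0] = _gaussian_bands(wavelengths, ligand_bands)
    for j, name in enumerate(names[1:], start=1):
        shift, gain = response[name]
        eps[j] = _gaussian_bands(wavelengths, [(c + shift, w, h * gain) for c, w, h in ligand_bands])

    prof = speciation_profile(model, series)
    cols = [model.components.index(ligand)] + [
        len(model.components) + j
        for j, sp in enumerate(model.species)
        if sp.stoich.get(ligand, 0) > 0
    ]
    conc = prof[:, cols]
    responses = conc @ eps  # path length 1 cm
    if noise_sd > 0:
        responses = responses + np.random.default_rng(seed).normal(0.0, noise_sd, responses.shape)

    dataset = SpectralDataset(
        kind=kind,
        wavelengths=wavelengths,
        responses=responses,
        series=series,
        path_length=1.0,
        dilution_corrected=True,  # simulated at speciation concentrations
    )
    truth = GroundTruth(
        seed=seed,
        log_betas={sp.name: sp.log_beta for sp in model.species},
        band_params={
            "ligand_bands": ligand_bands,
            "species_response": {k: list(v) for k, v in response.items()},
        },
        noise_sd=noise_sd,
    )
    return dataset, truth


def gen_itc(
    model: BindingModel,
    experiment: ITCExperiment,
    delta_h: dict[str, float],
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ITCExperiment, GroundTruth]:
    """Simulated ITC thermogram plus its ground truth (delegates to the
    calorimetry forward model)."""
    sim = simulate_itc(model, experiment, delta_h, offset=offset, noise_sd=noise_sd, seed=seed)
    truth = GroundTruth(
        seed=seed,
        log_betas={sp.name: sp.log_beta for sp in model.species},
        delta_h=dict(delta_h),
        offset=offset,
        noise_sd=noise_sd,
    )
    return sim, truth


# coordination template: distances (Angstrom) from the cation
DEFAULT_TEMPLATE = {
    "O_ether": 2.4,
    "O_carbonyl": 2.4,
    "N_phen": 2.6,
    "head_in_head": 2.8,  # occupant head when HEAD_IN
    "head_in_tail": 4.3,
    "tail_in_tail": 2.8,
    "tail_in_head": 4.3,
}


def gen_trajectory(
    schedule: list[tuple[str, str | None]],
    template: dict[str, float] | None = None,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    cation_element: str = "Ca",
    solvent: str = "MeCN",
    nphen_contact: "list[bool] | None" = None,
) -> tuple[LabeledTrajectory, GroundTruth]:
    """Build a labelled trajectory realising a cavity-occupancy schedule.

    ``schedule`` is one (state, occupant-id) pair per frame with state in
    {EMPTY, HEAD_IN, TAIL_IN}.  Donor atoms sit at template distances from
    the cation with Gaussian jitter; the occupant solvent molecule is
    placed inside the aromatic cone (the side of the ether-oxygen plane
    away from the cation) with its head or tail towards the cation as the
    state dictates; all other solvent molecules are parked far outside the
    cavity.  ``nphen_contact`` optionally pushes the phenanthridine
    nitrogens out of the first shell in selected frames (False = out).
    """
    tpl = {**DEFAULT_TEMPLATE, **(template or {})}
    for state, _ in schedule:
        if state not in (EMPTY, HEAD_IN, TAIL_IN):
            raise ValueError(f"invalid state label {state!r}")
    if nphen_contact is not None and len(nphen_contact) != len(schedule):
        raise ValueError("nphen_contact length must match the schedule")
    rng = np.random.default_rng(seed)

    solvent_ids = sorted({occ for _, occ in schedule if occ is not None})
    if not solvent_ids:
        solvent_ids = ["SOLV1"]
    head_el = "N" if solvent == "MeCN" else "O"

    # static geometry: ether-O plane at z=0, cation below it at z=-h
    r_e = tpl["O_ether"]
    h = 0.8  # cation depth below the ether plane
    rho = float(np.sqrt(max(r_e**2 - h**2, 0.25)))
    ether_xy = [(rho, 0.0), (0.0, rho), (-rho, 0.0), (0.0, -rho)]

    elements: list[str] = [cation_element]
    roles: list[str] = ["cation"]
    mol_ids: list[str] = ["CAT"]
    base: list[np.ndarray] = [np.array([0.0, 0.0, -h])]

    for x, y in ether_xy:
        elements.append("O"); roles.append("O_ether"); mol_ids.append("LIG")
        base.append(np.array([x, y, 0.0]))
    # carbonyl oxygens flank the cation below the plane; their carbons 1.23 A further out
    cat = np.array([0.0, 0.0, -h])
    for sgn in (+1.0, -1.0):
        direction = np.array([sgn, 0.0, -0.6])
        direction /= np.linalg.norm(direction)
        o_pos = cat + tpl["O_carbonyl"] * direction
        c_pos = o_pos + 1.23 * direction
        elements.append("O"); roles.append("O_carbonyl"); mol_ids.append("LIG")
        base.append(o_pos)
        elements.append("C"); roles.append("other"); mol_ids.append("LIG")
        base.append(c_pos)
    nphen_dirs = []
    for sgn in (+1.0, -1.0):
        direction = np.array([0.0, sgn, -0.5])
        direction /= np.linalg.norm(direction)
        nphen_dirs.append(direction)
        elements.append("N"); roles.append("N_phen"); mol_ids.append("LIG")
        base.append(cat + tpl["N_phen"] * direction)
    nphen_at = [len(base) - 2, len(base) - 1]

    solvent_slots: dict[str, tuple[int, int]] = {}
    for k, sid in enumerate(solvent_ids):
        elements.append(head_el); roles.append("solvent_head"); mol_ids.append(sid)
        base.append(np.array([14.0 + 4.0 * k, 0.0, 5.0]))
        elements.append("C"); roles.append("solvent_tail"); mol_ids.append(sid)
        base.append(np.array([14.0 + 4.0 * k, 0.0, 6.4]))
        solvent_slots[sid] = (len(base) - 2, len(base) - 1)

    base_arr = np.array(base)
    axis = np.array([0.0, 0.0, 1.0])  # cavity axis, cone side = +z
    frames = []
    for f, (state, occ) in enumerate(schedule):
        coords = base_arr + (rng.normal(0.0, jitter_sd, base_arr.shape) if jitter_sd > 0 else 0.0)
        if nphen_contact is not None and not nphen_contact[f]:
            for i, direction in zip(nphen_at, nphen_dirs):
                coords[i] = cat + 4.5 * direction  # outside the 3 A shell
        if state != EMPTY:
            ih, it = solvent_slots[occ]
            d_near = tpl["head_in_head"] if state == HEAD_IN else tpl["tail_in_tail"]
            d_far = tpl["head_in_tail"] if state == HEAD_IN else tpl["tail_in_head"]
            near = cat + d_near * axis
            far = cat + d_far * axis
            jn = rng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else 0.0
            jf = rng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else 0.0
            if state == HEAD_IN:
                coords[ih], coords[it] = near + jn, far + jf
            else:
                coords[it], coords[ih] = near + jn, far + jf
        frames.append(Frame(coords=coords, time_ps=float(f)))

    traj = LabeledTrajectory(elements, roles, mol_ids, frames)
    occ_seq = [o for _, o in schedule if o is not None]
    exchanges = sum(1 for a, b in zip(occ_seq, occ_seq[1:]) if a != b)
    truth = GroundTruth(
        seed=seed,
        schedule=[list(s) for s in schedule],
        exchanges=exchanges,
        noise_sd=jitter_sd,
    )
    return traj, truth


def make_1to1_model(log_k: float, ligand: str = "L", cation: str = "M") -> BindingModel:
    """Convenience: L + M <-> ML with the given log10 K."""
    return BindingModel([ligand, cation], [Species("ML", {ligand: 1, cation: 1}, log_k)])


def make_competitive_model(
    log_k_free: float,
    log_k_ref: float = 10.50,
    ligand: str = "L",
    cation: str = "M",
    reference: str = "Na",
) -> BindingModel:
    """L + M <-> ML (free) competing with L + Na <-> NaL (fixed)."""
    return BindingModel(
        [ligand, cation, reference],
        [
            Species("ML", {ligand: 1, cation: 1}, log_k_free),
            Species("NaL", {ligand: 1, reference: 1}, log_k_ref, fixed=True),
        ],
    )
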