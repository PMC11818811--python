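"""Post-processing of role-labelled MD trajectories of cation-macrocycle
complexes.

Atoms carry role tags (cation, ether/carbonyl oxygens, phenanthridine
nitrogens, solvent head/tail atoms) so the analysis is force-field and
engine agnostic: first-shell coordination counts, classification of the
solvent-inclusion state of the hydrophobic cavity (empty / head-in /
tail-in) with exchange counting, a per-frame coordination matrix reduced
by PCA and clustered to pick representative frames, and total-least-squares
plane geometry for distance reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOM_MASSES",
    "ROLES",
    "Frame",
    "LabeledTrajectory",
    "CoordinationMatrix",
    "InclusionTimeline",
    "PlaneFit",
    "coordination_series",
    "classify_inclusion",
    "count_exchanges",
    "build_coordination_matrix",
    "pca_cluster_representatives",
    "fit_plane",
    "geometry_report",
]

ROLES = ("cation", "O_ether", "O_carbonyl", "N_phen", "solvent_head", "solvent_tail", "other")

# enough of the periodic table for these systems (amu)
ATOM_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "Na": 22.990, "Mg": 24.305, "Ca": 40.078, "Sr": 87.62, "Ba": 137.327,
}

DEFAULT_ROLE_COUNTS = {"O_ether": 4, "O_carbonyl": 2, "N_phen": 2}
DEFAULT_CUTOFF = 3.0  # Angstrom, first-shell donor-cation contact
DEFAULT_CAVITY_DISTANCE = 7.5  # Angstrom, occupant atoms from cation


@dataclass
class Frame:
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    time_ps: float = 0.0


@dataclass
class LabeledTrajectory:
    """Frames of role-tagged coordinates; roles constant across frames."""

    elements: list[str]
    roles: list[str]
    mol_ids: list[str]
    frames: list[Frame]
    box: np.ndarray | None = None
    role_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROLE_COUNTS))

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not (len(self.roles) == len(self.mol_ids) == n):
            raise ValueError("elements, roles, mol_ids length mismatch")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        for fr in self.frames:
            fr.coords = np.asarray(fr.coords, dtype=float)
            if fr.coords.shape != (n, 3):
                raise ValueError("frame coordinate shape mismatch")
        if self.roles.count("cation") != 1:
            raise ValueError("exactly one cation required")
        for role, count in self.role_counts.items():
            if self.roles.count(role) != count:
                raise ValueError(f"expected {count} atoms with role {role}, got {self.roles.count(role)}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def cation_index(self) -> int:
        return self.roles.index("cation")

    def solvent_molecules(self) -> list[str]:
        """Molecule ids that carry solvent head/tail tags."""
        ids = []
        for i, r in enumerate(self.roles):
            if r in ("solvent_head", "solvent_tail") and self.mol_ids[i] not in ids:
                ids.append(self.mol_ids[i])
        return ids


def _block_se(x: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean by block averaging (serial correlation)."""
    n = len(x)
    if n < n_blocks * 2:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    m = n // n_blocks
    means = np.array([x[i * m : (i + 1) * m].mean() for i in range(n_blocks)])
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))


def coordination_series(
    traj: LabeledTrajectory,
    cutoffs: dict[str, float] | None = None,
) -> dict:
    """First-shell coordination counts of the cation per donor class.

    A donor coordinates when its distance to the cation is within the
    class cutoff (default 3.0 A).  Returns per-frame counts and
    time-averages with block-averaged standard errors.
    """
    cutoffs = {**{r: DEFAULT_CUTOFF for r in ("O_ether", "O_carbonyl", "N_phen")}, **(cutoffs or {})}
    if any(v <= 0 for v in cutoffs.values()):
        raise ValueError("cutoffs must be positive")
    ic = traj.cation_index()
    out: dict = {"counts": {}, "mean": {}, "se": {}}
    for role, cut in cutoffs.items():
        idx = traj.indices(role)
        if idx.size == 0:
            raise ValueError(f"no atoms with role {role}")
        counts = np.empty(traj.n_frames)
        for f, fr in enumerate(traj.frames):
            d = np.linalg.norm(fr.coords[idx] - fr.coords[ic], axis=1)
            counts[f] = int(np.sum(d <= cut))
        out["counts"][role] = counts
        out["mean"][role] = float(counts.mean())
        out["se"][role] = _block_se(counts)
    return out


@dataclass
class PlaneFit:
    """Total-least-squares plane: centroid + unit normal, oriented so the
    reference point (the cation) sits on the positive side."""

    normal: np.ndarray
    centroid: np.ndarray
    rms: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.centroid) @ self.normal

    def distance(self, point: np.ndarray) -> float:
        return float(abs(self.signed_distance(point)[0]))


def fit_plane(points: np.ndarray, orient_toward: np.ndarray | None = None) -> PlaneFit:
    """Orthogonal-regression (total-least-squares) plane through >= 3 points.

    The normal is the smallest principal direction of the centred points;
    perpendicular (not vertical) deviations are minimised.  Collinear
    point sets are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("points are collinear: plane undefined")
    normal = vt[-1]
    if orient_toward is not None and float((np.asarray(orient_toward) - centroid) @ normal) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(normal=normal, centroid=centroid, rms=rms)


EMPTY, HEAD_IN, TAIL_IN = "EMPTY", "HEAD_IN", "TAIL_IN"


@dataclass
class InclusionTimeline:
    """Per-frame cavity occupancy state and occupant identity."""

    states: list[str]
    occupants: list[str | None]

    def fractions(self) -> dict[str, float]:
        n = len(self.states)
        return {s: self.states.count(s) / n for s in (EMPTY, HEAD_IN, TAIL_IN)}

    def distinct_occupants(self) -> list[str]:
        seen = []
        for o in self.occupants:
            if o is not None and o not in seen:
                seen.append(o)
        return seen


def classify_inclusion(
    traj: LabeledTrajectory,
    max_distance: float = DEFAULT_CAVITY_DISTANCE,
) -> InclusionTimeline:
    """Classify the cavity occupancy of every frame.

    A solvent molecule occupies the cavity when both its tagged atoms lie
    within ``max_distance`` of the cation and on the aromatic-cone side of
    the ether-oxygen plane (the side opposite the cation).  Orientation is
    HEAD_IN when the head atom is nearer the cation than the tail,
    TAIL_IN otherwise; exact ties resolve to TAIL_IN with a warning.
    With several simultaneous candidates the nearest is kept and the event
    reported as a warning.
    """
    ic = traj.cation_index()
    ether = traj.indices("O_ether")
    solvents = traj.solvent_molecules()
    head_idx = {m: None for m in solvents}
    tail_idx = {m: None for m in solvents}
    for i, r in enumerate(traj.roles):
        if r == "solvent_head":
            head_idx[traj.mol_ids[i]] = i
        elif r == "solvent_tail":
            tail_idx[traj.mol_ids[i]] = i
    for m in solvents:
        if head_idx[m] is None or tail_idx[m] is None:
            raise ValueError(f"solvent molecule {m} missing a head or tail tag")

    states: list[str] = []
    occupants: list[str | None] = []
    for fr in traj.frames:
        cat = fr.coords[ic]
        plane = fit_plane(fr.coords[ether], orient_toward=cat)
        candidates = []
        for m in solvents:
            h, t = fr.coords[head_idx[m]], fr.coords[tail_idx[m]]
            dh = float(np.linalg.norm(h - cat))
            dt = float(np.linalg.norm(t - cat))
            if dh > max_distance or dt > max_distance:
                continue
            # cone side = opposite the cation across the ether-O plane
            if plane.signed_distance(h)[0] >= 0 or plane.signed_distance(t)[0] >= 0:
                continue
            candidates.append((min(dh, dt), m, dh, dt))
        if not candidates:
            states.append(EMPTY)
            occupants.append(None)
            continue
        if len(candidates) > 1:
            warnings.warn("multiple simultaneous cavity occupants; keeping the nearest", stacklevel=2)
        _, m, dh, dt = min(candidates)
        if dh == dt:
            warnings.warn("head and tail equidistant from cation; classifying TAIL_IN", stacklevel=2)
        states.append(HEAD_IN if dh < dt else TAIL_IN)
        occupants.append(m)
    return InclusionTimeline(states, occupants)


def count_exchanges(timeline: InclusionTimeline) -> tuple[int, int]:
    """(distinct occupants, exchange events).

    An exchange is a change of occupant identity between successive
    occupied stretches; EMPTY gaps are bridged, so A, EMPTY, A counts no
    exchange.
    """
    if not timeline.states:
        raise ValueError("empty timeline")
    occ = [o for o in timeline.occupants if o is not None]
    exchanges = sum(1 for a, b in zip(occ, occ[1:]) if a != b)
    return len(timeline.distinct_occupants()), exchanges


@dataclass
class CoordinationMatrix:
    """Per-frame cation coordination descriptors.

    Columns, in order: the 2 cation-carbonyl-O distances, the 4
    cation-ether-O distances, the 2 cation-phenanthridine-N distances and
    the 2 carbonyl angles (vertex at the carbonyl carbon, between the C=O
    bond vector and the C->cation vector), labelled accordingly.
    """

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.labels):
            raise ValueError("column count does not match labels")


def _carbonyl_carbons(traj: LabeledTrajectory, frame: Frame) -> list[int]:
    """Carbonyl carbon = nearest carbon-like 'other' atom to each
    carbonyl oxygen within bonding range in the ligand molecule."""
    carb_o = traj.indices("O_carbonyl")
    others = [i for i, r in enumerate(traj.roles) if r == "other" and traj.elements[i] == "C"]
    if not others:
        raise ValueError("no carbon atoms with role 'other': cannot define carbonyl angles")
    out = []
    for io in carb_o:
        cands = [i for i in others if traj.mol_ids[i] == traj.mol_ids[io]]
        if not cands:
            cands = others
        d = np.linalg.norm(frame.coords[cands] - frame.coords[io], axis=1)
        j = int(np.argmin(d))
        if d[j] > 2.0:
            raise ValueError("no carbon within bonding range of a carbonyl oxygen")
        out.append(cands[j])
    return out


def build_coordination_matrix(traj: LabeledTrajectory) -> CoordinationMatrix:
    """Distances and carbonyl angles per frame (columns as documented on
    :class:`CoordinationMatrix`); invariant under rigid motions."""
    ic = traj.cation_index()
    carb = traj.indices("O_carbonyl")
    ether = traj.indices("O_ether")
    nphen = traj.indices("N_phen")
    labels = (
        [f"d(cation-O_carbonyl{i+1})" for i in range(len(carb))]
        + [f"d(cation-O_ether{i+1})" for i in range(len(ether))]
        + [f"d(cation-N_phen{i+1})" for i in range(len(nphen))]
        + [f"angle(carbonyl{i+1})" for i in range(len(carb))]
    )
    rows = np.empty((traj.n_frames, len(labels)))
    for f, fr in enumerate(traj.frames):
        cat = fr.coords[ic]
        cc = _carbonyl_carbons(traj, fr)
        d_carb = np.linalg.norm(fr.coords[carb] - cat, axis=1)
        d_eth = np.linalg.norm(fr.coords[ether] - cat, axis=1)
        d_n = np.linalg.norm(fr.coords[nphen] - cat, axis=1)
        angles = []
        for io, icarbon in zip(carb, cc):
            v_co = fr.coords[io] - fr.coords[icarbon]
            v_cm = cat - fr.coords[icarbon]
            cosang = float(v_co @ v_cm / (np.linalg.norm(v_co) * np.linalg.norm(v_cm)))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        rows[f] = np.concatenate([d_carb, d_eth, d_n, angles])
    return CoordinationMatrix(rows, labels)


def pca_scores(matrix: CoordinationMatrix, n_components: int = 2) -> np.ndarray:
    """Column-centred PCA scores via singular value decomposition."""
    x = matrix.values - matrix.values.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


def pca_cluster_representatives(
    matrix: CoordinationMatrix,
    k_range: range = range(1, 7),
    seed: int = 0,
) -> dict:
    """Representative frames from k-means clustering of the first two
    principal-component scores of the coordination matrix.

    k is chosen by the silhouette score over ``k_range`` (k=1 scores 0;
    ties resolve to the smaller k).  Each cluster's representative is the
    frame nearest its centroid in PC space; clusters are reported in
    descending population order.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if matrix.values.shape[0] < 10:
        raise ValueError("need at least 10 frames")
    if np.allclose(matrix.values.var(axis=0), 0.0):
        # all frames identical: a single cluster represented by frame 0
        n = matrix.values.shape[0]
        return {"k": 1, "representatives": [0], "populations": [n], "labels": np.zeros(n, dtype=int), "scores": pca_scores(matrix)}
    scores = pca_scores(matrix, 2)
    best = (0, -np.inf, None, None)  # k, silhouette, labels, centers
    for k in k_range:
        if k < 1 or k >= len(scores):
            continue
        if k == 1:
            sil, labels, centers = 0.0, np.zeros(len(scores), dtype=int), scores.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(scores)
            labels, centers = km.labels_, km.cluster_centers_
            if len(np.unique(labels)) < k:
                continue
            sil = float(silhouette_score(scores, labels))
        if sil > best[1] + 1e-12:  # strict improvement: ties keep smaller k
            best = (k, sil, labels, centers)
    k, _, labels, centers = best
    pops = np.array([int(np.sum(labels == j)) for j in range(k)])
    order = np.argsort(-pops, kind="stable")
    reps, out_pops = [], []
    for j in order:
        members = np.where(labels == j)[0]
        d = np.linalg.norm(scores[members] - centers[j], axis=1)
        reps.append(int(members[np.argmin(d)]))
        out_pops.append(int(pops[j]))
    return {"k": k, "representatives": reps, "populations": out_pops, "labels": labels, "scores": scores}


def _center_of_mass(coords: np.ndarray, elements: list[str]) -> np.ndarray:
    masses = np.array([ATOM_MASSES[e] for e in elements])
    return masses @ coords / masses.sum()


def geometry_report(
    traj: LabeledTrajectory,
    frame: int = 0,
    solvent_mol: str | None = None,
) -> dict:
    """Distance report for one frame, in the published-table convention.

    Unsigned orthogonal distances from the ether-oxygen total-least-squares
    plane to the cation and to the solvent centre of mass, plus the
    cation-solvent distance; the triangle inequality
    |d(plane,solvent) - d(plane,cation)| <= d(cation,solvent) is checked
    and reported.
    """
    fr = traj.frames[frame]
    ic = traj.cation_index()
    plane = fit_plane(fr.coords[traj.indices("O_ether")], orient_toward=fr.coords[ic])
    report: dict = {
        "plane_cation": plane.distance(fr.coords[ic]),
        "plane_rms": plane.rms,
    }
    if solvent_mol is not None:
        idx = [i for i, m in enumerate(traj.mol_ids) if m == solvent_mol]
        if not idx:
            raise ValueError(f"solvent molecule {solvent_mol!r} not present")
        com = _center_of_mass(fr.coords[idx], [traj.elements[i] for i in idx])
        d_ps = plane.distance(com)
        d_cs = float(np.linalg.norm(com - fr.coords[ic]))
        report.update(
            plane_solvent=d_ps,
            cation_solvent=d_cs,
            triangle_ok=bool(abs(d_ps - report["plane_cation"]) <= d_cs + 1e-9),
        )
    return report
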