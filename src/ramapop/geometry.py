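"""Peptide construction from backbone dihedrals and geometric observables.

The builder places atoms sequentially from internal coordinates (bond
length, bond angle, torsion relative to three previously placed atoms —
NeRF-style construction), so a conformation is fully determined by the
per-residue backbone torsions (Φ, Ψ, ω) plus the fixed residue templates in
:mod:`ramapop.residues`.  Φ and Ψ follow the convention
Φ = C(i−1)–N(i)–Cα(i)–C(i), Ψ = N(i)–Cα(i)–C(i)–N(i+1); terminal caps
(acetyl / amide) supply the flanking C and N atoms, so a capped n-residue
peptide has n well-defined (Φ, Ψ) pairs.

All coordinates are in Å, all angles in degrees.  Hydrogens are not built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import residues as rt

__all__ = [
    "AtomRecord",
    "PeptideSpec",
    "Conformation",
    "DihedralRecord",
    "xao_spec",
    "ninemer_spec",
    "measure_dihedral",
    "build_conformation",
    "build_ensemble_coordinates",
    "extract_phi_psi",
    "end_to_end_distance",
    "radius_of_gyration",
    "select_nearest_waters",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a peptide topology (coordinates live in Conformation)."""

    name: str
    element: str
    mass: float
    electrons: int
    residue_index: int  # 1-based; 0 = N-terminal cap, n+1 = C-terminal cap
    residue_name: str

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for atom {self.name}")
        if self.electrons < 1:
            raise ValueError(f"electron count < 1 for atom {self.name}")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with its terminal chemistry.

    ``n_terminal_cap`` is ``"acetyl"`` or ``"free-charged"``;
    ``c_terminal_cap`` is ``"amide"`` or ``"free-charged"``.
    """

    sequence: tuple[str, ...]
    n_terminal_cap: str = "free-charged"
    c_terminal_cap: str = "free-charged"
    name: str = "peptide"

    def __post_init__(self):
        object.__setattr__(self, "sequence", rt.resolve_sequence(self.sequence))
        if self.n_terminal_cap not in ("acetyl", "free-charged"):
            raise ValueError(f"unknown N-terminal cap {self.n_terminal_cap!r}")
        if self.c_terminal_cap not in ("amide", "free-charged"):
            raise ValueError(f"unknown C-terminal cap {self.c_terminal_cap!r}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def xao_spec() -> PeptideSpec:
    """The 11-residue XAO peptide X2A7O2 with acetyl/amide caps."""
    return PeptideSpec(rt.XAO_SEQUENCE, "acetyl", "amide", name="XAO")


def ninemer_spec() -> PeptideSpec:
    """The 9-mer Arg-Pro-Pro-Gly-Phe-Ser-Ala-Phe-Lys with charged termini."""
    return PeptideSpec(rt.NINEMER_SEQUENCE, "free-charged", "free-charged", name="9-mer")


@dataclass
class Conformation:
    """One ensemble member: an atom list plus Cartesian coordinates (Å)."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray
    frame_id: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )

    def atom_index(self, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {residue_index}")

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element != "H" for a in self.atoms])


@dataclass(frozen=True)
class DihedralRecord:
    """A (Φ, Ψ) pair in degrees for one residue position."""

    residue_index: int
    phi: float
    psi: float


# ---------------------------------------------------------------------------
# torsion measurement

def _dihedral_vec(p1, p2, p3, p4):
    """Signed torsion in degrees for stacked points of shape (..., 3)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # canonical interval (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Returns a value in (−180, 180].  Raises ``ValueError`` for degenerate
    geometry (coincident consecutive points or collinear triples).
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    for a, b in zip(pts, pts[1:]):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError("degenerate dihedral: coincident consecutive points")
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    if (np.linalg.norm(np.cross(b1, b2)) < 1e-10
            or np.linalg.norm(np.cross(b2, b3)) < 1e-10):
        raise ValueError("degenerate dihedral: collinear points")
    return float(_dihedral_vec(*pts))


# ---------------------------------------------------------------------------
# NeRF placement

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place point D bonded to c: |cD|=bond, angle(b,c,D), torsion(a,b,c,D).

    Works on stacked frames: a, b, c of shape (F, 3); torsion_deg scalar or
    shape (F,).  Returns (F, 3).
    """
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_hat = np.cross(n_hat, bc_hat)
    st = np.sin(theta)
    if np.ndim(tau) > 0:
        tau = np.asarray(tau)[..., None]
        d_local = (
            -np.cos(theta) * bc_hat
            + st * np.cos(tau) * m_hat
            + st * np.sin(tau) * n_hat
        )
    else:
        d_local = (
            -np.cos(theta) * bc_hat
            + st * np.cos(tau) * m_hat
            + st * np.sin(tau) * n_hat
        )
    return c + bond * d_local


# ---------------------------------------------------------------------------
# build plan: compiled once per PeptideSpec, executed per frame batch

def _make_atom(name, element, res_idx, res_name):
    return AtomRecord(
        name=name,
        element=element,
        mass=rt.ATOMIC_MASS[element],
        electrons=rt.ELECTRON_COUNT[element],
        residue_index=res_idx,
        residue_name=res_name,
    )


class _BuildPlan:
    """Atom list in output order plus an ordered placement program."""

    def __init__(self, spec: PeptideSpec):
        self.spec = spec
        self.atoms: list[AtomRecord] = []
        self._index: dict[tuple[int, str], int] = {}
        n = spec.n_residues
        n_capped = spec.n_terminal_cap == "acetyl"
        c_capped = spec.c_terminal_cap == "amide"

        if n_capped:
            for nm, el in (("CH3", "C"), ("C", "C"), ("O", "O")):
                self._add(nm, el, 0, "ACE")
        for i, res in enumerate(spec.sequence, start=1):
            if res not in rt.SIDE_CHAINS:
                raise KeyError(f"unknown residue code {res!r}")
            self._add("N", "N", i, res)
            self._add("CA", "C", i, res)
            self._add("C", "C", i, res)
            self._add("O", "O", i, res)
            if i == n and not c_capped:
                self._add("OXT", "O", i, res)
            for entry in rt.SIDE_CHAINS[res]:
                self._add(entry[0], entry[1], i, res)
        if c_capped:
            self._add("N", "N", n + 1, "NH2")

        # placement program: (target, (a, b, c), bond, angle, torsion_spec)
        # torsion_spec: ("const", x) | ("phi"|"psi"|"psi+180"|"omega", res_i)
        self.steps: list[tuple] = []
        self.seed_keys: list[tuple[int, str]] = []
        self._compile(n, n_capped, c_capped)

    def _add(self, name, element, res_idx, res_name):
        key = (res_idx, name)
        self._index[key] = len(self.atoms)
        self.atoms.append(_make_atom(name, element, res_idx, res_name))

    def idx(self, res_idx, name):
        return self._index[(res_idx, name)]

    def _step(self, target, refs, bond, angle, torsion):
        self.steps.append((self.idx(*target),
                           tuple(self.idx(*r) for r in refs),
                           bond, angle, torsion))

    def _compile(self, n, n_capped, c_capped):
        if n_capped:
            # seeds: cap CH3, cap C, N(1)
            self.seed_keys = [(0, "CH3"), (0, "C"), (1, "N")]
            self.seed_geom = (rt.BOND_CA_C, rt.BOND_C_N, rt.ANGLE_CA_C_N)
            self._step((1, "CA"), ((0, "CH3"), (0, "C"), (1, "N")),
                       rt.BOND_N_CA, rt.ANGLE_C_N_CA, ("omega", 0))
            self._step((0, "O"), ((1, "CA"), (1, "N"), (0, "C")),
                       rt.BOND_C_O, rt.ANGLE_N_C_O, ("const", 180.0))
            self._step((1, "C"), ((0, "C"), (1, "N"), (1, "CA")),
                       rt.BOND_CA_C, rt.ANGLE_N_CA_C, ("phi", 0))
        else:
            # seeds: N(1), CA(1), C(1); Φ(1) has no preceding C and is ignored
            self.seed_keys = [(1, "N"), (1, "CA"), (1, "C")]
            self.seed_geom = (rt.BOND_N_CA, rt.BOND_CA_C, rt.ANGLE_N_CA_C)

        for i in range(1, n):
            self._step((i + 1, "N"), ((i, "N"), (i, "CA"), (i, "C")),
                       rt.BOND_C_N, rt.ANGLE_CA_C_N, ("psi", i - 1))
            self._step((i, "O"), ((i, "CA"), (i + 1, "N"), (i, "C")),
                       rt.BOND_C_O, rt.ANGLE_N_C_O, ("const", 180.0))
            self._side_chain(i)
            self._step((i + 1, "CA"), ((i, "CA"), (i, "C"), (i + 1, "N")),
                       rt.BOND_N_CA, rt.ANGLE_C_N_CA, ("omega", i))
            self._step((i + 1, "C"), ((i, "C"), (i + 1, "N"), (i + 1, "CA")),
                       rt.BOND_CA_C, rt.ANGLE_N_CA_C, ("phi", i))

        if c_capped:
            self._step((n + 1, "N"), ((n, "N"), (n, "CA"), (n, "C")),
                       rt.BOND_C_N, rt.ANGLE_CA_C_N, ("psi", n - 1))
            self._step((n, "O"), ((n, "CA"), (n + 1, "N"), (n, "C")),
                       rt.BOND_C_O, rt.ANGLE_N_C_O, ("const", 180.0))
        else:
            # carboxylate: OXT takes the place of the next-residue N
            self._step((n, "OXT"), ((n, "N"), (n, "CA"), (n, "C")),
                       rt.BOND_C_OXT, rt.ANGLE_CA_C_OXT, ("psi", n - 1))
            self._step((n, "O"), ((n, "N"), (n, "CA"), (n, "C")),
                       rt.BOND_C_OXT, rt.ANGLE_CA_C_OXT, ("psi+180", n - 1))
        self._side_chain(n)

    def _side_chain(self, i):
        res = self.spec.sequence[i - 1]
        for name, _el, refs, bond, angle, torsion in rt.SIDE_CHAINS[res]:
            self._step((i, name), tuple((i, r) for r in refs),
                       bond, angle, ("const", torsion))

    # -- execution ---------------------------------------------------------

    def run(self, phi, psi, omega):
        """Build coordinates for a batch: phi/psi/omega of shape (F, n)."""
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        psi = np.atleast_2d(np.asarray(psi, dtype=float))
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
        n = self.spec.n_residues
        for arr, nm in ((phi, "phi"), (psi, "psi"), (omega, "omega")):
            if arr.shape[1] != n:
                raise ValueError(f"{nm} must provide one angle per residue "
                                 f"(got {arr.shape[1]}, expected {n})")
        f = phi.shape[0]
        coords = np.zeros((f, len(self.atoms), 3))

        # seed triad in the xy-plane
        b1, b2, ang = self.seed_geom
        i0, i1, i2 = (self.idx(*k) for k in self.seed_keys)
        coords[:, i0] = (0.0, 0.0, 0.0)
        coords[:, i1] = (b1, 0.0, 0.0)
        a = np.radians(180.0 - ang)
        coords[:, i2] = (b1 + b2 * np.cos(a), b2 * np.sin(a), 0.0)

        tables = {"phi": phi, "psi": psi, "omega": omega}
        for target, (ia, ib, ic), bond, angle, (kind, val) in self.steps:
            if kind == "const":
                tau = val
            elif kind == "psi+180":
                tau = tables["psi"][:, val] + 180.0
            else:
                tau = tables[kind][:, val]
            coords[:, target] = _nerf(
                coords[:, ia], coords[:, ib], coords[:, ic], bond, angle, tau
            )
        return coords


_PLAN_CACHE: dict[PeptideSpec, _BuildPlan] = {}


def _plan_for(spec: PeptideSpec) -> _BuildPlan:
    plan = _PLAN_CACHE.get(spec)
    if plan is None:
        plan = _PLAN_CACHE[spec] = _BuildPlan(spec)
    return plan


def _angle_table(spec, backbone_angles, omega_default=180.0):
    """Normalise per-residue (Φ, Ψ[, ω]) input to three (n,) arrays."""
    n = spec.n_residues
    arr = np.asarray(backbone_angles, dtype=float)
    if arr.ndim == 1 and arr.size in (2, 3):
        arr = np.tile(arr, (n, 1))
    if arr.shape[0] != n or arr.shape[1] not in (2, 3):
        raise ValueError(
            f"backbone_angles must be (n_residues, 2 or 3); got {arr.shape}"
        )
    phi, psi = arr[:, 0], arr[:, 1]
    omega = arr[:, 2] if arr.shape[1] == 3 else np.full(n, omega_default)
    return phi, psi, omega


def build_conformation(spec: PeptideSpec, backbone_angles, frame_id: int = 0) -> Conformation:
    """Build one conformation from per-residue backbone torsions.

    ``backbone_angles`` is an (n, 2) or (n, 3) array of (Φ, Ψ[, ω]) in
    degrees, or a single (Φ, Ψ[, ω]) tuple applied to every residue.
    ω defaults to 180° (trans peptide bonds).  Side chains are placed in
    fixed all-trans rotamers from the residue templates.
    """
    plan = _plan_for(spec)
    phi, psi, omega = _angle_table(spec, backbone_angles)
    coords = plan.run(phi[None, :], psi[None, :], omega[None, :])[0]
    return Conformation(atoms=plan.atoms, coordinates=coords, frame_id=frame_id)


def build_ensemble_coordinates(spec: PeptideSpec, phi, psi, omega=180.0):
    """Vectorised build over frames.

    ``phi`` and ``psi`` have shape (F, n_residues); ``omega`` is a scalar or
    an (F, n) array.  Returns ``(atoms, coords)`` with coords of shape
    (F, n_atoms, 3).
    """
    plan = _plan_for(spec)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.ndim(omega) == 0:
        omega = np.full_like(phi, float(omega))
    return plan.atoms, plan.run(phi, psi, omega)


def template_bond_lengths(spec: PeptideSpec):
    """(i, j, length) for every bond fixed by the construction templates."""
    plan = _plan_for(spec)
    return [(ic, target, bond) for target, (_, _, ic), bond, _, _ in plan.steps]


# ---------------------------------------------------------------------------
# dihedral extraction

def _phi_psi_atom_quads(atoms, mode="strict"):
    """Index quadruples for each defined (Φ, Ψ) pair.

    Returns a list of (residue_index, phi_quad, psi_quad) where each quad is
    a 4-tuple of atom indices, or None if that angle is undefined.
    """
    index = {}
    for i, a in enumerate(atoms):
        index[(a.residue_index, a.name)] = i
    res_ids = sorted({a.residue_index for a in atoms
                      if a.residue_name not in ("ACE", "NH2")})
    phi = {}
    psi = {}
    for r in res_ids:
        try:
            phi[r] = (index[(r - 1, "C")], index[(r, "N")],
                      index[(r, "CA")], index[(r, "C")])
        except KeyError:
            pass
        try:
            psi[r] = (index[(r, "N")], index[(r, "CA")],
                      index[(r, "C")], index[(r + 1, "N")])
        except KeyError:
            pass
        for name in ("N", "CA", "C"):
            if (r, name) not in index:
                raise KeyError(f"missing backbone atom {name} in residue {r}")
    out = []
    if mode == "strict":
        for r in res_ids:
            if r in phi and r in psi:
                out.append((r, phi[r], psi[r]))
    elif mode == "adjacent":
        for r in res_ids:
            if r in psi and (r + 1) in phi:
                out.append((r, phi[r + 1], psi[r]))
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    return out


def extract_phi_psi(conf: Conformation, mode: str = "strict") -> list[DihedralRecord]:
    """Measure all defined (Φ, Ψ) pairs of a conformation.

    ``mode="strict"`` keeps residues for which both angles exist (a capped
    peptide yields one pair per residue).  ``mode="adjacent"`` pairs Ψ(i)
    with Φ(i+1), the convention that yields n−1 pairs for a peptide with
    free termini.
    """
    quads = _phi_psi_atom_quads(conf.atoms, mode)
    xyz = conf.coordinates
    return [
        DihedralRecord(
            residue_index=r,
            phi=float(_dihedral_vec(*(xyz[i] for i in pq))),
            psi=float(_dihedral_vec(*(xyz[i] for i in sq))),
        )
        for r, pq, sq in quads
    ]


def extract_phi_psi_batch(atoms, coords, mode: str = "strict"):
    """Vectorised (Φ, Ψ) extraction over an ensemble.

    ``coords`` has shape (F, n_atoms, 3).  Returns ``(residue_ids, phi,
    psi)`` with phi/psi of shape (F, n_pairs).
    """
    quads = _phi_psi_atom_quads(atoms, mode)
    res_ids = np.array([r for r, _, _ in quads])
    phi = np.stack(
        [_dihedral_vec(*(coords[:, i] for i in pq)) for _, pq, _ in quads], axis=1
    )
    psi = np.stack(
        [_dihedral_vec(*(coords[:, i] for i in sq)) for _, _, sq in quads], axis=1
    )
    return res_ids, phi, psi


# ---------------------------------------------------------------------------
# observables

def end_to_end_distance(conf: Conformation) -> float:
    """Distance (Å) from backbone N of residue 1 to backbone C of the last
    residue; terminal caps are excluded from the span."""
    res_ids = [a.residue_index for a in conf.atoms
               if a.residue_name not in ("ACE", "NH2")]
    first, last = min(res_ids), max(res_ids)
    p = conf.coordinates[conf.atom_index(first, "N")]
    q = conf.coordinates[conf.atom_index(last, "C")]
    return float(np.linalg.norm(q - p))


def end_to_end_distance_batch(atoms, coords) -> np.ndarray:
    res_ids = [a.residue_index for a in atoms if a.residue_name not in ("ACE", "NH2")]
    first, last = min(res_ids), max(res_ids)
    index = {(a.residue_index, a.name): i for i, a in enumerate(atoms)}
    i, j = index[(first, "N")], index[(last, "C")]
    return np.linalg.norm(coords[:, j] - coords[:, i], axis=-1)


def _weights(atoms, weighting):
    if weighting == "mass":
        return np.array([a.mass for a in atoms])
    if weighting == "electrons":
        return np.array([float(a.electrons) for a in atoms])
    if weighting == "uniform":
        return np.ones(len(atoms))
    raise ValueError(f"unknown weighting {weighting!r}")


def radius_of_gyration(conf: Conformation, weighting: str = "mass",
                       heavy_only: bool = True) -> float:
    """Weighted radius of gyration (Å): sqrt(Σ wᵢ|rᵢ−r̄|² / Σ wᵢ).

    Defaults to mass weighting over heavy atoms, caps included.
    """
    mask = conf.heavy_mask if heavy_only else np.ones(len(conf.atoms), bool)
    atoms = [a for a, m in zip(conf.atoms, mask) if m]
    if not atoms:
        raise ValueError("no atoms selected")
    w = _weights(atoms, weighting)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    xyz = conf.coordinates[mask]
    com = (w[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((w * ((xyz - com) ** 2).sum(axis=1)).sum() / total))


def radius_of_gyration_batch(atoms, coords, weighting: str = "mass",
                             heavy_only: bool = True) -> np.ndarray:
    mask = np.array([a.element != "H" for a in atoms]) if heavy_only \
        else np.ones(len(atoms), bool)
    sel = [a for a, m in zip(atoms, mask) if m]
    w = _weights(sel, weighting)
    total = w.sum()
    xyz = coords[:, mask]
    com = (w[None, :, None] * xyz).sum(axis=1) / total
    d2 = ((xyz - com[:, None, :]) ** 2).sum(axis=-1)
    return np.sqrt((w[None, :] * d2).sum(axis=1) / total)


def select_nearest_waters(peptide: Conformation, waters, n: int):
    """The ``n`` whole water molecules closest to the peptide.

    ``waters`` is a sequence of (3, 3) coordinate arrays, one (O, H, H)
    molecule each.  Distance is the minimum heavy-atom (water O to peptide
    heavy atom) separation; ties keep input order.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    waters = [np.asarray(w, dtype=float) for w in waters]
    if n >= len(waters):
        return list(waters)
    pep = peptide.coordinates[peptide.heavy_mask]
    dmin = np.array([
        np.min(np.linalg.norm(pep - w[0], axis=1)) for w in waters
    ])
    order = np.argsort(dmin, kind="stable")[:n]
    return [waters[i] for i in sorted(order)]
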