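"""Construction of ring, arc, slit and linear oligomer models.

A ring of N subunits is built by placing a monomer at radius R on the +x
axis (membrane normal = z, radial-outward = +x, ring tangent = +y at that
pose) and rotating it N times by 360/N degrees, giving exact N-fold
symmetry.  The radius is chosen by scanning a grid of radii for the minimum
of a surrogate inter-subunit potential: a soft-core repulsion between all
neighbouring atom pairs plus a Gaussian contact attraction between
designated interface atoms of adjacent subunits.  The surrogate replaces a
force-field in-vacuo minimisation: only the clash/contact trade-off that
selects the radius is modelled, so absolute energies are arbitrary
(dimensionless) and only nearest-neighbour pairs contribute, matching the
strictly adjacent inter-subunit bond topology of these oligomers.

Arcs are contiguous cuts of a ring; a slit is an arc plus its image under a
two-fold rotation, placed so the terminal subunits of the two arcs face
each other at a configurable gap; linear oligomers are translated copies
along the ring tangent (a ring of infinite curvature).  Units are nm
internally and Angstrom at the PDB boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import MonomerFixture

__all__ = [
    "OligomerModel", "SurrogateParams", "SurrogateEnergy",
    "build_ring", "build_arc", "build_slit", "build_linear",
    "optimal_ring_radius", "pair_energy", "write_pdb", "read_pdb",
]

#: Chain identifiers available in the PDB format, in assignment order.
_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class OligomerModel:
    """Per-subunit coordinate sets for one oligomer.

    ``subunits[k]`` is the (n_atoms, 3) nm coordinate array of subunit k;
    atom metadata (names, elements, residue ids) is shared across subunits
    and taken from the monomer.  ``ring_n`` is the stoichiometry of the
    underlying ring (equals the subunit count for rings) and fixes the
    rotation step 360/ring_n for rings and arcs.
    """

    subunits: list[np.ndarray]
    monomer: MonomerFixture
    shape: str                           # ring | arc | slit | linear
    ring_n: int | None = None
    radius: float | None = None          # nm (ring/arc)
    spacing: float | None = None         # nm (linear)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def rotation_step(self) -> float | None:
        """Degrees between adjacent subunits (ring/arc)."""
        return 360.0 / self.ring_n if self.ring_n else None

    @property
    def adjacency(self) -> list[tuple[int, int]]:
        """Neighbour pairs: cyclic for rings, a chain otherwise."""
        n = self.n_subunits
        pairs = [(k, k + 1) for k in range(n - 1)]
        if self.shape == "ring":
            pairs.append((n - 1, 0))
        return pairs

    def all_coords(self) -> np.ndarray:
        """All atoms of all subunits, stacked (subunit-major)."""
        return np.vstack(self.subunits)

    def subunit_centroids(self) -> np.ndarray:
        return np.array([c.mean(axis=0) for c in self.subunits])


def _rot_z(rad: float) -> np.ndarray:
    c, s = math.cos(rad), math.sin(rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_ring(monomer: MonomerFixture, n: int, radius: float,
               clash_radius: float = 0.15) -> OligomerModel:
    """Ring of ``n`` subunits: the monomer rotated n times by 360/n degrees.

    The monomer's local frame (z up, +x radial, +y tangential) is translated
    to radius ``radius`` along +x and copied by exact rotations about z, so
    subunit k is subunit 0 rotated by k*360/n degrees to machine precision.
    A radius smaller than the monomer's radial extent earns a clash warning.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 subunits")
    if radius <= 0:
        raise ValueError("radius must be positive")
    base = monomer.coords + np.array([radius, 0.0, 0.0])
    radial_extent = float(np.abs(monomer.coords[:, 0]).max())
    if radius < radial_extent:
        warnings.warn(f"ring radius {radius} nm smaller than the monomer "
                      f"radial extent {radial_extent:.2f} nm: subunits "
                      "overlap the axis", stacklevel=2)
    step = 2 * math.pi / n
    subunits = [base @ _rot_z(k * step).T for k in range(n)]
    model = OligomerModel(subunits, monomer, "ring", ring_n=n, radius=radius,
                          provenance=[f"build_ring n={n} R={radius:.4f}"])
    dmin = _min_intersubunit_distance(model)
    if dmin < clash_radius:
        warnings.warn(f"adjacent subunits clash (min distance "
                      f"{dmin:.3f} nm)", stacklevel=2)
    return model


def build_arc(ring: OligomerModel, m: int) -> OligomerModel:
    """First ``m`` contiguous subunits cut from a ring, geometry unchanged."""
    if ring.shape != "ring":
        raise ValueError("build_arc expects a ring model")
    if not 2 <= m < ring.n_subunits:
        raise ValueError("arc size must be in [2, N-1]")
    return OligomerModel([s.copy() for s in ring.subunits[:m]], ring.monomer,
                         "arc", ring_n=ring.ring_n, radius=ring.radius,
                         provenance=ring.provenance + [f"build_arc m={m}"])


def build_slit(arc1: OligomerModel, arc2: OligomerModel, gap: float,
               clash_radius: float = 0.15) -> OligomerModel:
    """Two arcs placed end to end, terminals facing at distance ``gap``.

    ``arc2`` is mapped by a two-fold rotation about the vertical axis
    through the slit centre, chosen so each of its terminal subunit centres
    sits ``gap`` nm from the corresponding terminal of ``arc1``.  For two
    copies of the same arc the construction has an exact two-fold axis.
    """
    if arc1.shape != "arc" or arc2.shape != "arc":
        raise ValueError("build_slit expects two arc models")
    c1 = arc1.subunit_centroids()
    c2 = arc2.subunit_centroids()
    terminals = 0.25 * (c1[0] + c1[-1] + c2[0] + c2[-1])
    bulge = np.concatenate([c1[:, :2].mean(axis=0)[:2], [0.0]])
    norm = np.linalg.norm(bulge[:2])
    if norm < 1e-9:
        raise ValueError("arc bulge direction undefined")
    n_hat = -bulge / norm
    centre = terminals + 0.5 * gap * n_hat
    centre[2] = 0.0

    def rot180(xyz: np.ndarray) -> np.ndarray:
        out = xyz.copy()
        out[:, 0] = 2 * centre[0] - xyz[:, 0]
        out[:, 1] = 2 * centre[1] - xyz[:, 1]
        return out

    placed = [rot180(s) for s in arc2.subunits]
    a1 = np.vstack(arc1.subunits)
    a2 = np.vstack(placed)
    dmin = _min_distance_between(a1, a2)
    if dmin < clash_radius:
        raise ValueError(f"slit arcs sterically overlap (min inter-arc atom "
                         f"distance {dmin:.3f} nm < {clash_radius} nm)")
    return OligomerModel([s.copy() for s in arc1.subunits] + placed,
                         arc1.monomer, "slit", ring_n=arc1.ring_n,
                         radius=arc1.radius,
                         provenance=arc1.provenance
                         + [f"build_slit gap={gap:.3f}"])


def build_linear(monomer: MonomerFixture, m: int, spacing: float
                 ) -> OligomerModel:
    """``m`` copies translated along the ring tangent (+y) at ``spacing`` nm."""
    if m < 2:
        raise ValueError("a linear oligomer needs at least 2 subunits")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    subunits = [monomer.coords + np.array([0.0, k * spacing, 0.0])
                for k in range(m)]
    return OligomerModel(subunits, monomer, "linear", spacing=spacing,
                         provenance=[f"build_linear m={m} s={spacing:.3f}"])


def _min_distance_between(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    return float(cKDTree(a).query(b, k=1)[0].min())


def _min_intersubunit_distance(model: OligomerModel) -> float:
    return min(_min_distance_between(model.subunits[i], model.subunits[j])
               for i, j in model.adjacency)


# ---------------------------------------------------------------------------
# Surrogate potential and radius optimisation
# ---------------------------------------------------------------------------

@dataclass
class SurrogateParams:
    """Parameters of the surrogate inter-subunit potential (lengths in nm)."""

    core_radius: float = 0.25       # soft-core onset between any atom pair
    k_repulsion: float = 200.0      # quadratic soft-core strength
    contact_r0: float = 0.30        # preferred interface-atom distance
    contact_sigma: float = 0.15     # width of the contact well
    contact_weight: float = 1.0     # depth of the contact well


@dataclass
class SurrogateEnergy:
    """Decomposed surrogate energy (dimensionless)."""

    total: float
    repulsion: float
    attraction: float
    params: SurrogateParams

    def __post_init__(self) -> None:
        if not np.isfinite(self.total):
            raise ValueError("energy must be finite")
        if self.repulsion < 0:
            raise ValueError("repulsion term must be >= 0")


def default_interface_sets(monomer: MonomerFixture
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Default interface atoms: +y-edge donors pair with -y-edge acceptors."""
    right = np.flatnonzero(np.isin(monomer.atom_names, ("N", "NZ")))
    left = np.flatnonzero(np.isin(monomer.atom_names, ("O", "OE1")))
    return right, left


def pair_energy(coords_a: np.ndarray, coords_b: np.ndarray,
                interface: tuple[np.ndarray, np.ndarray],
                params: SurrogateParams) -> SurrogateEnergy:
    """Surrogate energy of one adjacent subunit pair.

    ``interface`` gives (indices in a facing b, indices in b facing a):
    the attraction acts across those designated atoms; the soft-core
    repulsion acts between all atom pairs of the two subunits.
    """
    from scipy.spatial import cKDTree
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, params.core_radius)
    rep = 0.0
    for i, hits in enumerate(pairs):
        if hits:
            d = np.linalg.norm(coords_b[hits] - coords_a[i], axis=1)
            rep += params.k_repulsion * np.sum((params.core_radius - d) ** 2)
    right, left = interface
    att = 0.0
    if len(right) and len(left):
        d = np.linalg.norm(coords_a[right][:, None, :]
                           - coords_b[left][None, :, :], axis=-1)
        att = -params.contact_weight * float(np.sum(
            np.exp(-0.5 * ((d - params.contact_r0)
                           / params.contact_sigma) ** 2)))
    return SurrogateEnergy(total=rep + att, repulsion=rep, attraction=att,
                           params=params)


def ring_energy(monomer, n: int, radius: float,
                interface: tuple[np.ndarray, np.ndarray] | None = None,
                params: SurrogateParams | None = None) -> SurrogateEnergy:
    """Total surrogate energy of an N-ring at the given radius.

    Only nearest neighbours interact, and by symmetry all N neighbour pairs
    are congruent, so the total is N times one pair energy.
    """
    params = params or SurrogateParams()
    if interface is None:
        interface = default_interface_sets(monomer)
    base = monomer.coords + np.array([radius, 0.0, 0.0])
    neighbour = base @ _rot_z(2 * math.pi / n).T
    e = pair_energy(base, neighbour, interface, params)
    return SurrogateEnergy(total=n * e.total, repulsion=n * e.repulsion,
                           attraction=n * e.attraction, params=params)


def optimal_ring_radius(monomer, n: int, r_grid,
                        interface: tuple[np.ndarray, np.ndarray] | None = None,
                        params: SurrogateParams | None = None):
    """Ring radius at the surrogate-energy minimum over a radius grid.

    Returns ``(r_opt, curve)`` where ``curve`` is a pandas DataFrame with
    columns ``radius_nm``, ``total``, ``repulsion``, ``attraction``.  The
    grid argmin is refined by parabolic interpolation.  A grid without an
    interior minimum (monotone energy) is an error: the grid does not span
    the optimum.
    """
    import pandas as pd

    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or len(r_grid) < 3:
        raise ValueError("r_grid must contain at least 3 radii")
    energies = [ring_energy(monomer, n, r, interface, params)
                for r in r_grid]
    totals = np.array([e.total for e in energies])
    i = int(np.argmin(totals))
    if i == 0 or i == len(totals) - 1:
        raise ValueError("no interior energy minimum on the radius grid")
    denom = totals[i - 1] - 2 * totals[i] + totals[i + 1]
    r_opt = float(r_grid[i])
    if denom > 0:
        r_opt += 0.5 * (totals[i - 1] - totals[i + 1]) / denom \
            * (r_grid[i + 1] - r_grid[i])
    curve = pd.DataFrame({
        "radius_nm": r_grid,
        "total": totals,
        "repulsion": [e.repulsion for e in energies],
        "attraction": [e.attraction for e in energies],
    })
    return r_opt, curve


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _res_name(monomer: MonomerFixture, res_id: int) -> str:
    names = monomer.atom_names[monomer.res_ids == res_id]
    if "NZ" in names:
        return "LYS"
    if "OE1" in names:
        return "GLU"
    return "ALA"


def write_pdb(model: OligomerModel, path: str | Path) -> list[Path]:
    """Write an oligomer as PDB, one chain per subunit, coordinates in A.

    Models with more than 62 subunits (the PDB chain-id alphabet) are split
    into numbered segments with a warning.  Occupancy and B-factor default
    to 1.00 and 0.00.  Returns the list of files written.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    mono = model.monomer
    n_per = mono.n_atoms
    segments = [model.subunits[i:i + len(_CHAIN_IDS)]
                for i in range(0, model.n_subunits, len(_CHAIN_IDS))]
    if len(segments) > 1:
        warnings.warn(f"{model.n_subunits} subunits exceed the 62 PDB chain "
                      "ids; writing segmented files", stacklevel=2)
    written = []
    for seg_idx, seg in enumerate(segments):
        atoms = struc.AtomArray(n_per * len(seg))
        coords = np.vstack(seg) * 10.0          # nm -> Angstrom
        atoms.coord = coords.astype(np.float32)
        atoms.atom_name = np.tile(mono.atom_names, len(seg))
        atoms.element = np.tile(np.char.upper(mono.elements), len(seg))
        atoms.res_id = np.tile(mono.res_ids, len(seg))
        atoms.res_name = np.tile(
            np.array([_res_name(mono, r) for r in mono.res_ids]), len(seg))
        atoms.chain_id = np.repeat(
            np.array(list(_CHAIN_IDS[:len(seg)])), n_per)
        atoms.hetero = np.zeros(atoms.array_length(), dtype=bool)
        atoms.set_annotation("occupancy",
                             np.ones(atoms.array_length(), dtype=float))
        atoms.set_annotation("b_factor",
                             np.zeros(atoms.array_length(), dtype=float))
        out = path if len(segments) == 1 else path.with_name(
            f"{path.stem}_part{seg_idx + 1}{path.suffix}")
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(out)
        written.append(out)
    return written


def read_pdb(path: str | Path):
    """Read a PDB written by :func:`write_pdb`.

    Returns ``(coords_by_chain, atoms)``: a list of (n, 3) nm coordinate
    arrays, one per chain, plus the raw biotite AtomArray (coordinates
    in Angstrom).
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        atoms = PDBFile.read(str(path)).get_structure(
            model=1, extra_fields=["occupancy", "b_factor"])
    except Exception as exc:          # surface the parser's line context
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    coords_by_chain = []
    for cid in dict.fromkeys(atoms.chain_id):
        coords_by_chain.append(
            np.asarray(atoms.coord[atoms.chain_id == cid], dtype=float) / 10.0)
    return coords_by_chain, atoms
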