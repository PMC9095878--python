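"""Per-subunit structural observables on oligomer coordinate models.

Quantifies how the globular head domain of each subunit is oriented
relative to its transmembrane beta-hairpins, and how strongly neighbouring
subunits interact:

* principal axes of the head (PH1, PH2) and hairpin (PB1, PB3) blocks;
* the angle triple tau (PH1 vs PB1, vertical head movement), chi (PH1 vs
  PB3, horizontal movement) and alpha (rotation of PH2 about PB1, measured
  from PB3 projected into the plane perpendicular to PB1);
* geometric hydrogen-bond counts (donor-acceptor distance <= 0.35 nm and
  hydrogen-donor-acceptor angle <= 30 deg) and salt-bridge counts
  (opposite-charge heavy atoms <= 0.40 nm, one count per residue pair)
  between the hairpins and heads of adjacent subunits;
* optimally superposed (Kabsch) or direct C-alpha RMSD between frames.

All quantities are invariant to rigid motion of the whole model.  Principal
axes carry an intrinsic sign ambiguity; signs are fixed against reference
directions (membrane normal, radial-outward), so alpha is well defined as
long as PH2 keeps a positive projection onto its reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .builder import OligomerModel
from .synthetic import MonomerFixture

__all__ = [
    "DomainPartition", "AngleTriple", "Chemistry", "InteractionReport",
    "principal_axes", "head_angles", "count_hydrogen_bonds",
    "count_salt_bridges", "neighbor_interaction_report", "rmsd_ca",
    "partition_from_fixture",
]

HBOND_R_MAX_NM = 0.35
HBOND_ANGLE_MAX_DEG = 30.0
SALTBRIDGE_R_MAX_NM = 0.40


# ---------------------------------------------------------------------------
# Domain partition
# ---------------------------------------------------------------------------

@dataclass
class DomainPartition:
    """Residue-id sets of the head, hairpin and connector domains."""

    head_residues: set[int]
    hairpin_residues: set[int]
    connector_residues: set[int]

    def __post_init__(self) -> None:
        sets = (self.head_residues, self.hairpin_residues,
                self.connector_residues)
        if any(not s for s in sets):
            raise ValueError("every domain needs at least one residue")
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("domain residue sets must be disjoint")


def partition_from_fixture(monomer: MonomerFixture) -> DomainPartition:
    """The partition a synthetic pseudo-monomer ships with."""
    return DomainPartition(head_residues=set(monomer.domain_map["head"]),
                           hairpin_residues=set(monomer.domain_map["hairpin"]),
                           connector_residues=set(
                               monomer.domain_map["connector"]))


# ---------------------------------------------------------------------------
# Principal axes and head-orientation angles
# ---------------------------------------------------------------------------

def _fix_sign(axis: np.ndarray, refs) -> np.ndarray:
    """Orient ``axis`` toward the first reference it is not orthogonal to."""
    for ref in refs:
        d = float(axis @ ref)
        if abs(d) > 1e-8:
            return axis if d > 0 else -axis
    return axis


def principal_axes(coords: np.ndarray,
                   ref1=(0.0, 0.0, 1.0),
                   ref2=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Principal axes of a point set, rows (P1, P2, P3) by falling variance.

    Eigenvectors of the positional covariance about the centroid.  P1 is
    oriented toward ``ref1`` (membrane normal by default), P2 toward
    ``ref2`` (radial-outward), and P3 = P1 x P2.  Degenerate (within 1e-9
    relative) eigenvalues leave the orientation undefined and are an error,
    as are fewer than 3 non-collinear points.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    scale = max(evals[0], 1e-30)
    if np.min(-np.diff(evals)) / scale < 1e-9:
        raise ValueError("degenerate principal axes (eigenvalue tie)")
    ref1 = np.asarray(ref1, dtype=float)
    ref2 = np.asarray(ref2, dtype=float)
    fallback = (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
                np.array([1.0, 0.0, 0.0]))
    p1 = _fix_sign(evecs[:, 0], (ref1, *fallback))
    p2 = _fix_sign(evecs[:, 1], (ref2, *fallback))
    p3 = np.cross(p1, p2)
    return np.vstack([p1, p2, p3])


@dataclass
class AngleTriple:
    """Head-domain orientation relative to the hairpin block, degrees."""

    tau: float       # angle(PH1, PB1), vertical head movement, [0, 180]
    chi: float       # angle(PH1, PB3), horizontal head movement, [0, 180]
    alpha: float     # rotation of PH2 about PB1 from projected PB3, (-180, 180]
    ph1: np.ndarray = field(repr=False, default=None)
    ph2: np.ndarray = field(repr=False, default=None)
    pb1: np.ndarray = field(repr=False, default=None)
    pb3: np.ndarray = field(repr=False, default=None)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                      -1.0, 1.0))
    return math.degrees(math.acos(c))


def head_angles(coords: np.ndarray, res_ids: np.ndarray,
                partition: DomainPartition,
                radial_ref=None) -> AngleTriple:
    """Angle triple (tau, chi, alpha) of one subunit.

    ``radial_ref`` fixes the sign of the in-plane axes; by default it is the
    outward xy direction of the subunit centroid (sensible for subunits of a
    ring centred on the z axis), falling back to +x for a subunit at the
    origin.  PB3 is additionally sign-fixed against the radial reference and
    PB2 recomputed from it, so the reference pose (head axes coincident with
    hairpin axes) yields tau = 0, chi = 90 and alpha = 0.
    """
    coords = np.asarray(coords, dtype=float)
    res_ids = np.asarray(res_ids)
    head = coords[np.isin(res_ids, sorted(partition.head_residues))]
    hairpin = coords[np.isin(res_ids, sorted(partition.hairpin_residues))]
    if radial_ref is None:
        xy = coords.mean(axis=0)[:2]
        radial_ref = np.array([*xy, 0.0]) / np.linalg.norm(xy) \
            if np.linalg.norm(xy) > 1e-6 else np.array([1.0, 0.0, 0.0])
    radial_ref = np.asarray(radial_ref, dtype=float)

    ph = principal_axes(head, ref2=radial_ref)
    ph1, ph2 = ph[0], ph[1]
    pb = principal_axes(hairpin, ref2=radial_ref)
    pb1 = pb[0]
    # Sign-fix the smallest axis directly against the radial reference (its
    # cross-product sign would be arbitrary) and complete the frame from it.
    pb3 = _fix_sign(pb[2], (radial_ref, np.array([1.0, 0.0, 0.0]),
                            np.array([0.0, 1.0, 0.0])))

    tau = _angle_deg(ph1, pb1)
    chi = _angle_deg(ph1, pb3)

    proj = ph2 - (ph2 @ pb1) * pb1
    ref = pb3 - (pb3 @ pb1) * pb1
    if np.linalg.norm(proj) < 1e-8:
        raise ValueError("PH2 parallel to PB1: alpha undefined")
    if np.linalg.norm(ref) < 1e-8:
        raise ValueError("PB3 parallel to PB1: alpha reference undefined")
    alpha = math.degrees(math.atan2(float(np.cross(ref, proj) @ pb1),
                                    float(ref @ proj)))
    return AngleTriple(tau=tau, chi=chi, alpha=alpha,
                       ph1=ph1, ph2=ph2, pb1=pb1, pb3=pb3)


# ---------------------------------------------------------------------------
# Geometric hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass
class Chemistry:
    """Donor/acceptor/charged-group coordinates of one region.

    ``donors`` and ``donor_h`` are aligned (one hydrogen per donor);
    ``donor_h`` may be None, in which case hydrogens are idealised along
    each candidate donor-acceptor direction (a distance-only criterion) and
    the fact is flagged on the instance.  Charged groups carry the residue
    id of each atom so a residue pair is counted once.
    """

    donors: np.ndarray
    donor_h: np.ndarray | None
    acceptors: np.ndarray
    positive_ids: np.ndarray
    positive_xyz: np.ndarray
    negative_ids: np.ndarray
    negative_xyz: np.ndarray
    hydrogens_idealized: bool = False

    def __post_init__(self) -> None:
        if self.donor_h is None and len(self.donors):
            self.hydrogens_idealized = True

    @classmethod
    def from_fixture_domain(cls, monomer: MonomerFixture,
                            coords: np.ndarray, domain: str) -> "Chemistry":
        """Chemistry of one domain of a placed subunit.

        Atom roles follow the fixture's naming convention: N atoms with an
        H in the same residue donate, O atoms accept, NZ/NH* are positive
        and OE*/OD* negative charged groups.
        """
        mask = monomer.domain_atom_mask(domain)
        names = monomer.atom_names
        rid = monomer.res_ids
        donors, dh = [], []
        for i in np.flatnonzero(mask & (names == "N")):
            j = np.flatnonzero((rid == rid[i]) & (names == "H"))
            if len(j):
                donors.append(coords[i])
                dh.append(coords[j[0]])
        pos = mask & (np.char.startswith(names, "NZ")
                      | np.char.startswith(names, "NH"))
        neg = mask & (np.char.startswith(names, "OE")
                      | np.char.startswith(names, "OD"))
        return cls(
            donors=np.array(donors).reshape(-1, 3),
            donor_h=np.array(dh).reshape(-1, 3) if donors else None,
            acceptors=coords[mask & (names == "O")],
            positive_ids=rid[pos], positive_xyz=coords[pos],
            negative_ids=rid[neg], negative_xyz=coords[neg])


def _hbonds_directional(donors, donor_h, acceptors,
                        r_max: float, angle_max: float) -> int:
    if len(donors) == 0 or len(acceptors) == 0:
        return 0
    count = 0
    tree = cKDTree(acceptors)
    for i, hits in enumerate(tree.query_ball_point(donors, r_max)):
        for j in hits:
            da = acceptors[j] - donors[i]
            if donor_h is None:
                count += 1          # idealised hydrogen along D->A
                continue
            dh = donor_h[i] - donors[i]
            ang = _angle_deg(dh, da)
            if ang <= angle_max:
                count += 1
    return count


def count_hydrogen_bonds(region_a: Chemistry, region_b: Chemistry,
                         r_max: float = HBOND_R_MAX_NM,
                         angle_max: float = HBOND_ANGLE_MAX_DEG) -> int:
    """Hydrogen bonds between two regions, both donation directions.

    A bond is a (donor, acceptor) pair with donor-acceptor distance
    <= ``r_max`` and hydrogen-donor-acceptor angle <= ``angle_max``; each
    pair is counted once.  Regions without donors and acceptors yield 0
    with a warning.
    """
    if (len(region_a.donors) == 0 and len(region_a.acceptors) == 0) or \
            (len(region_b.donors) == 0 and len(region_b.acceptors) == 0):
        warnings.warn("a region has no donors or acceptors; count is 0",
                      stacklevel=2)
        return 0
    return (_hbonds_directional(region_a.donors, region_a.donor_h,
                                region_b.acceptors, r_max, angle_max)
            + _hbonds_directional(region_b.donors, region_b.donor_h,
                                  region_a.acceptors, r_max, angle_max))


def count_salt_bridges(region_a: Chemistry, region_b: Chemistry,
                       r_max: float = SALTBRIDGE_R_MAX_NM) -> int:
    """Salt bridges between two regions: opposite-charge residue pairs whose
    minimum heavy-atom distance is <= ``r_max``, one count per residue pair.
    """
    count = 0
    for pid, pxyz, nid, nxyz in (
            (region_a.positive_ids, region_a.positive_xyz,
             region_b.negative_ids, region_b.negative_xyz),
            (region_b.positive_ids, region_b.positive_xyz,
             region_a.negative_ids, region_a.negative_xyz)):
        if len(pid) == 0 or len(nid) == 0:
            continue
        d = np.linalg.norm(pxyz[:, None, :] - nxyz[None, :, :], axis=-1)
        close = d <= r_max
        seen = set()
        for i, j in zip(*np.nonzero(close)):
            pair = (int(pid[i]), int(nid[j]))
            if pair not in seen:
                seen.add(pair)
                count += 1
    return count


# ---------------------------------------------------------------------------
# Per-subunit reports
# ---------------------------------------------------------------------------

@dataclass
class InteractionReport:
    """Interaction counts and head angles for every subunit (and frame).

    ``per_frame`` has one row per (frame, subunit) with columns HB_beta,
    HB_head, SB_head, tau_deg, chi_deg, alpha_deg; ``summary`` holds the
    boxplot statistics (Q1, median, Q3, mean) per metric across rows.
    """

    per_frame: pd.DataFrame
    summary: pd.DataFrame


def _subunit_chemistry(model: OligomerModel, k: int
                       ) -> tuple[Chemistry, Chemistry]:
    mono = model.monomer
    return (Chemistry.from_fixture_domain(mono, model.subunits[k], "hairpin"),
            Chemistry.from_fixture_domain(mono, model.subunits[k], "head"))


def neighbor_interaction_report(models, partition: DomainPartition
                                ) -> InteractionReport:
    """Neighbour interaction counts and head angles per subunit.

    ``models`` is one :class:`OligomerModel` or a list of them (frames of
    the same oligomer).  Adjacency follows the model topology: cyclic for
    rings, a chain for arcs, slits and linear oligomers, so arc terminals
    have a single neighbour.  HB_beta counts hydrogen bonds between the
    hairpins of a subunit and both its neighbours, HB_head / SB_head the
    hydrogen bonds / salt bridges between head domains.
    """
    if isinstance(models, OligomerModel):
        models = [models]
    if not models:
        raise ValueError("no model frames given")
    rows = []
    for f, model in enumerate(models):
        n = model.n_subunits
        if n < 2:
            raise ValueError("adjacency undefined for a single subunit")
        chems = [_subunit_chemistry(model, k) for k in range(n)]
        hb_beta = np.zeros(n, dtype=int)
        hb_head = np.zeros(n, dtype=int)
        sb_head = np.zeros(n, dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, j in model.adjacency:
                hb = count_hydrogen_bonds(chems[i][0], chems[j][0])
                hh = count_hydrogen_bonds(chems[i][1], chems[j][1])
                sb = count_salt_bridges(chems[i][1], chems[j][1])
                hb_beta[i] += hb
                hb_beta[j] += hb
                hb_head[i] += hh
                hb_head[j] += hh
                sb_head[i] += sb
                sb_head[j] += sb
        for k in range(n):
            ang = head_angles(model.subunits[k], model.monomer.res_ids,
                              partition)
            rows.append({"frame": f, "subunit": k,
                         "HB_beta": int(hb_beta[k]),
                         "HB_head": int(hb_head[k]),
                         "SB_head": int(sb_head[k]),
                         "tau_deg": ang.tau, "chi_deg": ang.chi,
                         "alpha_deg": ang.alpha})
    per_frame = pd.DataFrame(rows)
    metrics = ["HB_beta", "HB_head", "SB_head",
               "tau_deg", "chi_deg", "alpha_deg"]
    summary = pd.DataFrame({
        "metric": metrics,
        "q1": [per_frame[m].quantile(0.25) for m in metrics],
        "median": [per_frame[m].median() for m in metrics],
        "q3": [per_frame[m].quantile(0.75) for m in metrics],
        "mean": [per_frame[m].mean() for m in metrics],
    })
    return InteractionReport(per_frame=per_frame, summary=summary)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd_ca(frame: np.ndarray, reference: np.ndarray,
            fit: bool = True) -> float:
    """C-alpha RMSD between two matched coordinate sets, in nm.

    With ``fit=True`` the frame is first optimally superposed on the
    reference (least-squares rigid rotation after centring, Kabsch); with
    ``fit=False`` the RMSD is computed on the raw coordinates.
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    if fit:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(b, a)
        a = rot.apply(a)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
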