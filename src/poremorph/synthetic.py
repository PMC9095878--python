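"""Synthetic AFM scenes and pseudo-monomer fixtures.

Emulates topographs of membrane-inserted pore-forming oligomers: a flat
supported lipid membrane at a reference level, ring/arc/slit-shaped
oligomers protruding ~3.4 nm above it with crest diameters of ~20-34 nm,
lumens either plugged (pre-pore) or penetrating the membrane by >= 2 nm
(pore), imaged by a finite spherical tip (grayscale dilation), slow-axis
drift (pure y stretch) and Gaussian scan noise.

The defaults mirror the measured populations the analysis modules are
validated against: ring crest diameters Normal(26.3, 2.2^2) nm, protrusion
heights 3.4 nm (arcs, rings) and 3.5 nm (slits), ring stoichiometries
centred on 30 subunits.

All randomness flows from a single integer seed; independent sub-streams
are split off with :class:`numpy.random.SeedSequence` spawning so that the
pixel-noise, line-noise and population streams never interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import CubicSpline

from .morphometry import PORE_THRESHOLD_NM
from .topograph import Topograph

__all__ = [
    "ParticleSpec", "SceneSpec", "MonomerFixture", "MonomerGeometry",
    "PopulationParams", "render_scene", "render_tip_dilation",
    "make_monomer_fixture", "sample_population", "ground_truth_table",
]

# Generator defaults (configured truths for the downstream round-trip checks).
DEFAULT_RING_DIAMETER_NM = 26.3   # mean crest diameter of rings
DEFAULT_RING_DIAMETER_SD_NM = 2.2
DEFAULT_HEIGHT_NM = {"ring": 3.4, "arc": 3.4, "slit": 3.5}
DEFAULT_SUBUNIT_WIDTH_NM = 1.1    # Gaussian sigma of one protomer bump;
                                  # chosen so ~30 bumps on a 26 nm crest stay
                                  # resolvable at ~2 nm lateral resolution
PORE_FLOOR_NM = -3.0              # rendered lumen floor of an open pore
DEFAULT_N = 30                    # most frequent ring stoichiometry

_SHAPES = ("ring", "arc", "slit")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class ParticleSpec:
    """Geometry of one oligomer to render.

    ``lumen_depth`` is the lumen floor relative to the membrane (<= 0);
    ``-inf`` is accepted as a sentinel for a fully open pore and rendered at
    :data:`PORE_FLOOR_NM`. ``pore_state`` defaults to the value implied by
    ``lumen_depth`` and the 2 nm call threshold.
    """

    center: tuple[float, float]            # (x, y) in nm
    shape: str = "ring"
    n_subunits: int = DEFAULT_N
    arc_span: int | None = None            # subunits per arc (arc/slit)
    crest_diameter: float = DEFAULT_RING_DIAMETER_NM
    height: float = 3.4                    # subunit bump height above membrane
    subunit_width: float = DEFAULT_SUBUNIT_WIDTH_NM
    lumen_depth: float = 0.0
    phase_deg: float = 0.0                 # rotation of the bump pattern
    pore_state: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.n_subunits < 3:
            raise ValueError("n_subunits must be >= 3")
        if self.crest_diameter <= 0:
            raise ValueError("crest_diameter must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.subunit_width <= 0:
            raise ValueError("subunit_width must be positive")
        if self.lumen_depth > 0:
            raise ValueError("lumen_depth must be <= 0 (depth below membrane)")
        if self.shape in ("arc", "slit"):
            if self.arc_span is None:
                self.arc_span = max(3, self.n_subunits // 2)
            if not 2 <= self.arc_span <= self.n_subunits:
                raise ValueError("arc_span must be in [2, n_subunits]")
        implied = "pore" if self.rendered_lumen_depth <= -PORE_THRESHOLD_NM \
            else "pre_pore"
        if self.pore_state is None:
            self.pore_state = implied
        elif self.pore_state != implied:
            raise ValueError(
                f"pore_state {self.pore_state!r} inconsistent with "
                f"lumen_depth {self.lumen_depth} and the "
                f"{PORE_THRESHOLD_NM} nm rule")

    @property
    def rendered_lumen_depth(self) -> float:
        """Lumen floor actually rendered (-inf sentinel -> pore floor)."""
        return PORE_FLOOR_NM if np.isneginf(self.lumen_depth) \
            else self.lumen_depth

    @property
    def footprint_radius(self) -> float:
        """Radius (nm) of the disc the particle occupies, with bump skirt."""
        return self.crest_diameter / 2 + 3 * self.subunit_width


@dataclass
class SceneSpec:
    """Full description of one synthetic topograph."""

    image_size: tuple[int, int] = (128, 128)       # (rows, cols)
    pixel_size: float = 0.5                        # nm/px
    membrane_level: float = 0.0                    # nm
    particles: list[ParticleSpec] = field(default_factory=list)
    noise_sd: float = 0.0                          # nm, per pixel
    line_noise_sd: float = 0.0                     # nm, per scan line
    drift_y_scale: float = 1.0                     # slow-axis stretch factor
    tip_radius: float = 0.0                        # nm
    rng_seed: int = 0
    overlap_tolerance: float = 0.0                 # allowed footprint overlap, nm

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.noise_sd < 0 or self.line_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.drift_y_scale <= 0:
            raise ValueError("drift_y_scale must be positive")
        if self.tip_radius < 0:
            raise ValueError("tip_radius must be >= 0")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _subunit_centers(p: ParticleSpec) -> np.ndarray:
    """(n, 2) array of bump centres in nm, relative to the particle centre."""
    radius = p.crest_diameter / 2
    step = 2 * math.pi / p.n_subunits
    phase = math.radians(p.phase_deg)
    if p.shape == "ring":
        angles = phase + step * np.arange(p.n_subunits)
        return radius * np.column_stack([np.cos(angles), np.sin(angles)])
    # An arc spans ``arc_span`` contiguous crest positions, bulge toward +y.
    span = step * (p.arc_span - 1)
    angles = math.pi / 2 - span / 2 + step * np.arange(p.arc_span) + phase
    arc = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    if p.shape == "arc":
        return arc
    # Slit: the arc plus its image under a two-fold rotation, with the two
    # arcs shifted together so terminal subunits face at one crest spacing.
    spacing = p.crest_diameter * math.sin(math.pi / p.n_subunits)
    chord_y = radius * math.cos(span / 2)     # y of the terminal subunits
    shift = chord_y - spacing / 2
    upper = arc - [0.0, shift]
    lower = -upper                            # 180 deg rotation about origin
    return np.vstack([upper, lower])


def _render_surface(spec: SceneSpec) -> np.ndarray:
    """Noise-free, dilation-free, drift-free surface in nm."""
    rows, cols = spec.image_size
    px = spec.pixel_size
    surface = np.zeros((rows, cols))
    extent = (rows * px, cols * px)

    # Overlap / bounds checks on particle footprints.
    for i, p in enumerate(spec.particles):
        cx, cy = p.center
        r = p.footprint_radius
        if not (r <= cx <= extent[1] - r and r <= cy <= extent[0] - r):
            raise ValueError(f"particle {i} extends outside the field of view")
        for j, q in enumerate(spec.particles[:i]):
            dist = math.hypot(cx - q.center[0], cy - q.center[1])
            if dist < p.footprint_radius + q.footprint_radius \
                    - spec.overlap_tolerance:
                raise ValueError(f"particles {j} and {i} overlap beyond "
                                 "the configured tolerance")

    y_nm = np.arange(rows)[:, None] * px
    x_nm = np.arange(cols)[None, :] * px
    for p in spec.particles:
        cx, cy = p.center
        w = p.subunit_width
        half = p.footprint_radius
        r0 = max(0, int((cy - half) / px))
        r1 = min(rows, int(np.ceil((cy + half) / px)) + 1)
        c0 = max(0, int((cx - half) / px))
        c1 = min(cols, int(np.ceil((cx + half) / px)) + 1)
        ywin = y_nm[r0:r1] - cy
        xwin = x_nm[:, c0:c1] - cx

        # Protomer bumps, max-combined so the crest height stays exactly h.
        bumps = np.zeros((r1 - r0, c1 - c0))
        for bx, by in _subunit_centers(p):
            d2 = (xwin - bx) ** 2 + (ywin - by) ** 2
            np.maximum(bumps, p.height * np.exp(-d2 / (2 * w * w)), out=bumps)

        # Lumen: a plateau at the configured floor inside the crest circle,
        # tapering to the membrane over one subunit width.  The taper ends
        # two widths inside the crest so bump peaks are unaffected.  The
        # (negative) lumen is added after combining the positive bumps with
        # the membrane, or a pore floor below 0 would be clipped away.
        lumen = 0.0
        depth = p.rendered_lumen_depth
        if depth < 0:
            r_in = p.crest_diameter / 2 - 2 * w
            if r_in > 0:
                rr = np.hypot(xwin + 0 * ywin, ywin + 0 * xwin)
                t = np.clip((r_in - rr) / w, 0.0, 1.0)
                lumen = depth * (0.5 - 0.5 * np.cos(math.pi * t))
        surface[r0:r1, c0:c1] = np.maximum(surface[r0:r1, c0:c1],
                                           bumps) + lumen

    return surface + spec.membrane_level


def _tip_structure(tip_radius: float, pixel_size: tuple[float, float]
                   ) -> np.ndarray:
    """Grayscale structuring element of a spherical tip (apex at 0)."""
    dy, dx = pixel_size
    ky = int(math.floor(tip_radius / dy))
    kx = int(math.floor(tip_radius / dx))
    yy = np.arange(-ky, ky + 1)[:, None] * dy
    xx = np.arange(-kx, kx + 1)[None, :] * dx
    d2 = yy * yy + xx * xx
    s = np.full(d2.shape, -np.inf)
    inside = d2 <= tip_radius ** 2
    s[inside] = np.sqrt(tip_radius ** 2 - d2[inside]) - tip_radius
    return s


def render_tip_dilation(surface: Topograph | np.ndarray,
                        tip_radius: float,
                        pixel_size: float | tuple[float, float] | None = None,
                        ) -> Topograph | np.ndarray:
    """Image a surface with a finite spherical tip (grayscale dilation).

    The recorded height at each pixel is the apex height of a sphere of
    radius ``tip_radius`` lowered until it first touches the surface, the
    standard forward model of AFM tip convolution.  The output is pointwise
    >= the input and a flat input is returned unchanged.
    """
    if tip_radius < 0:
        raise ValueError("tip_radius must be >= 0")
    if isinstance(surface, Topograph):
        px = surface.pixel_size
        heights = surface.heights
    else:
        if pixel_size is None:
            raise ValueError("pixel_size required for bare arrays")
        px = (pixel_size, pixel_size) if np.isscalar(pixel_size) \
            else tuple(pixel_size)
        heights = np.asarray(surface, dtype=float)
    if tip_radius == 0:
        out = heights.copy()
    else:
        structure = _tip_structure(tip_radius, px)
        out = ndi.grey_dilation(heights, structure=structure, mode="nearest")
    if isinstance(surface, Topograph):
        return surface.with_heights(out, f"tip_dilation r={tip_radius} nm")
    return out


def _apply_drift(heights: np.ndarray, scale: float) -> np.ndarray:
    """Stretch the slow (y) axis by ``scale``: drifted(y) = ideal(y/scale)."""
    if scale == 1.0:
        return heights
    rows = heights.shape[0]
    src = np.clip(np.arange(rows) / scale, 0, rows - 1)
    spline = CubicSpline(np.arange(rows), heights, axis=0)
    return spline(src)


def render_scene(spec: SceneSpec) -> Topograph:
    """Render a synthetic topograph from a scene description.

    Pipeline: analytic surface -> tip dilation -> slow-axis drift stretch ->
    pixel and scan-line Gaussian noise.  Deterministic for a fixed
    ``spec.rng_seed``.
    """
    surface = _render_surface(spec)
    if spec.tip_radius > 0:
        surface = render_tip_dilation(surface, spec.tip_radius,
                                      spec.pixel_size)
    surface = _apply_drift(surface, spec.drift_y_scale)

    noise_seq, line_seq = np.random.SeedSequence(spec.rng_seed).spawn(2)
    if spec.noise_sd > 0:
        surface = surface + np.random.default_rng(noise_seq).normal(
            0.0, spec.noise_sd, surface.shape)
    if spec.line_noise_sd > 0:
        offsets = np.random.default_rng(line_seq).normal(
            0.0, spec.line_noise_sd, surface.shape[0])
        surface = surface + offsets[:, None]
    return Topograph(surface, (spec.pixel_size, spec.pixel_size),
                     channel="trace",
                     provenance=[f"render_scene seed={spec.rng_seed}"])


def ground_truth_table(spec: SceneSpec):
    """Ground-truth particle table for a scene, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, p in enumerate(spec.particles):
        rows.append({
            "particle_id": i,
            "shape": p.shape,
            "N": p.n_subunits,
            "crest_diameter_nm": p.crest_diameter,
            "height_nm": p.height,
            "lumen_depth_nm": p.rendered_lumen_depth,
            "pore_state": p.pore_state,
            "center_x_nm": p.center[0],
            "center_y_nm": p.center[1],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pseudo-monomer fixture
# ---------------------------------------------------------------------------

@dataclass
class MonomerGeometry:
    """Tunable geometry of the pseudo-monomer (all lengths in nm).

    The local frame is the pose convention used for oligomer building:
    z = membrane normal and hairpin long axis, +x = radial-outward,
    +y = tangential (toward the next subunit in a ring).
    """

    residue_rise: float = 0.35        # per-residue rise along a strand
    neighbor_spacing: float = 1.6     # design centre-to-centre spacing at
                                      # which inter-subunit bonds are formed
    hbond_length: float = 0.30        # designed donor-acceptor N...O distance
    saltbridge_length: float = 0.36   # designed charged-group distance
    strand_pleat: float = 0.06        # out-of-plane zig-zag of strands
    hairpin_top: float = 0.65         # z of the top hairpin residue
    head_center_z: float = 2.0
    head_semiaxes: tuple[float, float, float] = (1.1, 0.5, 1.2)   # (x, y, z)
    head_tilt_deg: float = 0.0        # rotation of the head about +y (tau)
    head_roll_deg: float = 0.0        # rotation of the head about +z (alpha)
    atom_radius: float = 0.2          # rendering radius of one pseudo-atom


@dataclass
class MonomerFixture:
    """A synthetic stand-in for a pore-forming protomer.

    Two antiparallel pseudo-beta strands ("hairpin") run along z; the strand
    facing +y carries backbone N-H donors, the strand facing -y carbonyl-O
    acceptors, so that adjacent subunits placed one ``neighbor_spacing``
    apart along the ring tangent form one hydrogen bond per strand residue.
    An ellipsoidal "head" block sits above the membrane with one donor, one
    acceptor, one positively and one negatively charged contact atom on its
    tangential faces.  A short "connector" joins the two blocks.
    """

    atom_names: np.ndarray            # str array, n atoms
    elements: np.ndarray              # str array
    res_ids: np.ndarray               # int array
    coords: np.ndarray                # (n, 3) nm, local frame
    domain_map: dict[str, set[int]]   # domain -> residue id set
    geometry: MonomerGeometry
    radial_axis: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def domain_atom_mask(self, domain: str) -> np.ndarray:
        ids = self.domain_map[domain]
        return np.isin(self.res_ids, sorted(ids))

    def domain_coords(self, domain: str) -> np.ndarray:
        return self.coords[self.domain_atom_mask(domain)]


def _rotation(axis: str, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(axis)


def make_monomer_fixture(n_head_atoms: int = 30,
                         n_hairpin_atoms: int = 14,
                         geometry: MonomerGeometry | None = None,
                         rng_seed: int = 0) -> MonomerFixture:
    """Build the pseudo-monomer.

    ``n_hairpin_atoms`` is the residue count per strand; each strand residue
    contributes its edge atoms (N+H on the donor strand, O on the acceptor
    strand) plus a CA trace atom.  ``n_head_atoms`` pseudo-CA atoms are drawn
    uniformly inside the head ellipsoid (reproducible for a fixed seed).
    """
    g = geometry or MonomerGeometry()
    if n_head_atoms < 3 or n_hairpin_atoms < 3:
        raise ValueError("need at least 3 atoms per domain")
    if g.strand_pleat <= 0 or min(g.head_semiaxes) <= 0:
        raise ValueError("degenerate domain geometry")

    names, elements, res_ids, coords = [], [], [], []
    half_w = (g.neighbor_spacing - g.hbond_length) / 2  # strand edge |y|
    z_top = g.hairpin_top
    rid = 0

    def add(name, element, residue, xyz):
        names.append(name)
        elements.append(element)
        res_ids.append(residue)
        coords.append(xyz)

    # Strand A (acceptor edge, -y), running down; strand B (donor edge, +y).
    # Only the CA trace carries the pleat, with opposite phase on the two
    # strands at each height, so the block's cross-covariances cancel
    # exactly and its principal axes are exactly (z, y, x).
    hairpin_res = set()
    for k in range(n_hairpin_atoms):
        z = z_top - k * g.residue_rise
        pleat = g.strand_pleat * (1 if k % 2 == 0 else -1)
        rid += 1
        hairpin_res.add(rid)
        add("CA", "C", rid, [pleat, -half_w + 0.1, z])
        add("O", "O", rid, [0.0, -half_w, z])
    for k in range(n_hairpin_atoms):
        level = n_hairpin_atoms - 1 - k
        z = z_top - level * g.residue_rise
        pleat = g.strand_pleat * (1 if level % 2 == 0 else -1)
        rid += 1
        hairpin_res.add(rid)
        add("CA", "C", rid, [-pleat, half_w - 0.1, z])
        add("N", "N", rid, [0.0, half_w, z])
        add("H", "H", rid, [0.0, half_w + 0.1, z])

    # Connector: three residues bridging hairpin top and head bottom.
    connector_res = set()
    for k in range(3):
        rid += 1
        connector_res.add(rid)
        z = z_top + (k + 1) * (g.head_center_z - g.head_semiaxes[2]
                               - z_top) / 4
        add("CA", "C", rid, [0.05 * (k - 1), 0.0, z])

    # Head: ellipsoidal pseudo-CA cloud plus apex and face contact atoms.
    # The head's principal axes must be exactly (z, x, y) in the untilted
    # pose (they define the tau/chi/alpha zero references downstream), so
    # the seeded cloud is rotated into its own principal frame and rescaled
    # to exact per-axis variances, and every off-axis contact atom comes
    # with moment-balancing partners that cancel all cross-covariances.
    ax, ay, az = g.head_semiaxes
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    k = np.arange(n_head_atoms)
    cos_t = 1 - 2 * (k + 0.5) / n_head_atoms
    sin_t = np.sqrt(1 - cos_t ** 2)
    phi = golden * k
    radii = ((k + 0.5) / n_head_atoms) ** (1 / 3)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    cloud = dirs * radii[:, None] + rng.normal(0.0, 0.05, (n_head_atoms, 3))
    cloud -= cloud.mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(cloud.T, bias=True))
    principal = cloud @ evecs[:, ::-1]        # columns: falling variance
    principal /= principal.std(axis=0)
    # Largest target variance along z, middle along x, smallest along y.
    scale = np.array([ax, ay, az]) / math.sqrt(5.0)
    cloud = np.column_stack([principal[:, 1] * scale[0],
                             principal[:, 2] * scale[1],
                             principal[:, 0] * scale[2]])
    face_y = (g.neighbor_spacing - g.hbond_length) / 2
    sb_y = (g.neighbor_spacing - g.saltbridge_length) / 2
    # Residue groups: the donor N and its H must share a residue (that is
    # how donors are recognised); the CB atoms balance the cross moments of
    # their group partners so the head covariance stays exactly diagonal.
    head_groups = [[("CA", "C", p)] for p in cloud]
    head_groups.append([("CA", "C", np.array([0.0, 0.0, az]))])  # apex
    head_groups += [
        [("N", "N", [0.0, face_y, 0.3]),                   # donor, +y face
         ("H", "H", [0.0, face_y + 0.1, 0.3])],
        [("O", "O", [0.0, -face_y, 0.3]),                  # acceptor, -y face
         ("CB", "C", [0.0, -face_y - 0.1, 0.3])],          # balances H
        [("NZ", "N", [0.3, sb_y, -0.3]),                   # positive charge
         ("CB", "C", [-0.3, sb_y, -0.3])],
        [("OE1", "O", [0.3, -sb_y, -0.3]),                 # negative charge
         ("CB", "C", [-0.3, -sb_y, -0.3])],
    ]
    tilt = _rotation("z", g.head_roll_deg) @ _rotation("y", g.head_tilt_deg)
    head_res = set()
    for group in head_groups:
        rid += 1
        head_res.add(rid)
        for name, element, p in group:
            add(name, element, rid,
                tilt @ np.asarray(p, dtype=float) + [0, 0, g.head_center_z])

    fixture = MonomerFixture(
        atom_names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), coords=np.array(coords),
        domain_map={"hairpin": hairpin_res, "connector": connector_res,
                    "head": head_res},
        geometry=g)

    # Reject geometries whose domains have no well-defined principal frame.
    for domain in ("hairpin", "head"):
        pts = fixture.domain_coords(domain)
        evals = np.linalg.eigvalsh(np.cov(pts.T))
        if np.min(np.diff(np.sort(evals))) < 1e-9:
            raise ValueError(f"degenerate {domain} domain geometry")
    return fixture


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationParams:
    """Distributions a particle population is drawn from.

    Crest diameters are Normal(diameter_mean, diameter_sd^2); heights are
    Normal around the shape's default protrusion height (sd 0 by default,
    i.e. set exactly to the configured value); ring stoichiometry follows
    the diameter through the default crest spacing so that larger rings
    carry more subunits.
    """

    shape: str = "ring"
    diameter_mean: float = DEFAULT_RING_DIAMETER_NM
    diameter_sd: float = DEFAULT_RING_DIAMETER_SD_NM
    height_mean: float | None = None      # default: shape's configured height
    height_sd: float = 0.0
    pore_fraction: float = 0.0            # fraction rendered as open pores
    arc_span_fraction: float = 0.5        # arc length as a fraction of a ring
    subunit_width: float = DEFAULT_SUBUNIT_WIDTH_NM

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.diameter_sd < 0 or self.height_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if not 0 <= self.pore_fraction <= 1:
            raise ValueError("pore_fraction must be in [0, 1]")


def sample_population(params: PopulationParams, n: int,
                      rng_seed: int = 0,
                      center: tuple[float, float] = (0.0, 0.0),
                      ) -> list[ParticleSpec]:
    """Draw ``n`` particle specs from the configured distributions.

    All specs share ``center``; callers rendering many particles place each
    spec in its own scene (or re-centre them).  Reproducible for a fixed
    seed; two equal seeds give identical populations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    height_mean = params.height_mean
    if height_mean is None:
        height_mean = DEFAULT_HEIGHT_NM[params.shape]
    spacing0 = math.pi * DEFAULT_RING_DIAMETER_NM / DEFAULT_N
    out = []
    for _ in range(n):
        d = float(rng.normal(params.diameter_mean, params.diameter_sd)) \
            if params.diameter_sd > 0 else params.diameter_mean
        d = max(d, 10.0)
        h = float(rng.normal(height_mean, params.height_sd)) \
            if params.height_sd > 0 else height_mean
        n_sub = max(3, round(math.pi * d / spacing0))
        pore = rng.uniform() < params.pore_fraction
        span = None
        if params.shape in ("arc", "slit"):
            span = max(3, round(params.arc_span_fraction * n_sub))
        out.append(ParticleSpec(
            center=center, shape=params.shape, n_subunits=n_sub,
            arc_span=span, crest_diameter=d, height=h,
            subunit_width=params.subunit_width,
            lumen_depth=PORE_FLOOR_NM if pore else 0.0,
            phase_deg=float(rng.uniform(0, 360))))
    return out


def scene_for_particle(p: ParticleSpec, *, pixel_size: float = 0.5,
                       noise_sd: float = 0.0, tip_radius: float = 0.0,
                       rng_seed: int = 0, margin: float = 4.0) -> SceneSpec:
    """A minimal single-particle scene centred on ``p`` (testing helper)."""
    half = p.footprint_radius + tip_radius + margin
    npx = max(64, int(np.ceil(2 * half / pixel_size)))
    extent = npx * pixel_size
    q = replace(p, center=(extent / 2, extent / 2))
    return SceneSpec(image_size=(npx, npx), pixel_size=pixel_size,
                     particles=[q], noise_sd=noise_sd,
                     tip_radius=tip_radius, rng_seed=rng_seed)
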