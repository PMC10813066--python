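"""Synthetic tooth-root meshes and confocal-style height maps with ground truth.

Real inputs to the pipeline are micro-CT-derived surface meshes (a dentine
core and its cementum envelope) and confocal height maps.  This module
generates both with a fully analytic ground truth, so every downstream
operation (thickness mapping, localization, shape classification, topography
scoring) can be tested for parameter recovery.

Roots are tapered superellipse tubes capped by a hemispherical apex — the
simplest closed shape with four distinguishable anatomical sides.  The
cementum envelope is the dentine mesh displaced outward along vertex normals
by an analytic thickness field:

    base + angular/axial gradient + shape primitives + correlated texture

Anatomical convention (shared with the partitioning code): the buccal
reference direction is ``<``, its opposite is lingual ``>``, and the ±90°
rotations about the root axis are mesial ``m`` / distal ``d``.  Root thirds
are numbered from the apex: 1 apical, 2 middle, 3 cervical.

All randomness flows from one explicit integer seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .topography import HeightMap

SIDE_ANGLE = {"<": 0.0, "m": 0.5 * np.pi, ">": np.pi, "d": 1.5 * np.pi}


@dataclass(frozen=True)
class RootMesh:
    """A closed triangulated root surface with landmarks and orientation."""

    vertices: np.ndarray          # (n, 3) mm
    triangles: np.ndarray         # (m, 3) vertex indices
    apex_point: np.ndarray        # 3D point, mm
    cej_ring_height: float | None # axial coordinate of the CEJ (mm from apex); None if crownless
    axis: np.ndarray              # unit vector apex -> cervix
    buccal_reference: np.ndarray  # unit vector orthogonal to axis

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def save(self, path) -> None:
        """Write PLY or OBJ (by extension)."""
        self.to_trimesh().export(str(path))


@dataclass(frozen=True)
class ShapePrimitive:
    """One atypical apposition primitive with its ground-truth dimensions.

    Kinds follow the field's typology: NOD single node (> 2 mm), Nds nodule
    cluster (each < 2 mm), OG atypical overgrowth (> 3 mm, ≥ 2 sides), RID
    oblique ridge field (each ridge width < 1 mm, length > 2 mm, height
    > 0.5 mm), LSP localized spike-like projection (< 2 mm, spiky).
    """

    kind: str                     # NOD | Nds | OG | RID | LSP
    third: int = 2                # axial center: 1 apical, 2 middle, 3 cervical
    side: str = "d"
    diameter_mm: float = 2.5
    height_mm: float = 1.0
    length_mm: float = 2.5       # RID only
    count: int = 4               # Nds bumps / RID ridges / LSP spikes
    obliquity_deg: float = 45.0  # RID only
    angle_offset_deg: float = 0.0

    def __post_init__(self):
        if self.kind not in ("NOD", "Nds", "OG", "RID", "LSP"):
            raise ValueError(f"unknown shape primitive kind {self.kind!r}")
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValueError("primitive dimensions must be positive")
        if self.third not in (1, 2, 3) or self.side not in SIDE_ANGLE:
            raise ValueError(f"invalid primitive position ({self.third}, {self.side!r})")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the seed fully determines the output."""

    root_length_mm: float = 12.0
    base_radius_mm: float = 2.2
    taper: float = 0.35
    base_cementum_um: float = 500.0
    # (direction side, amplitude um, axial-center third) or None
    angular_gradient: tuple[str, float, int] | None = None
    shape_primitives: tuple[ShapePrimitive, ...] = ()
    # (amplitude um P2V, correlation length um, relief density per mm^2)
    texture: tuple[float, float, float] = (100.0, 500.0, 0.0)
    nm_fraction: float = 0.0
    seed: int = 0
    n_theta: int = 72
    n_axial: int = 90

    def __post_init__(self):
        if self.root_length_mm <= 0 or self.base_radius_mm <= 0:
            raise ValueError("root dimensions must be positive")
        if not 0 < self.taper <= 1:
            raise ValueError(f"taper must be in (0, 1], got {self.taper}")
        if self.base_cementum_um < 0:
            raise ValueError("base cementum thickness must be >= 0")
        if not 0 <= self.nm_fraction < 0.3:
            raise ValueError("nm_fraction must be in [0, 0.3)")
        if self.angular_gradient is not None:
            side, amp, third = self.angular_gradient
            if side not in SIDE_ANGLE or amp < 0 or third not in (1, 2, 3):
                raise ValueError(f"invalid angular gradient {self.angular_gradient}")


# ---------------------------------------------------------------------------
# dentine core

_SUPERELLIPSE_EXP = 2.5


def _profile_radius(z: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Tube radius along the axis: linear taper with a hemispherical apex cap."""
    length = spec.root_length_mm
    r_tube = spec.base_radius_mm * (spec.taper + (1 - spec.taper) * z / length)
    z_cap = spec.base_radius_mm * spec.taper
    cap = np.ones_like(z)
    in_cap = z < z_cap
    cap[in_cap] = np.sqrt(np.clip(1 - ((z_cap - z[in_cap]) / z_cap) ** 2, 0, 1))
    return r_tube * cap


def _make_dentine(spec: SyntheticSpec) -> tuple[RootMesh, np.ndarray, np.ndarray]:
    """Build the dentine mesh; also return per-vertex (z, theta) coordinates."""
    nt, nz = spec.n_theta, spec.n_axial
    length = spec.root_length_mm
    theta = np.arange(nt) * 2 * np.pi / nt
    # ring stations: skip z=0 (apex point vertex) and include z=L (rim)
    z_st = np.linspace(length / nz, length, nz)
    rho = _profile_radius(z_st, spec)
    f = (np.abs(np.cos(theta)) ** _SUPERELLIPSE_EXP
         + np.abs(np.sin(theta)) ** _SUPERELLIPSE_EXP) ** (-1 / _SUPERELLIPSE_EXP)
    r = rho[:, None] * f[None, :]
    x = r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]
    zz = np.broadcast_to(z_st[:, None], r.shape)
    # cervical cap: concentric shrinking rings keep triangle size bounded
    n_cap = 4
    cap_scales = [(n_cap - i) / (n_cap + 1) for i in range(n_cap)]
    cap_rings = [
        np.column_stack([s * x[-1], s * y[-1], np.full(nt, length)])
        for s in cap_scales
    ]
    ring_verts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])
    apex = np.array([0.0, 0.0, 0.0])
    top_center = np.array([0.0, 0.0, length])
    vertices = np.vstack([ring_verts] + cap_rings + [apex, top_center])
    n_rings_total = nz + n_cap
    i_apex = n_rings_total * nt
    i_top = i_apex + 1

    faces = []
    idx = lambda i, j: i * nt + (j % nt)  # noqa: E731
    for j in range(nt):  # apex fan (ring 0)
        faces.append([i_apex, idx(0, j + 1), idx(0, j)])
    for i in range(n_rings_total - 1):  # tube + cap quads
        for j in range(nt):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(nt):  # innermost cap ring fan
        faces.append([i_top, idx(n_rings_total - 1, j), idx(n_rings_total - 1, j + 1)])
    tri = np.asarray(faces, dtype=np.int64)

    mesh = trimesh.Trimesh(vertices, tri, process=False)
    if not mesh.is_winding_consistent:
        trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        trimesh.repair.fix_normals(mesh)
    root = RootMesh(
        vertices=mesh.vertices.view(np.ndarray).copy(),
        triangles=mesh.faces.view(np.ndarray).copy(),
        apex_point=apex,
        cej_ring_height=length,
        axis=np.array([0.0, 0.0, 1.0]),
        buccal_reference=np.array([1.0, 0.0, 0.0]),
    )
    vz = root.vertices[:, 2]
    vtheta = np.mod(np.arctan2(root.vertices[:, 1], root.vertices[:, 0]), 2 * np.pi)
    return root, vz, vtheta


# ---------------------------------------------------------------------------
# analytic thickness field


def _wrap_angle(dtheta: np.ndarray) -> np.ndarray:
    return (dtheta + np.pi) % (2 * np.pi) - np.pi


def _third_center(third: int, length: float) -> float:
    return length * (2 * third - 1) / 6


def _gradient_field(vz, vtheta, spec: SyntheticSpec) -> np.ndarray:
    side, amp_um, third = spec.angular_gradient
    dtheta = _wrap_angle(vtheta - SIDE_ANGLE[side])
    angular = ((1 + np.cos(dtheta)) / 2) ** 2
    zc = _third_center(third, spec.root_length_mm)
    axial = np.exp(-((vz - zc) / (spec.root_length_mm / 3)) ** 2)
    return amp_um * angular * axial


def _surface_distance(vz, vtheta, z0, theta0, rho0) -> np.ndarray:
    """Approximate geodesic distance on the tube surface, mm."""
    return np.hypot(vz - z0, rho0 * _wrap_angle(vtheta - theta0))


def _cap_bump(d_mm, radius_mm, height_mm) -> np.ndarray:
    """Spherical-cap profile peaking exactly at ``height_mm``."""
    return height_mm * np.sqrt(np.clip(1 - (d_mm / radius_mm) ** 2, 0, 1))


def _primitive_field(vz, vtheta, prim: ShapePrimitive, spec: SyntheticSpec,
                     rng: np.random.Generator) -> np.ndarray:
    length = spec.root_length_mm
    z0 = _third_center(prim.third, length)
    theta0 = SIDE_ANGLE[prim.side] + np.deg2rad(prim.angle_offset_deg)
    rho0 = float(_profile_radius(np.array([z0]), spec)[0])
    radius = prim.diameter_mm / 2
    out = np.zeros_like(vz)

    if prim.kind in ("NOD", "OG"):
        d = _surface_distance(vz, vtheta, z0, theta0, rho0)
        bump = _cap_bump(d, radius, prim.height_mm)
        if prim.kind == "OG":
            # irregular angular modulation, = 1 at the center so the peak is exact
            bump *= 0.75 + 0.25 * np.cos(3 * _wrap_angle(vtheta - theta0))
        out += bump
    elif prim.kind == "Nds":
        spread = max(1.4 * prim.diameter_mm, 0.9)
        for k in range(prim.count):
            ang = 2 * np.pi * k / prim.count + rng.uniform(-0.25, 0.25)
            dz = spread * np.cos(ang)
            dth = spread * np.sin(ang) / rho0
            d = _surface_distance(vz, vtheta, z0 + dz, theta0 + dth, rho0)
            out = np.maximum(out, _cap_bump(d, radius, prim.height_mm))
    elif prim.kind == "RID":
        alpha = np.deg2rad(prim.obliquity_deg)
        u = vz - z0
        w = rho0 * _wrap_angle(vtheta - theta0)
        along = u * np.cos(alpha) + w * np.sin(alpha)
        across = -u * np.sin(alpha) + w * np.cos(alpha)
        width = prim.diameter_mm            # one ridge's width (< 1 mm)
        spacing = max(2.0 * width, 1.4)
        half_len = prim.length_mm / 2
        taper_mm = 0.4
        envelope = np.clip((half_len - np.abs(along)) / taper_mm, 0, 1)
        for k in range(prim.count):
            bk = (k - (prim.count - 1) / 2) * spacing
            cross = np.clip(1 - ((across - bk) / (width / 2)) ** 2, 0, 1)
            out = np.maximum(out, prim.height_mm * cross * envelope)
    elif prim.kind == "LSP":
        d = _surface_distance(vz, vtheta, z0, theta0, rho0)
        out += _cap_bump(d, radius, prim.height_mm * 0.55)
        spike_h = prim.height_mm * 0.45
        spike_sigma = 0.09
        spikes = np.zeros_like(vz)
        for k in range(prim.count):
            rr = rng.uniform(0, 0.5 * radius)
            aa = rng.uniform(0, 2 * np.pi)
            dz, dw = rr * np.cos(aa), rr * np.sin(aa)
            ds = _surface_distance(vz, vtheta, z0 + dz, theta0 + dw / rho0, rho0)
            spikes = np.maximum(spikes, spike_h * np.exp(-(ds / spike_sigma) ** 2))
        out += spikes
    return out * 1000.0  # mm -> um


def _mesh_texture(mesh: trimesh.Trimesh, amplitude_um: float,
                  rng: np.random.Generator, n_smooth: int = 4) -> np.ndarray:
    """Correlated per-vertex noise, peak-to-valley scaled to ``amplitude_um``."""
    if amplitude_um <= 0:
        return np.zeros(len(mesh.vertices))
    noise = rng.standard_normal(len(mesh.vertices))
    adj = mesh.vertex_adjacency_graph
    neighbors = [np.fromiter(adj.neighbors(i), dtype=np.int64) for i in range(len(mesh.vertices))]
    for _ in range(n_smooth):
        smoothed = np.array([noise[nb].mean() if len(nb) else noise[i]
                             for i, nb in enumerate(neighbors)])
        noise = 0.5 * noise + 0.5 * smoothed
    p2v = noise.max() - noise.min()
    return amplitude_um * (noise - noise.min()) / p2v if p2v > 0 else noise * 0


def make_root_pair(spec: SyntheticSpec) -> tuple[RootMesh, RootMesh, np.ndarray]:
    """Generate (dentine, cementum, truth) for one synthetic root.

    The cementum mesh shares the dentine topology: each dentine vertex is
    displaced outward along its normal by the analytic thickness field.  The
    returned truth is that field in µm, aligned to the cementum vertices.

    Raises ``ValueError`` when the requested displacement is large enough,
    relative to the root radius, to risk a self-intersecting envelope.
    """
    rng = np.random.default_rng(spec.seed)
    dentine, vz, vtheta = _make_dentine(spec)
    thickness_um = np.full(len(dentine.vertices), float(spec.base_cementum_um))
    if spec.angular_gradient is not None:
        thickness_um += _gradient_field(vz, vtheta, spec)
    for prim in spec.shape_primitives:
        thickness_um += _primitive_field(vz, vtheta, prim, spec, rng)
    dmesh = dentine.to_trimesh()
    thickness_um += _mesh_texture(dmesh, spec.texture[0], rng)

    # outward displacement of a convex-ish tube is safe until it approaches
    # the tube radius itself (fold-over at the apex cap)
    max_disp_mm = thickness_um.max() / 1000.0
    if max_disp_mm > 0.8 * spec.base_radius_mm:
        raise ValueError(
            f"displacement {max_disp_mm:.2f} mm too large for base radius "
            f"{spec.base_radius_mm} mm: cementum envelope would self-intersect"
        )
    normals = dmesh.vertex_normals.view(np.ndarray)
    cem_vertices = dentine.vertices + normals * (thickness_um[:, None] / 1000.0)
    cementum = RootMesh(
        vertices=cem_vertices,
        triangles=dentine.triangles.copy(),
        apex_point=cem_vertices[np.argmin(cem_vertices[:, 2])],
        # measured from the (displaced) cementum apex to its cervical rim
        cej_ring_height=float(cem_vertices[:, 2].max() - cem_vertices[:, 2].min()),
        axis=dentine.axis.copy(),
        buccal_reference=dentine.buccal_reference.copy(),
    )
    return dentine, cementum, thickness_um


# ---------------------------------------------------------------------------
# confocal-style height maps


def make_height_map(
    amplitude_um: float,
    correlation_length_um: float = 25.0,
    relief_density_per_mm2: float = 30.0,
    form_curvature_um: float = 0.0,
    nm_fraction: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_um: float = 0.65,
    noise_rms_um: float = 1.5,
    relief_radius_um: float = 60.0,
    edge_width_um: float = 60.0,
) -> HeightMap:
    """Generate a confocal-style height map of controlled amplitude and relief.

    The grid is a degree-2 form (peak-to-valley ``form_curvature_um``) plus a
    field of smooth-edged relief mounds (count ≈ density × area, heights
    scaled so the peak-to-valley of the form-removed relief ≈
    ``amplitude_um``) plus correlated Gaussian noise of RMS ``noise_rms_um``
    and correlation length ``correlation_length_um``.  ``nm_fraction`` of the
    pixels are marked non-measured.  The output is fully determined by the
    arguments and the seed.
    """
    from scipy import ndimage

    if amplitude_um < 0 or relief_density_per_mm2 < 0 or nm_fraction < 0:
        raise ValueError("amplitude, density and nm_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx].astype(float) * pixel_um
    cx, cy = x.max() / 2, y.max() / 2
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    z = form_curvature_um * r2 / r2.max() if form_curvature_um else np.zeros(shape)

    noise = np.zeros(shape)
    if noise_rms_um > 0:
        white = rng.standard_normal(shape)
        corr = ndimage.gaussian_filter(white, sigma=correlation_length_um / pixel_um,
                                       mode="nearest")
        rms = corr.std()
        if rms > 0:
            noise = corr * (noise_rms_um / rms)

    A = np.column_stack([
        np.ones(x.size), x.ravel(), y.ravel(),
        x.ravel() ** 2, (x * y).ravel(), y.ravel() ** 2,
    ])

    def detrended_p2v(f: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(A, f.ravel(), rcond=None)
        r = f.ravel() - A @ coef
        return float(r.max() - r.min())

    if amplitude_um > 0:
        area_mm2 = (nx * pixel_um) * (ny * pixel_um) / 1e6
        n_bumps = max(1, int(round(relief_density_per_mm2 * area_mm2)))
        # shrink mounds when many must fit in the field
        radius = min(relief_radius_um,
                     0.42 * min(nx, ny) * pixel_um / max(np.sqrt(n_bumps), 1.0))
        # dense fields need narrow skirts or neighboring mounds merge
        edge = min(edge_width_um, (1.2 if n_bumps <= 6 else 0.5) * radius)
        centers: list[tuple[float, float]] = []
        min_sep = 1.9 * radius
        for _ in range(800):
            if len(centers) >= n_bumps:
                break
            px = rng.uniform(0.10, 0.90) * x.max()
            py = rng.uniform(0.10, 0.90) * y.max()
            if all((px - qx) ** 2 + (py - qy) ** 2 >= min_sep**2 for qx, qy in centers):
                centers.append((px, py))
        relief = np.zeros(shape)
        from scipy.special import erf

        for px, py in centers:
            d = np.hypot(x - px, y - py)
            h = rng.uniform(0.8, 1.0)
            relief = np.maximum(relief, h * 0.5 * (1 + erf((radius - d) / edge)))
        # soften the creases where mound skirts meet; cementum mounds blend
        # smoothly into the surface
        relief = ndimage.gaussian_filter(relief, sigma=10.0 / pixel_um, mode="nearest")
        # scale relief so the detrended relief+noise peak-to-valley hits the
        # requested amplitude (the noise share is measured, not assumed)
        p2v_relief = detrended_p2v(relief)
        p2v_noise = detrended_p2v(noise)
        target = max(amplitude_um - p2v_noise, 0.05 * amplitude_um)
        if p2v_relief > 0:
            relief *= target / p2v_relief
        z = z + relief
    z = z + noise

    mask = None
    if nm_fraction > 0:
        mask = rng.random(shape) < nm_fraction
    return HeightMap(z, pixel_um, mask)


#: Generator settings reproducing the eight surface-aspect archetypes.
#: Elevation: '+' >= 200 um P2V, '-' below; texture: S broad smooth-edged
#: relief over long-correlation noise / R strong short-wavelength noise;
#: frequency: 1 dense relief mounds / 2 sparse.  Densities assume the default
#: 512x512 grid at 0.65 um/px (0.111 mm^2 field).
ASPECT_ARCHETYPES: dict[str, dict] = {
    "+S1": dict(amplitude_um=430.0, relief_density_per_mm2=110.0,
                noise_rms_um=1.2, correlation_length_um=30.0),
    "+S2": dict(amplitude_um=430.0, relief_density_per_mm2=18.0,
                noise_rms_um=1.2, correlation_length_um=30.0),
    "+R1": dict(amplitude_um=430.0, relief_density_per_mm2=110.0,
                noise_rms_um=16.0, correlation_length_um=2.0),
    "+R2": dict(amplitude_um=430.0, relief_density_per_mm2=18.0,
                noise_rms_um=16.0, correlation_length_um=2.0),
    "-S1": dict(amplitude_um=150.0, relief_density_per_mm2=110.0,
                noise_rms_um=1.2, correlation_length_um=30.0),
    "-S2": dict(amplitude_um=150.0, relief_density_per_mm2=18.0,
                noise_rms_um=1.2, correlation_length_um=30.0),
    "-R1": dict(amplitude_um=150.0, relief_density_per_mm2=110.0,
                noise_rms_um=8.0, correlation_length_um=2.0),
    "-R2": dict(amplitude_um=150.0, relief_density_per_mm2=18.0,
                noise_rms_um=8.0, correlation_length_um=2.0),
}


def make_archetype_map(label: str, seed: int = 0, amplitude_um: float | None = None,
                       shape: tuple[int, int] = (512, 512)) -> HeightMap:
    """Generate a height map whose intended aspect score is ``label``."""
    params = dict(ASPECT_ARCHETYPES[label])
    if amplitude_um is not None:
        params["amplitude_um"] = amplitude_um
    return make_height_map(seed=seed, shape=shape, form_curvature_um=150.0, **params)


def write_sidecar(spec: SyntheticSpec, path) -> None:
    """Record the generator spec as a key-value text sidecar."""
    lines = [
        f"root_length_mm = {spec.root_length_mm}",
        f"base_radius_mm = {spec.base_radius_mm}",
        f"taper = {spec.taper}",
        f"base_cementum_um = {spec.base_cementum_um}",
        f"angular_gradient = {spec.angular_gradient}",
        f"texture = {spec.texture}",
        f"nm_fraction = {spec.nm_fraction}",
        f"seed = {spec.seed}",
    ] + [f"primitive = {p}" for p in spec.shape_primitives]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def sample_primitive(kind: str, rng: np.random.Generator) -> ShapePrimitive:
    """Draw a primitive with dimensions well inside its category's bounds.

    Used for parameter-recovery studies: every dimension stays at least ~20%
    away from the category boundaries (2 mm for NOD/Nds/LSP, 3 mm for OG,
    the 1 mm / 2 mm / 0.5 mm ridge rules), so a correct classifier should
    recover the kind essentially always.
    """
    side = ("m", "d", "<", ">")[int(rng.integers(4))]
    if kind == "NOD":
        return ShapePrimitive("NOD", 2, side, diameter_mm=float(rng.uniform(2.4, 2.9)),
                              height_mm=float(rng.uniform(0.8, 1.1)))
    if kind == "Nds":
        return ShapePrimitive("Nds", 2, side, diameter_mm=float(rng.uniform(0.9, 1.5)),
                              height_mm=float(rng.uniform(0.7, 0.9)),
                              count=int(rng.integers(3, 6)))
    if kind == "OG":
        return ShapePrimitive("OG", 2, side, diameter_mm=float(rng.uniform(3.7, 4.4)),
                              height_mm=float(rng.uniform(0.9, 1.1)),
                              angle_offset_deg=45.0)
    if kind == "RID":
        return ShapePrimitive("RID", 2, side, diameter_mm=float(rng.uniform(0.55, 0.75)),
                              height_mm=float(rng.uniform(0.65, 0.8)),
                              length_mm=float(rng.uniform(2.6, 3.2)),
                              count=int(rng.integers(4, 7)))
    if kind == "LSP":
        return ShapePrimitive("LSP", 2, side, diameter_mm=float(rng.uniform(1.1, 1.6)),
                              height_mm=float(rng.uniform(0.9, 1.1)),
                              count=int(rng.integers(3, 6)))
    raise ValueError(f"unknown primitive kind {kind!r}")


def recovery_spec(index: int, seed: int, n_theta: int = 64, n_axial: int = 80) -> tuple[SyntheticSpec, str, bool]:
    """One parameter-recovery replicate: (spec, true kind, gradient present).

    Replicates cycle through the five shape kinds; every second one adds an
    apico-lingual gradient so the preferential flag is exercised both ways.
    """
    kinds = ("NOD", "Nds", "OG", "RID", "LSP")
    rng = np.random.default_rng(seed + index)
    kind = kinds[index % 5]
    prim = sample_primitive(kind, rng)
    grad = (">", float(rng.uniform(600, 800)), 1) if index % 2 else None
    spec = SyntheticSpec(
        base_radius_mm=2.6, base_cementum_um=500.0, angular_gradient=grad,
        shape_primitives=(prim,), texture=(100.0, 500.0, 0.0),
        seed=seed + 10_000 + index, n_theta=n_theta, n_axial=n_axial,
    )
    return spec, kind, grad is not None
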