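"""Synthetic dimer ensembles with planted, correlated collective modes.

Generates an idealized C2-symmetric two-chain four-helix-bundle C-alpha
template (residue numbering matching the Tar helix ranges), plants two
orthonormal collective modes on it — an anti-symmetric inter-monomer
rotation field and an alpha4 axial-slide field — and samples ensembles
whose mode amplitudes follow a (possibly multi-basin) correlated
Gaussian, plus isotropic site noise and optional per-frame random rigid
poses. Because the planted modes and amplitudes are known exactly, every
pipeline stage (superposition, PCA, projections, clustering, pocket
geometry) can be validated without molecular-dynamics trajectories.

No physics is emulated here: the generator reproduces the *statistical*
structure of a fluctuating dimer (collective modes, amplitude
correlations, basins, site noise, arbitrary frame poses), not its
energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError, ValidationError
from .structure_io import Ensemble, SiteSet, TAR_ALPHA4_RANGE, TAR_HELIX_RANGES


@dataclass
class SyntheticSpec:
    """Template geometry and sampling conditions for synthetic ensembles.

    Defaults give a Tar-like dimer: four ideal helices per chain with the
    Tar residue ranges, 0.15 nm rise and 0.23 nm helix radius (consecutive
    C-alpha spacing ~0.38 nm), two planted modes with variances
    0.04 / 0.01 nm^2 and amplitude correlation 0.6, 0.01 nm site noise,
    a single basin at the origin, and random rigid poses per frame.
    """

    # template geometry
    helix_ranges: tuple[tuple[int, int], ...] = TAR_HELIX_RANGES
    alpha4_range: tuple[int, int] = TAR_ALPHA4_RANGE
    rise_nm: float = 0.15
    helix_radius_nm: float = 0.23
    twist_deg: float = 100.0
    bundle_spacing_nm: float = 1.0
    chain_offset_nm: float = 0.9
    alpha4_offset_nm: float = 0.0
    chains: tuple[str, str] = ("A", "B")
    # planted-mode statistics
    mode_std_nm: tuple[float, float] = (0.2, 0.1)
    mode_correlation: float = 0.6
    noise_sigma_nm: float = 0.01
    basins: tuple[tuple[tuple[float, float], float], ...] = (((0.0, 0.0), 1.0),)
    # sampling
    n_frames: int = 5000
    seed: int = 0
    rigid_jitter: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.noise_sigma_nm < 0:
            raise ParameterError("noise sigma must be >= 0")
        if not -1.0 < self.mode_correlation < 1.0:
            raise ParameterError("mode correlation must lie in (-1, 1)")
        if any(s < 0 for s in self.mode_std_nm):
            raise ParameterError("mode amplitude std must be >= 0")
        weights = [w for _, w in self.basins]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ParameterError("basin weights must be nonnegative and sum to 1")
        if self.rise_nm <= 0 or self.helix_radius_nm <= 0 or self.bundle_spacing_nm <= 0:
            raise ParameterError("template lengths must be positive")

    def basin_covariance(self) -> np.ndarray:
        """Within-basin 2x2 amplitude covariance (nm^2)."""
        d = np.diag(self.mode_std_nm)
        corr = np.array([[1.0, self.mode_correlation], [self.mode_correlation, 1.0]])
        return d @ corr @ d

    def amplitude_covariance(self) -> np.ndarray:
        """Total (mixture) amplitude covariance over basins (nm^2)."""
        cov_b = self.basin_covariance()
        centers = np.array([c for c, _ in self.basins], float)
        weights = np.array([w for _, w in self.basins], float)
        mean = weights @ centers
        total = cov_b.copy()
        for c, w in zip(centers, weights):
            d = c - mean
            total += w * np.outer(d, d)
        return total

    def expected_pca_eigenvalues(self) -> np.ndarray:
        """Descending eigenvalues of the planted amplitude covariance (nm^2).

        These — not the per-mode variances — are what ensemble PCA recovers
        when the planted amplitudes are correlated or multi-basin.
        """
        return np.sort(np.linalg.eigvalsh(self.amplitude_covariance()))[::-1]


@dataclass
class GroundTruth:
    """Planted modes and per-frame amplitudes of a synthetic ensemble."""

    mode_vectors: np.ndarray  # (3N, K), orthonormal planted modes
    raw_fields: dict  # unit fields before rigid-mode removal / orthogonalization
    template: SiteSet
    spec: SyntheticSpec
    amplitudes: np.ndarray | None = None  # (M, K), nm
    basin_labels: np.ndarray | None = None  # (M,)


def _helix_trace(n: int, axis_xy: np.ndarray, up: bool, spec: SyntheticSpec) -> np.ndarray:
    j = np.arange(n)
    phi = np.deg2rad(spec.twist_deg) * j
    x = axis_xy[0] + spec.helix_radius_nm * np.cos(phi)
    y = axis_xy[1] + spec.helix_radius_nm * np.sin(phi)
    half = 0.5 * (n - 1) * spec.rise_nm
    z = -half + j * spec.rise_nm if up else half - j * spec.rise_nm
    return np.column_stack([x, y, z])


def make_template(spec: SyntheticSpec | None = None) -> SiteSet:
    """Idealized C2-symmetric four-helix-bundle dimer C-alpha template.

    Chain A's four helix axes sit on the corners of a square of side
    ``bundle_spacing_nm`` centered ``chain_offset_nm`` from the dimer (z)
    axis, antiparallel (alternating up/down); chain B is the exact C2
    image (180 degree rotation about z). ``alpha4_offset_nm`` pushes the
    alpha4 helix radially outward, weakening its spring connectivity —
    the knob used to make the softest network mode an alpha4 slide.
    """
    spec = spec or SyntheticSpec()
    s = spec.bundle_spacing_nm / 2.0
    d = spec.chain_offset_nm
    corners = np.array([[-s, -s], [-s, s], [s, s], [s, -s]])
    # alpha4 radially outward from the chain center: weakens its contacts
    # with both neighboring helices symmetrically
    corners[3] += spec.alpha4_offset_nm * np.array([1.0, -1.0]) / np.sqrt(2.0)
    labels: list[tuple[str, int]] = []
    coords: list[np.ndarray] = []
    chain_a: list[np.ndarray] = []
    for k, (start, end) in enumerate(spec.helix_ranges):
        n = end - start + 1
        trace = _helix_trace(n, corners[k] + np.array([d, 0.0]), up=(k % 2 == 0), spec=spec)
        chain_a.append(trace)
        labels.extend((spec.chains[0], r) for r in range(start, end + 1))
    coords.extend(chain_a)
    rot_c2 = np.diag([-1.0, -1.0, 1.0])
    for k, (start, end) in enumerate(spec.helix_ranges):
        coords.append(chain_a[k] @ rot_c2.T)
        labels.extend((spec.chains[1], r) for r in range(start, end + 1))
    return SiteSet(labels=labels, xyz=np.vstack(coords),
                   selection={"ranges": {c: list(spec.helix_ranges) for c in spec.chains}})


def rigid_generators(xyz: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of infinitesimal rigid-body motions at xyz."""
    xyz = np.asarray(xyz, float).reshape(-1, 3)
    n = xyz.shape[0]
    c = xyz - xyz.mean(axis=0)
    gens = np.zeros((3 * n, 6))
    for ax in range(3):
        gens[ax::3, ax] = 1.0
    for ax, u in enumerate(np.eye(3)):
        gens[:, 3 + ax] = np.cross(u, c).reshape(-1)
    q, _ = np.linalg.qr(gens)
    return q


def remove_rigid_component(vec: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Project the 6 rigid-body generators at xyz out of a 3N vector."""
    q = rigid_generators(xyz)
    vec = np.asarray(vec, float).reshape(-1)
    return vec - q @ (q.T @ vec)


def planted_modes(
    template: SiteSet,
    spec: SyntheticSpec | None = None,
    remove_rigid: bool = True,
) -> GroundTruth:
    """Construct the planted rotation and alpha4-slide fields on a template.

    The anti-symmetric rotation field displaces chain-A sites under an
    infinitesimal +theta rotation about the dimer (z) axis and chain-B
    sites under -theta; the slide field displaces both chains' alpha4
    sites along -z and nothing else. With ``remove_rigid`` (default) the
    rigid-body components unidentifiable after superposition are projected
    out before Gram-Schmidt orthonormalization, so the planted truth lies
    in the model class that ensemble PCA of superposed frames can recover;
    the raw unit fields are kept in ``raw_fields``.
    """
    spec = spec or SyntheticSpec()
    xyz = template.xyz
    n = xyz.shape[0]
    chain_a = spec.chains[0]
    rot = np.cross(np.array([0.0, 0.0, 1.0]), xyz)
    sign = np.array([1.0 if c == chain_a else -1.0 for c, _ in template.labels])
    rot *= sign[:, None]
    a4_lo, a4_hi = spec.alpha4_range
    slide = np.zeros_like(xyz)
    slide[[a4_lo <= r <= a4_hi for _, r in template.labels], 2] = -1.0
    raw = {}
    fields = []
    for name, f in (("rotation", rot.reshape(-1)), ("slide", slide.reshape(-1))):
        norm = np.linalg.norm(f)
        if norm == 0:
            raise ValidationError(f"planted {name} field is identically zero")
        raw[name] = f / norm
        fields.append(f / norm)
    if remove_rigid:
        fields = [remove_rigid_component(f, xyz) for f in fields]
    # Gram-Schmidt in listed order
    ortho: list[np.ndarray] = []
    for f in fields:
        for g in ortho:
            f = f - (g @ f) * g
        norm = np.linalg.norm(f)
        if norm < 1e-10:
            raise ValidationError("planted fields are linearly dependent")
        ortho.append(f / norm)
    return GroundTruth(mode_vectors=np.column_stack(ortho), raw_fields=raw,
                       template=template, spec=spec)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rot = Rotation.from_quat(quat).as_matrix()
    trans = rng.uniform(-2.0, 2.0, size=3)
    return rot, trans


def sample_ensemble(
    template: SiteSet,
    truth: GroundTruth,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
) -> tuple[Ensemble, GroundTruth]:
    """Sample frames = template + sum_k a_k v_k + noise, in random rigid poses.

    Per frame a basin is drawn by weight, mode amplitudes from that
    basin's correlated Gaussian, isotropic Gaussian noise of
    ``noise_sigma_nm`` added per coordinate, and (optionally) a uniform
    random rotation plus a translation applied. Fully reproducible from
    the seed (``spec.seed`` unless overridden).
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m = spec.n_frames
    k = truth.mode_vectors.shape[1]
    centers = np.array([c for c, _ in spec.basins], float)
    weights = np.array([w for _, w in spec.basins], float)
    cov = spec.basin_covariance()
    # symmetric PSD square root: exact zeros when a mode std is zero
    evals, evecs = np.linalg.eigh(cov)
    sqrt_cov = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    basin_labels = rng.choice(len(weights), size=m, p=weights)
    amplitudes = centers[basin_labels] + rng.standard_normal((m, 2)) @ sqrt_cov.T
    if k != 2:
        raise ValidationError("sampler expects exactly two planted modes")
    base = template.coords
    frames = np.empty((m, base.size))
    for i in range(m):
        x = base + truth.mode_vectors @ amplitudes[i]
        if spec.noise_sigma_nm > 0:
            x = x + rng.normal(scale=spec.noise_sigma_nm, size=base.size)
        xyz = x.reshape(-1, 3)
        if spec.rigid_jitter:
            rot, trans = _random_rigid(rng)
            xyz = xyz @ rot.T + trans
        frames[i] = xyz.reshape(-1)
    ensemble = Ensemble(
        labels=list(template.labels),
        xyz=frames.reshape(m, -1, 3),
        provenance={"synthetic": True, "seed": int(spec.seed if seed is None else seed),
                    "n_frames": m},
    )
    out = GroundTruth(mode_vectors=truth.mode_vectors, raw_fields=truth.raw_fields,
                      template=template, spec=spec, amplitudes=amplitudes,
                      basin_labels=basin_labels)
    return ensemble, out


def make_ensemble(spec: SyntheticSpec | None = None, seed: int | None = None) -> tuple[Ensemble, GroundTruth]:
    """Template + planted modes + sampling in one call."""
    spec = spec or SyntheticSpec()
    template = make_template(spec)
    truth = planted_modes(template, spec)
    return sample_ensemble(template, truth, spec, seed=seed)


def weak_alpha4_spec() -> SyntheticSpec:
    """Template spec whose alpha4 helices are weakly coupled to the core.

    With the bundle widened to 1.2 nm and alpha4 pushed 0.8 nm radially
    outward, alpha4 has far fewer within-cutoff contacts than the core at
    the default 1.5 nm cutoff (while the network stays connected), and the
    softest ANM mode becomes an alpha4 axial slide.
    """
    return SyntheticSpec(bundle_spacing_nm=1.2, alpha4_offset_nm=0.8)


#: Basin centers of the two-basin landscape fixture, (pe1, pe2) in nm:
#: a compact basin near the origin and a rotated/slid basin.
TWO_BASIN_CENTERS: tuple[tuple[float, float], tuple[float, float]] = ((0.15, 0.75), (1.53, -1.83))


def two_basin_fixture(
    n_frames: int = 3000,
    weights: tuple[float, float] = (0.7, 0.3),
    seed: int = 7,
    basin_std_nm: float = 0.15,
) -> tuple[Ensemble, GroundTruth]:
    """Fixed-seed two-basin ensemble for landscape-clustering tests.

    Basins sit at mode-space centers (0.15, 0.75) and (1.53, -1.83) nm with
    isotropic within-basin spread ``basin_std_nm`` — far smaller than the
    basin separation, so the planted partition is unambiguous.
    """
    spec = SyntheticSpec(
        mode_std_nm=(basin_std_nm, basin_std_nm),
        mode_correlation=0.0,
        basins=((TWO_BASIN_CENTERS[0], weights[0]), (TWO_BASIN_CENTERS[1], weights[1])),
        n_frames=n_frames,
        seed=seed,
    )
    return make_ensemble(spec)
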