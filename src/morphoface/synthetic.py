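"""Seeded generator of face-like cohorts with exported ground truth.

The generator emulates the statistical structure the analysis assumes: a
schematic frontal-face template of 119 landmarks and semilandmarks (69 of
which enter the shape analysis), a cohort of covariates (BMI, WHR) drawn from
a truncated bivariate normal matching the study population's moments, a
linear shape effect of BMI along a known unit direction, independent nuisance
shape factors (face width, jaw size, brow height), per-landmark digitizing
noise, nuisance similarity transforms (pose), and a procedurally painted skin
texture whose brightness and redness increase linearly with BMI.

Everything is keyed to a single integer seed; the written TPS/CSV/PNG files
are byte-identical across runs with the same spec.  The exported ground truth
(the applied effect directions and the analytically implied score-covariate
correlation) enables parameter-recovery checks of the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import polygon as _sk_polygon, disk as _sk_disk

from morphoface.io import (
    LandmarkConfiguration,
    SemilandmarkScheme,
    write_tps,
    save_image,
)
from morphoface.warping import (
    MeanFrame,
    build_mean_frame,
    fit_tps,
    apply_tps,
    fit_similarity,
    _frame_pixel_centers,
    _sample_bilinear,
)


# --------------------------------------------------------------------------
# template construction
# --------------------------------------------------------------------------

def _resample_equal_arclength(dense: np.ndarray, n: int) -> np.ndarray:
    """Pick n points at equal arclength spacing along a dense polyline."""
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, dense[:, 0])
    out[:, 1] = np.interp(targets, s, dense[:, 1])
    return out


def _ellipse_arc(center: tuple[float, float], a: float, b: float,
                 theta0: float, theta1: float, n: int, dense: int = 2000) -> np.ndarray:
    th = np.linspace(np.deg2rad(theta0), np.deg2rad(theta1), dense)
    pts = np.column_stack([center[0] + a * np.cos(th), center[1] + b * np.sin(th)])
    return _resample_equal_arclength(pts, n)


def _symmetric_arc(center_y: float, a: float, b: float, theta_mid: float,
                   theta_end: float, n: int) -> np.ndarray:
    """A bilaterally symmetric ellipse arc with an odd point count.

    The right half (from the midline point at ``theta_mid`` to ``theta_end``)
    is resampled at equal arclength and mirrored exactly, so the curve is
    symmetric about x = 0 to machine precision.  Returned left-to-right.
    """
    assert n % 2 == 1
    half = (n + 1) // 2
    right = _ellipse_arc((0.0, center_y), a, b, theta_mid, theta_end, half)
    right[0, 0] = 0.0  # exact midline
    left = right[1:][::-1].copy()
    left[:, 0] = -left[:, 0]
    return np.vstack([left, right])


def _brow_arc(n: int) -> np.ndarray:
    """Right-side brow: a shallow quadratic arc, inner to outer end."""
    t = np.linspace(0.0, 1.0, 400)
    p0, p1, p2 = np.array([0.20, 0.50]), np.array([0.44, 0.62]), np.array([0.68, 0.48])
    dense = ((1 - t) ** 2)[:, None] * p0 + (2 * t * (1 - t))[:, None] * p1 + (t**2)[:, None] * p2
    return _resample_equal_arclength(dense, n)


def _eye_contour() -> np.ndarray:
    """Right eye contour: outer corner, 3 upper-lid, inner corner, 3 lower-lid."""
    cx, cy, hw, hh = 0.42, 0.25, 0.20, 0.085
    xs = np.array([0.32, 0.42, 0.52])
    up = np.column_stack([xs, cy + hh * np.sqrt(1 - ((xs - cx) / hw) ** 2)])
    lo = np.column_stack([xs[::-1], cy - hh * np.sqrt(1 - ((xs[::-1] - cx) / hw) ** 2)])
    return np.vstack([[cx + hw, cy], up[::-1], [cx - hw, cy], lo[::-1]])
    # order: outer corner, upper (outer->inner), inner corner, lower (inner->outer)


def _mirror_x(pts: np.ndarray) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = -out[:, 0]
    return out


def build_template(outline_n: int = 19, vertex_n: int = 21, hairline_n: int = 11,
                   brow_n: int = 6, lip_n: int = 7, ear_n: int = 7
                   ) -> tuple[np.ndarray, SemilandmarkScheme]:
    """Deterministic schematic frontal-face template.

    Defaults give 119 landmarks and semilandmarks with a 69-point shape
    subset: face outline, brows, eye contours, nose, lips, and chin carry the
    shape analysis, while the vertex (head) outline, ears, hairline, and neck
    points additionally support the image warping.  The template is
    bilaterally symmetric about the vertical midline, and semilandmarks are
    spaced at near-equal arclength along their curves.
    """
    if outline_n % 2 == 0 or vertex_n % 2 == 0 or hairline_n % 2 == 0 or lip_n % 2 == 0:
        raise ValueError("midline-crossing curves need odd point counts")
    groups: dict[str, np.ndarray] = {}
    # shape-analysis groups
    groups["outline"] = _symmetric_arc(0.05, 1.00, 1.35, 270.0, 370.0, outline_n)
    groups["brow_l"] = _mirror_x(_brow_arc(brow_n))
    groups["brow_r"] = _brow_arc(brow_n)
    groups["eye_l"] = _mirror_x(_eye_contour())
    groups["eye_r"] = _eye_contour()
    groups["nose"] = np.array([
        [0.0, 0.38], [0.0, 0.20], [0.0, 0.02],       # nasion + bridge
        [0.0, -0.10],                                  # tip
        [-0.17, -0.13], [0.17, -0.13],                 # alae
        [0.0, -0.20],                                  # subnasale
    ])
    groups["lip_upper"] = _symmetric_arc(-0.56, 0.30, 0.14, 90.0, 1.0, lip_n)
    groups["lip_lower"] = _symmetric_arc(-0.50, 0.26, 0.14, 270.0, 339.0, lip_n)
    groups["chin"] = np.array([[0.0, -0.95]])
    # warp-only groups
    groups["vertex"] = _symmetric_arc(0.05, 1.05, 1.45, 90.0, 10.0, vertex_n)
    groups["ear_l"] = _mirror_x(_ellipse_arc((1.0, 0.2), 0.13, 0.22, -80.0, 80.0, ear_n))
    groups["ear_r"] = _ellipse_arc((1.0, 0.2), 0.13, 0.22, -80.0, 80.0, ear_n)
    groups["hairline"] = _symmetric_arc(0.15, 0.82, 1.00, 90.0, 25.0, hairline_n)
    groups["neck"] = np.array([
        [-0.42, -1.25], [0.42, -1.25],     # at the height of the chin
        [-0.38, -1.55], [0.38, -1.55],     # where the chin outline meets the neck
    ])

    order = ["outline", "brow_l", "brow_r", "eye_l", "eye_r", "nose",
             "lip_upper", "lip_lower", "chin",
             "vertex", "ear_l", "ear_r", "hairline", "neck"]
    points = np.vstack([groups[g] for g in order])
    idx: dict[str, np.ndarray] = {}
    start = 0
    for g in order:
        idx[g] = np.arange(start, start + len(groups[g]))
        start += len(groups[g])

    curves = [list(idx[g]) for g in
              ("outline", "brow_l", "brow_r", "lip_upper", "lip_lower",
               "vertex", "ear_l", "ear_r", "hairline")]
    curve_interiors = {i for c in curves for i in c[1:-1]}
    fixed = sorted(set(range(len(points))) - curve_interiors)
    shape_groups = ("outline", "brow_l", "brow_r", "eye_l", "eye_r", "nose",
                    "lip_upper", "lip_lower", "chin")
    shape_subset = sorted(int(i) for g in shape_groups for i in idx[g])
    scheme = SemilandmarkScheme(
        n_points=len(points),
        curves=[[int(i) for i in c] for c in curves],
        fixed_indices=[int(i) for i in fixed],
        shape_subset=shape_subset,
        warp_set=list(range(len(points))),
    )
    return points, scheme


_TEMPLATE_GROUPS = ("outline", "brow_l", "brow_r", "eye_l", "eye_r", "nose",
                    "lip_upper", "lip_lower", "chin",
                    "vertex", "ear_l", "ear_r", "hairline", "neck")


def _template_index(outline_n=19, vertex_n=21, hairline_n=11, brow_n=6,
                    lip_n=7, ear_n=7) -> dict[str, np.ndarray]:
    sizes = {"outline": outline_n, "brow_l": brow_n, "brow_r": brow_n,
             "eye_l": 8, "eye_r": 8, "nose": 7, "lip_upper": lip_n,
             "lip_lower": lip_n, "chin": 1, "vertex": vertex_n,
             "ear_l": ear_n, "ear_r": ear_n, "hairline": hairline_n, "neck": 4}
    out, start = {}, 0
    for g in _TEMPLATE_GROUPS:
        out[g] = np.arange(start, start + sizes[g])
        start += sizes[g]
    return out


# --------------------------------------------------------------------------
# effect and nuisance directions
# --------------------------------------------------------------------------

def _similarity_basis(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k x 4) of the similarity directions at a
    configuration: x/y translation, rotation, and scaling."""
    c = ref - ref.mean(axis=0)
    k = ref.shape[0]
    dirs = np.zeros((2 * k, 4))
    dirs[0::2, 0] = 1.0                      # translate x
    dirs[1::2, 1] = 1.0                      # translate y
    dirs[0::2, 2], dirs[1::2, 2] = -c[:, 1], c[:, 0]   # infinitesimal rotation
    dirs[0::2, 3], dirs[1::2, 3] = c[:, 0], c[:, 1]    # scaling
    q, _ = np.linalg.qr(dirs)
    return q


def _project_out(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return v - basis @ (basis.T @ v)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _normal_at_sliding(d: np.ndarray, template: np.ndarray,
                       scheme: SemilandmarkScheme) -> np.ndarray:
    """Remove the curve-tangential component of a displacement field at every
    sliding semilandmark.  Displacement along a curve is exactly what the
    sliding algorithm treats as arbitrary, so only the normal component of an
    effect is identifiable; constructing the ground-truth effect normal to
    the curves makes it recoverable by the full pipeline."""
    from morphoface.procrustes import _curve_tangents

    out = d.reshape(template.shape).copy()
    for j, t in _curve_tangents(template, scheme).items():
        out[j] = out[j] - (out[j] @ t) * t
    return out.ravel()


def _sliding_projection(template: np.ndarray, scheme: SemilandmarkScheme) -> np.ndarray:
    """The (idempotent) linear operator applied to small displacement fields
    by one bending-energy sliding step against the template.

    Sliding moves each semilandmark along its tangent by the offset minimizing
    the TPS bending energy of the residual; for small displacements this is
    the oblique projection S = I - T (T' M T)^-1 T' M, where T embeds the unit
    tangents and M is the bending-energy quadratic form (per coordinate).
    S transforms both the covariate effect and the digitizing noise, so the
    generator uses it to express which effect direction the full protocol can
    actually recover, and with which noise amplification.
    """
    from morphoface.procrustes import bending_energy_matrix, _curve_tangents

    k = template.shape[0]
    M = bending_energy_matrix(template).matrix
    tangents = _curve_tangents(template, scheme)
    cols = sorted(tangents)
    T = np.zeros((2 * k, len(cols)))
    for col, j in enumerate(cols):
        T[2 * j, col], T[2 * j + 1, col] = tangents[j]
    M2 = np.zeros((2 * k, 2 * k))
    M2[0::2, 0::2] = M
    M2[1::2, 1::2] = M
    return np.eye(2 * k) - T @ np.linalg.solve(T.T @ M2 @ T, T.T @ M2)


def _bmi_shape_direction(template: np.ndarray, idx: dict[str, np.ndarray]) -> np.ndarray:
    """Raw BMI shape-effect field: wider outline and nose, lower brows,
    smaller eyes, thinner lips.  (2k,) flattened, before projection."""
    d = np.zeros_like(template)
    d[idx["outline"], 0] = 0.8 * template[idx["outline"], 0]
    for g in ("brow_l", "brow_r"):
        d[idx[g], 1] = -0.5
    for g in ("eye_l", "eye_r"):
        center = template[idx[g]].mean(axis=0)
        d[idx[g]] = -0.5 * (template[idx[g]] - center)
    d[idx["nose"][4], 0] = -0.3   # left ala outward
    d[idx["nose"][5], 0] = 0.3    # right ala outward
    d[idx["lip_upper"], 1] = -0.25
    d[idx["lip_lower"], 1] = 0.25
    return d.ravel()


def _nuisance_directions(template: np.ndarray, idx: dict[str, np.ndarray]) -> np.ndarray:
    """Three raw nuisance fields: overall face width, lower-jaw size, brow height."""
    k = template.shape[0]
    u = np.zeros((2 * k, 3))
    d = np.zeros_like(template)  # face width: widen the whole head outline
    for g in ("outline", "vertex", "ear_l", "ear_r", "hairline"):
        d[idx[g], 0] = template[idx[g], 0]
    u[:, 0] = d.ravel()
    d = np.zeros_like(template)  # jaw size: lower outline radially from mid-face
    sel = idx["outline"][template[idx["outline"], 1] < -0.4]
    d[sel] = template[sel] - np.array([0.0, -0.2])
    d[idx["chin"], 1] = -0.6
    u[:, 1] = d.ravel()
    d = np.zeros_like(template)  # brow height
    for g in ("brow_l", "brow_r"):
        d[idx[g], 1] = 1.0
    d[idx["hairline"], 1] = 0.3
    u[:, 2] = d.ravel()
    return u


# --------------------------------------------------------------------------
# spec and ground truth
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Full parameterization (with seed) of a simulated cohort.

    Covariate defaults reproduce the study population: BMI mean 23.0, SD 4.0,
    range 17.0-35.4 kg/m^2; WHR mean 0.72, SD 0.04, range 0.66-0.82; BMI-WHR
    correlation 0.47.  Shape units are template units (face half-width = 1).
    """

    n: int = 49
    seed: int = 0
    bmi_mean: float = 23.0
    bmi_sd: float = 4.0
    bmi_range: tuple[float, float] = (17.0, 35.4)
    whr_mean: float = 0.72
    whr_sd: float = 0.04
    whr_range: tuple[float, float] = (0.66, 0.82)
    rho_bmi_whr: float = 0.47
    v_shape_mag: float = 0.006       # shape units per BMI unit
    whr_shape_mag: float = 0.0       # WHR acts through its BMI correlation
    shape_noise_sds: tuple[float, ...] = (0.06, 0.045, 0.03)
    digitize_sd: float = 0.005       # per-landmark isotropic, template units
    skin_rgb: tuple[float, float, float] = (0.78, 0.62, 0.55)
    brightness_slope: float = 0.004  # added to R,G,B per BMI unit
    redness_slope: float = 0.004     # added to R only per BMI unit
    skin_jitter_lum_sd: float = 0.02
    skin_jitter_channel_sd: float = 0.008
    pixel_noise_sd: float = 0.01
    hair_rgb: tuple[float, float, float] = (0.22, 0.16, 0.10)
    iris_rgb: tuple[float, float, float] = (0.25, 0.18, 0.12)
    sclera_rgb: tuple[float, float, float] = (0.92, 0.92, 0.90)
    lip_rgb: tuple[float, float, float] = (0.72, 0.38, 0.38)
    background_rgb: tuple[float, float, float] = (0.45, 0.45, 0.45)
    rotation_deg: float = 3.0        # pose: uniform in +/- this
    scale_range: tuple[float, float] = (0.95, 1.05)
    translation_frac: float = 0.02   # of image size, uniform in +/-
    image_size: tuple[int, int] = (64, 64)  # (H, W)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (-1.0 < self.rho_bmi_whr < 1.0):
            raise ValueError("rho must be in (-1, 1)")
        for lo, hi, mean in ((*self.bmi_range, self.bmi_mean), (*self.whr_range, self.whr_mean)):
            if not lo <= mean <= hi:
                raise ValueError("range must contain the mean")
        if any(s < 0 for s in self.shape_noise_sds) or self.digitize_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class GroundTruth:
    """The generator's hidden parameters, exported next to each cohort."""

    v_shape_full: np.ndarray     # unit effect direction, all landmarks (2k,)
    v_shape_subset: np.ndarray   # unit effect direction within the shape subset
    v_shape_mag: float
    texture_slope_rgb: tuple[float, float, float]  # d(skin RGB)/d(BMI)
    bmi: np.ndarray
    whr: np.ndarray
    nuisance_scores: np.ndarray  # (n, 3)
    oracle_r: float

    def to_json(self, path: str | Path) -> None:
        data = {
            "v_shape_full": self.v_shape_full.tolist(),
            "v_shape_subset": self.v_shape_subset.tolist(),
            "v_shape_mag": self.v_shape_mag,
            "texture_slope_rgb": list(self.texture_slope_rgb),
            "bmi": self.bmi.tolist(),
            "whr": self.whr.tolist(),
            "nuisance_scores": self.nuisance_scores.tolist(),
            "oracle_r": self.oracle_r,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            v_shape_full=np.array(d["v_shape_full"]),
            v_shape_subset=np.array(d["v_shape_subset"]),
            v_shape_mag=d["v_shape_mag"],
            texture_slope_rgb=tuple(d["texture_slope_rgb"]),
            bmi=np.array(d["bmi"]),
            whr=np.array(d["whr"]),
            nuisance_scores=np.array(d["nuisance_scores"]),
            oracle_r=d["oracle_r"],
        )


def _truncated_moments(mu: np.ndarray, sd: np.ndarray, rho: float,
                       box: tuple[tuple[float, float], tuple[float, float]],
                       n_nodes: int = 80) -> np.ndarray:
    """(mean1, sd1, mean2, sd2, corr) of a bivariate normal truncated to a
    box, by tensor Gauss-Legendre quadrature."""
    x, wx = np.polynomial.legendre.leggauss(n_nodes)

    def nodes(lo, hi):
        return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * wx

    y1, w1 = nodes(*box[0])
    y2, w2 = nodes(*box[1])
    Y1, Y2 = np.meshgrid(y1, y2, indexing="ij")
    W = np.outer(w1, w2)
    Z1 = (Y1 - mu[0]) / sd[0]
    Z2 = (Y2 - mu[1]) / sd[1]
    det = 1.0 - rho * rho
    pdf = np.exp(-(Z1**2 - 2 * rho * Z1 * Z2 + Z2**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det) * sd[0] * sd[1])
    m00 = (W * pdf).sum()
    if m00 < 1e-12:
        raise ValueError("truncation region too small: negligible probability mass")
    e1 = (W * pdf * Y1).sum() / m00
    e2 = (W * pdf * Y2).sum() / m00
    v1 = (W * pdf * Y1**2).sum() / m00 - e1**2
    v2 = (W * pdf * Y2**2).sum() / m00 - e2**2
    cov = (W * pdf * Y1 * Y2).sum() / m00 - e1 * e2
    return np.array([e1, np.sqrt(v1), e2, np.sqrt(v2), cov / np.sqrt(v1 * v2)])


_LATENT_CACHE: dict[tuple, tuple] = {}


def _latent_params(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Latent normal parameters whose box-truncated distribution has the
    spec's target means, SDs, and correlation.

    Truncation to an asymmetric box shifts means, shrinks SDs, and attenuates
    correlation, so the latent parameters are calibrated by solving the five
    truncated-moment equations (quadrature + root finding).
    """
    box = (spec.bmi_range, spec.whr_range)
    target = np.array([spec.bmi_mean, spec.bmi_sd, spec.whr_mean, spec.whr_sd,
                       spec.rho_bmi_whr])
    key = tuple(np.round(target, 12)) + (box,)
    if key not in _LATENT_CACHE:
        from scipy.optimize import root

        def residual(theta):
            mu = theta[[0, 2]]
            sd = np.abs(theta[[1, 3]])
            rho = np.clip(theta[4], -0.999, 0.999)
            return _truncated_moments(mu, sd, rho, box) - target

        sol = root(residual, target.copy(), method="hybr", tol=1e-12)
        if not sol.success or np.abs(sol.fun).max() > 1e-6:
            raise ValueError(
                "truncation region too narrow: cannot calibrate the covariate "
                "sampler to the target moments")
        theta = sol.x
        _LATENT_CACHE[key] = (theta[[0, 2]].copy(), np.abs(theta[[1, 3]]),
                              float(np.clip(theta[4], -0.999, 0.999)))
    return _LATENT_CACHE[key]


def sample_covariates(spec: SyntheticSpec, n: int | None = None,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (BMI, WHR) from the truncated correlated bivariate normal.

    Truncation to the stated ranges is by rejection (not clipping); the
    latent normal is calibrated so that the *truncated* population has the
    spec's target means, SDs, and correlation.
    """
    n = spec.n if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mean_lat, sd_lat, rho = _latent_params(spec)
    cov = np.array([
        [sd_lat[0]**2, rho * sd_lat[0] * sd_lat[1]],
        [rho * sd_lat[0] * sd_lat[1], sd_lat[1]**2],
    ])
    mean = mean_lat
    L = np.linalg.cholesky(cov)
    bmi = np.empty(n)
    whr = np.empty(n)
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise ValueError("rejection sampling failed: truncation region too small")
        draw = mean + rng.standard_normal((max(n * 2, 64), 2)) @ L.T
        ok = ((draw[:, 0] >= spec.bmi_range[0]) & (draw[:, 0] <= spec.bmi_range[1])
              & (draw[:, 1] >= spec.whr_range[0]) & (draw[:, 1] <= spec.whr_range[1]))
        accepted = draw[ok]
        take = min(len(accepted), n - filled)
        bmi[filled:filled + take] = accepted[:take, 0]
        whr[filled:filled + take] = accepted[:take, 1]
        filled += take
    return bmi, whr


def _truncated_bmi_sd(spec: SyntheticSpec) -> float:
    # the sampler is moment-calibrated, so the truncated BMI SD is the target
    return spec.bmi_sd


@dataclass(frozen=True)
class _EffectGeometry:
    """Template-level quantities shared by the generator and the oracle."""

    template: np.ndarray
    scheme: SemilandmarkScheme
    v: np.ndarray            # applied unit effect direction, full set (2k,)
    w: np.ndarray            # recoverable unit direction in subset coords
    sub_coords: np.ndarray
    signal_gain: float       # |P_sub R S v|: effect magnitude surviving the protocol
    noise_gain: float        # |S' E(w)|: digitizing-noise amplification along w
    nuisance: np.ndarray     # (2k, 3) orthonormal nuisance directions


def _effect_geometry_uncached() -> _EffectGeometry:
    template, scheme = build_template()
    idx = _template_index()
    sim_basis = _similarity_basis(template)
    v_raw = _normal_at_sliding(_bmi_shape_direction(template, idx), template, scheme)
    v = _unit(_project_out(v_raw, sim_basis))
    sub = np.array(scheme.shape_subset)
    sub_coords = np.sort(np.concatenate([2 * sub, 2 * sub + 1]))
    # the direction the protocol can recover: slide, restrict to the shape
    # subset, remove the subset's similarity components
    S = _sliding_projection(template, scheme)
    subsim = _similarity_basis(template[sub])
    w_raw = _project_out((S @ v)[sub_coords], subsim)
    signal_gain = float(np.linalg.norm(w_raw))
    w = w_raw / signal_gain
    w_emb = np.zeros_like(v)
    w_emb[sub_coords] = w
    noise_gain = float(np.linalg.norm(S.T @ w_emb))
    # nuisance factors orthogonal to the effect as applied (v) and as scored
    # after sliding (S u must have no component along w in the subset, i.e.
    # u must be orthogonal to S' E(w)), so they contribute no variance to the
    # effect scores
    U_raw = _nuisance_directions(template, idx)
    U = np.empty_like(U_raw)
    Q, _ = np.linalg.qr(np.column_stack([sim_basis, v, w_emb, S.T @ w_emb]))
    for j in range(U_raw.shape[1]):
        u = _unit(_project_out(U_raw[:, j], Q))
        U[:, j] = u
        Q = np.column_stack([Q, u])
    return _EffectGeometry(template=template, scheme=scheme, v=v, w=w,
                           sub_coords=sub_coords, signal_gain=signal_gain,
                           noise_gain=noise_gain, nuisance=U)


_GEOMETRY_CACHE: list[_EffectGeometry] = []


def _effect_geometry() -> _EffectGeometry:
    if not _GEOMETRY_CACHE:
        _GEOMETRY_CACHE.append(_effect_geometry_uncached())
    return _GEOMETRY_CACHE[0]


def oracle_correlation(spec: SyntheticSpec) -> float:
    """Analytically implied correlation between BMI and the noise-free effect score.

    Along the recoverable unit effect direction (the applied direction after
    the sliding projection and the subset similarity projection) the signal
    SD is v_shape_mag * signal_gain * sd(BMI) and the noise SD is
    digitize_sd * noise_gain (the nuisance factors are constructed to carry
    no variance along this direction); the correlation is the signal fraction
    of the combined SD.  sd(BMI) is the SD of the range-truncated BMI
    marginal; both gains follow in closed form from the template geometry.
    """
    if spec.v_shape_mag == 0:
        return 0.0
    geo = _effect_geometry()
    sig = spec.v_shape_mag * geo.signal_gain * _truncated_bmi_sd(spec)
    if spec.digitize_sd == 0:
        return 1.0
    return float(sig / np.hypot(sig, spec.digitize_sd * geo.noise_gain))


# --------------------------------------------------------------------------
# texture painting and cohort generation
# --------------------------------------------------------------------------

def _poly_mask(shape: tuple[int, int], pts_px: np.ndarray) -> np.ndarray:
    """Boolean mask of the polygon with vertices in (x, y-up) pixel coords."""
    H, W = shape
    rows = (H - 1) - pts_px[:, 1]
    cols = pts_px[:, 0]
    rr, cc = _sk_polygon(rows, cols, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _disk_mask(shape: tuple[int, int], center_px: np.ndarray, radius: float) -> np.ndarray:
    H, _ = shape
    rr, cc = _sk_disk(((H - 1) - center_px[1], center_px[0]), radius, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _thicken(curve: np.ndarray, half_width: float) -> np.ndarray:
    """Turn a polyline into a closed ribbon polygon of given half width (in y)."""
    up = curve + np.array([0.0, half_width])
    down = curve[::-1] - np.array([0.0, half_width])
    return np.vstack([up, down])


class _FaceMasks:
    """Region masks for the template painted into a frame (computed once)."""

    def __init__(self, frame: MeanFrame, template: np.ndarray,
                 idx: dict[str, np.ndarray]):
        place = frame.place
        shape = (frame.height, frame.width)
        s = frame.scale
        t = template
        head_boundary = np.vstack([t[idx["outline"]], t[idx["vertex"]][::-1]])
        face_boundary = np.vstack([t[idx["outline"]], t[idx["hairline"]][::-1]])
        self.head = _poly_mask(shape, place(head_boundary))
        self.face = _poly_mask(shape, place(face_boundary))
        self.brows = np.zeros(shape, dtype=bool)
        for g in ("brow_l", "brow_r"):
            self.brows |= _poly_mask(shape, place(_thicken(t[idx[g]], 0.03)))
        self.sclera = np.zeros(shape, dtype=bool)
        self.iris = np.zeros(shape, dtype=bool)
        for g in ("eye_l", "eye_r"):
            self.sclera |= _poly_mask(shape, place(t[idx[g]]))
            center = place(t[idx[g]].mean(axis=0))
            self.iris |= _disk_mask(shape, center, 0.055 * s)
        self.iris &= self.sclera
        lips_boundary = np.vstack([t[idx["lip_upper"]], t[idx["lip_lower"]][::-1]])
        self.lips = _poly_mask(shape, place(lips_boundary))
        nostrils = np.zeros(shape, dtype=bool)
        for j in (4, 5):
            nostrils |= _disk_mask(shape, place(t[idx["nose"][j]]), 0.018 * s)
        self.nostrils = nostrils
        self.skin = self.face & ~(self.brows | self.sclera | self.lips | self.nostrils)


def _paint_face(masks: _FaceMasks, spec: SyntheticSpec, skin_rgb: np.ndarray
                ) -> np.ndarray:
    H, W = masks.head.shape
    canvas = np.empty((H, W, 3))
    canvas[:] = spec.background_rgb
    canvas[masks.head] = spec.hair_rgb
    canvas[masks.face] = skin_rgb
    canvas[masks.brows] = spec.hair_rgb
    canvas[masks.sclera] = spec.sclera_rgb
    canvas[masks.iris] = spec.iris_rgb
    canvas[masks.lips] = spec.lip_rgb
    canvas[masks.nostrils] = np.asarray(spec.iris_rgb) * 0.8
    return np.clip(canvas, 0.0, 1.0)


def _warp_painting(painting: np.ndarray, frame: MeanFrame,
                   template_px: np.ndarray, target_px: np.ndarray) -> np.ndarray:
    """Backward-warp a template-frame painting onto target pixel landmarks."""
    A, t = fit_similarity(template_px, target_px)
    border_tgt = frame.border_points @ A + t
    transform = fit_tps(np.vstack([target_px, border_tgt]),
                        np.vstack([template_px, frame.border_points]))
    mapped = apply_tps(transform, _frame_pixel_centers(frame))
    out, _ = _sample_bilinear(painting, mapped, (frame.height, frame.width))
    return out


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path, write_images: bool = True
                    ) -> tuple[list[LandmarkConfiguration], SemilandmarkScheme, GroundTruth]:
    """Generate a full synthetic dataset and write it to ``out_dir``.

    Writes ``landmarks.tps`` (image pixel coordinates, y up), ``covariates.csv``,
    ``scheme.yaml``, ``images/<id>.png``, and ``ground_truth.json``.  Per
    specimen the landmarks are template + BMI shape effect + nuisance factors
    + digitizing noise, followed by a random similarity (pose) transform; the
    texture is painted in the template frame and TPS-warped onto the
    specimen's landmarks.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    # separate stream for sensor noise so landmark data are identical
    # whether or not images are rendered
    pix_rng = np.random.default_rng((spec.seed, 0xFACE))

    geo = _effect_geometry()
    template, scheme = geo.template, geo.scheme
    idx = _template_index()
    k = template.shape[0]
    v, U = geo.v, geo.nuisance

    bmi, whr = sample_covariates(spec, spec.n, int(rng.integers(2**31 - 1)))
    nuis = rng.standard_normal((spec.n, len(spec.shape_noise_sds)))

    H, W = spec.image_size
    frame = build_mean_frame(template, height=H, width=W, margin=0.10)
    template_px = frame.landmarks
    masks = _FaceMasks(frame, template, idx) if write_images else None

    ids = [f"s{i + 1:03d}" for i in range(spec.n)]
    configs: list[LandmarkConfiguration] = []
    slope = np.array([spec.brightness_slope + spec.redness_slope,
                      spec.brightness_slope, spec.brightness_slope])
    center_frame = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    for i, sid in enumerate(ids):
        shape_i = template.ravel() + (bmi[i] - spec.bmi_mean) * spec.v_shape_mag * v
        for j, s_j in enumerate(spec.shape_noise_sds):
            shape_i = shape_i + s_j * nuis[i, j] * U[:, j]
        shape_i = shape_i.reshape(k, 2)
        shape_i = shape_i + rng.normal(0.0, spec.digitize_sd, size=(k, 2))
        # pose: similarity transform in pixel space about the frame center
        theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
        scale = rng.uniform(*spec.scale_range)
        trans = rng.uniform(-spec.translation_frac, spec.translation_frac, size=2) * [W, H]
        R = scale * np.array([[np.cos(theta), np.sin(theta)],
                              [-np.sin(theta), np.cos(theta)]])
        lm_px = (frame.place(shape_i) - center_frame) @ R + center_frame + trans

        skin = np.asarray(spec.skin_rgb) + (bmi[i] - spec.bmi_mean) * slope
        skin = skin + rng.normal(0.0, spec.skin_jitter_lum_sd)
        skin = skin + rng.normal(0.0, spec.skin_jitter_channel_sd, size=3)
        if write_images:
            painting = _paint_face(masks, spec, np.clip(skin, 0.0, 1.0))
            img = _warp_painting(painting, frame, template_px, lm_px)
            if spec.pixel_noise_sd > 0:
                img = img + pix_rng.normal(0.0, spec.pixel_noise_sd, size=img.shape)
            save_image(np.clip(img, 0.0, 1.0), out_dir / "images" / f"{sid}.png")
        configs.append(LandmarkConfiguration(specimen_id=sid, points=lm_px,
                                             image_ref=f"images/{sid}.png"))

    write_tps(configs, out_dir / "landmarks.tps")
    scheme.to_yaml(out_dir / "scheme.yaml")
    lines = ["id,bmi,whr"] + [f"{sid},{bmi[i]:.6f},{whr[i]:.6f}" for i, sid in enumerate(ids)]
    (out_dir / "covariates.csv").write_text("\n".join(lines) + "\n")
    truth = GroundTruth(
        v_shape_full=v, v_shape_subset=geo.w, v_shape_mag=spec.v_shape_mag,
        texture_slope_rgb=tuple(slope), bmi=bmi, whr=whr, nuisance_scores=nuis,
        oracle_r=oracle_correlation(spec),
    )
    truth.to_json(out_dir / "ground_truth.json")
    return configs, scheme, truth


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    for key in ("bmi_range", "whr_range", "scale_range", "shape_noise_sds",
                "skin_rgb", "hair_rgb", "iris_rgb", "sclera_rgb", "lip_rgb",
                "background_rgb", "image_size"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SyntheticSpec(**d)
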