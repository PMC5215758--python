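"""Full-analysis orchestration: dataset -> superimposition -> registration ->
statistics -> figures -> machine-readable report.

The geometric stages (GPA, semilandmark sliding, image registration) are
computed once on the full sample; they are blind to the covariates, so only
the statistical fits are refitted inside cross-validation folds.  The shape
analysis runs on the shape subset of landmarks (re-superimposed after
sliding), while rendering and image registration use the full warp set.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from morphoface.io import (  # noqa: E402
    SemilandmarkScheme,
    read_tps,
    read_covariates,
    load_image,
    save_image,
)
from morphoface.procrustes import gpa, slide_semilandmarks  # noqa: E402
from morphoface.warping import (  # noqa: E402
    MeanFrame,
    RegisteredTexture,
    build_mean_frame,
    fit_similarity,
    register_image,
    mean_texture,
    render_shape,
)
from morphoface import stats as mstats  # noqa: E402
from morphoface.synthetic import SyntheticSpec, generate_cohort, spec_from_dict  # noqa: E402

logger = logging.getLogger("morphoface")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_dir`` (a directory holding ``landmarks.tps``,
    ``covariates.csv``, ``scheme.yaml`` and an ``images/`` folder) or
    ``synthetic`` (a :class:`SyntheticSpec`) must be set.
    """

    output_dir: str = "morphoface_out"
    input_dir: str | None = None
    synthetic: SyntheticSpec | None = None
    frame_size: int = 64
    covariates: tuple[str, ...] = ("bmi", "whr")
    n_pcs_list: tuple[int, ...] = (1, 2, 5, 10)
    alphas: tuple[float, ...] = (0.008, 1e9)
    n_perm: int = 999
    seed: int = 0
    strict_cv: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir or synthetic must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = spec_from_dict(data["synthetic"])
        for key in ("covariates", "n_pcs_list", "alphas"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_resolved_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        if data["synthetic"] is not None:
            data["synthetic"] = {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in data["synthetic"].__dict__.items()}
        for key in ("covariates", "n_pcs_list", "alphas"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class AnalysisReport:
    """Machine-readable summary of one run; every correlation is in [-1, 1]
    and every variance fraction in [0, 1] (checked by :meth:`validate`)."""

    n_specimens: int
    seed: int
    shape_variance_fractions: list[float]
    texture_variance_fractions: list[float]
    covariate_results: dict  # per covariate: per block r_within/p_perm/r_cv etc.
    pc_shape_texture_r2: list[list[float]]
    gpa_iterations: int
    gpa_converged: bool
    figures: list[str] = field(default_factory=list)

    def validate(self) -> None:
        fr = self.shape_variance_fractions + self.texture_variance_fractions
        if any(not (0.0 <= f <= 1.0 + 1e-9) for f in fr):
            raise ValueError("variance fraction outside [0, 1]")
        for cov, res in self.covariate_results.items():
            for key, val in _iter_numeric(res):
                if key.startswith("r") and not (np.isnan(val) or -1 - 1e-9 <= val <= 1 + 1e-9):
                    raise ValueError(f"{cov}:{key} correlation {val} outside [-1, 1]")
        for row in self.pc_shape_texture_r2:
            if any(not 0.0 <= v <= 1.0 + 1e-9 for v in row):
                raise ValueError("pairwise R^2 outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))

    def summary(self) -> str:
        lines = [f"n = {self.n_specimens}, seed = {self.seed}",
                 f"shape PC1+PC2 variance: {sum(self.shape_variance_fractions[:2]):.1%}",
                 f"texture PC1+PC2 variance: {sum(self.texture_variance_fractions[:2]):.1%}"]
        for cov, res in self.covariate_results.items():
            s, t = res["shape"], res["texture"]
            lines.append(
                f"{cov}: shape r = {s['r_within']:.2f} ({s['r_cv']:.2f} cross-validated, "
                f"p = {s['p_perm']:.3g}); texture r = {t['r_within']:.2f} "
                f"({t['r_cv']:.2f} cross-validated, p = {t['p_perm']:.3g}); "
                f"combined r_cv = {res['combined']['r_cv']:.2f}"
            )
        return "\n".join(lines)


def _iter_numeric(d: dict, prefix: str = ""):
    for k, v in d.items():
        if isinstance(v, dict):
            yield from _iter_numeric(v, f"{prefix}{k}.")
        elif isinstance(v, (int, float)):
            yield f"{prefix}{k}".rsplit(".", 1)[-1], float(v)


@dataclass
class _Dataset:
    ids: list[str]
    landmarks: np.ndarray  # (n, k, 2), image pixel coords (y up)
    scheme: SemilandmarkScheme
    images: list[np.ndarray]
    covariates: dict[str, np.ndarray]


def _load_dataset(config: RunConfig, out_dir: Path) -> _Dataset:
    if config.synthetic is not None:
        data_dir = out_dir / "dataset"
        generate_cohort(config.synthetic, data_dir)
    else:
        data_dir = Path(config.input_dir)
    configs = read_tps(data_dir / "landmarks.tps")
    scheme = SemilandmarkScheme.from_yaml(data_dir / "scheme.yaml")
    cov = read_covariates(data_dir / "covariates.csv")
    tps_ids = [c.specimen_id for c in configs]
    missing = set(tps_ids).symmetric_difference(cov.index)
    if missing:
        raise ValueError(f"stage io: specimen id mismatch between TPS and covariates: "
                         f"{sorted(missing)[0]!r}")
    images = []
    for c in configs:
        ref = c.image_ref if c.image_ref else f"images/{c.specimen_id}.png"
        path = data_dir / ref
        if not path.exists():
            raise ValueError(f"stage io: missing image for specimen {c.specimen_id!r}")
        images.append(load_image(path))
    return _Dataset(
        ids=tps_ids,
        landmarks=np.stack([c.points for c in configs]),
        scheme=scheme,
        images=images,
        covariates={name: cov.loc[tps_ids, name].to_numpy() for name in config.covariates},
    )


def _slid_image_landmarks(aligned: np.ndarray, original_px: np.ndarray) -> np.ndarray:
    """Map slid (aligned-frame) landmarks back into each image's pixel frame
    via the least-squares similarity between the aligned and digitized points."""
    out = np.empty_like(original_px)
    for i in range(aligned.shape[0]):
        A, t = fit_similarity(aligned[i], original_px[i])
        out[i] = aligned[i] @ A + t
    return out


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the whole analysis and write report, figures, and resolved config."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_resolved_yaml(out_dir / "config_resolved.yaml")
    t0 = time.time()
    ds = _load_dataset(config, out_dir)
    n = len(ds.ids)
    logger.info("loaded %d specimens (%.1fs)", n, time.time() - t0)

    # superimposition + sliding on the warp set
    try:
        slid, full_res = slide_semilandmarks(ds.landmarks, ds.scheme,
                                             specimen_ids=ds.ids)
    except ValueError as e:
        raise ValueError(f"stage superimposition: {e}") from e
    logger.info("GPA+sliding done: %d iterations, converged=%s",
                full_res.n_iterations, full_res.converged)

    # shape block: re-superimpose the shape subset of the slid configurations
    sub = np.array(ds.scheme.shape_subset)
    sub_res = gpa(slid[:, sub, :])
    X_shape = sub_res.aligned.reshape(n, -1)
    # rendering block: the full warp set in the common alignment
    X_warp = full_res.aligned.reshape(n, -1)

    # texture block: register every photograph to the mean shape frame
    frame = build_mean_frame(full_res.mean_shape, height=config.frame_size,
                             width=config.frame_size)
    slid_px = _slid_image_landmarks(full_res.aligned, ds.landmarks)
    textures = []
    for i in range(n):
        try:
            textures.append(register_image(ds.images[i], slid_px[i], frame))
        except ValueError as e:
            raise ValueError(f"stage registration: specimen {ds.ids[i]!r}: {e}") from e
    X_tex = np.stack([t.vector for t in textures])
    logger.info("registration done (%.1fs)", time.time() - t0)

    pca_shape = mstats.fit_pca(X_shape)
    pca_tex = mstats.fit_pca(X_tex)
    S_shape = pca_shape.transform(X_shape)
    S_tex = pca_tex.transform(X_tex)
    n_lead = min(4, S_shape.shape[1], S_tex.shape[1])
    r2 = [[float(np.corrcoef(S_shape[:, i], S_tex[:, j])[0, 1] ** 2)
           for j in range(n_lead)] for i in range(n_lead)]

    rng = np.random.default_rng(config.seed)
    cov_results: dict[str, dict] = {}
    models: dict[str, dict] = {}
    for name in config.covariates:
        x = ds.covariates[name]
        res: dict = {}
        for label, X in (("shape", X_shape), ("texture", X_tex)):
            model = mstats.regress_on_covariate(X, x, name)
            model.p_perm = mstats.permutation_test(
                X, x, n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)))
            loocv = mstats.loocv_scores(X, x, name)
            res[label] = {"r_within": model.r_within, "p_perm": model.p_perm,
                          "r_cv": loocv.r_cv}
            models.setdefault(name, {})[label] = model
        models[name]["warp"] = mstats.regress_on_covariate(X_warp, x, name)
        for label, X in (("shape", X_shape), ("texture", X_tex)):
            res[f"pcr_{label}"] = {}
            for n_pcs in config.n_pcs_list:
                if n_pcs > min(n - 2, X.shape[1]):
                    continue
                rep = mstats.pcr_predict(X, x, n_pcs, strict_cv=config.strict_cv)
                res[f"pcr_{label}"][str(n_pcs)] = {"r_within": rep.r_within,
                                                   "r_cv": rep.r_cv}
            res[f"ridge_{label}"] = {}
            for alpha in config.alphas:
                rep = mstats.ridge_predict(X, x, alpha)
                res[f"ridge_{label}"][f"{alpha:g}"] = {"r_within": rep.r_within,
                                                       "r_cv": rep.r_cv}
        comb = mstats.combine_scores([X_shape, X_tex], x)
        res["combined"] = {"r_within": comb.r_within, "r_cv": comb.r_cv}
        cov_results[name] = res
        logger.info("covariate %s done (%.1fs)", name, time.time() - t0)

    figures: list[str] = []
    if config.make_figures:
        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        avg_tex = mean_texture(textures)
        save_image(avg_tex.channels, fig_dir / "mean_face.png")
        figures.append("figures/mean_face.png")
        for block, pca, S in (("shape", pca_shape, S_shape), ("texture", pca_tex, S_tex)):
            p = fig_dir / f"scree_{block}.png"
            figure_scree(pca, p)
            figures.append(str(p.relative_to(out_dir)))
        for name in config.covariates:
            x = ds.covariates[name]
            for block, pca, S in (("shape", pca_shape, S_shape),
                                  ("texture", pca_tex, S_tex)):
                p = fig_dir / f"pc_scatter_{block}_{name}.png"
                figure_pc_scatter(S, x, models[name][block.split("_")[0]], pca, p)
                figures.append(str(p.relative_to(out_dir)))
            p = fig_dir / f"reconstruction_{name}.png"
            figure_reconstruction_row(models[name]["warp"], models[name]["texture"],
                                      x, frame, avg_tex, full_res.mean_shape, p)
            figures.append(str(p.relative_to(out_dir)))
            p = fig_dir / f"channels_{name}.png"
            figure_channel_panels(models[name]["texture"], x, frame, p)
            figures.append(str(p.relative_to(out_dir)))

    report = AnalysisReport(
        n_specimens=n,
        seed=config.seed,
        shape_variance_fractions=[float(f) for f in pca_shape.variance_fractions[:10]],
        texture_variance_fractions=[float(f) for f in pca_tex.variance_fractions[:10]],
        covariate_results=cov_results,
        pc_shape_texture_r2=r2,
        gpa_iterations=full_res.n_iterations,
        gpa_converged=bool(full_res.converged),
        figures=figures,
    )
    report.validate()
    report.to_json(out_dir / "report.json")
    (out_dir / "report.txt").write_text(report.summary() + "\n")
    logger.info("analysis complete (%.1fs)", time.time() - t0)
    return report


# --------------------------------------------------------------------------
# figures
# --------------------------------------------------------------------------

def figure_scree(pca: mstats.PCAModel, path: str | Path, n_show: int = 15) -> None:
    fr = pca.variance_fractions[:n_show]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(np.arange(1, len(fr) + 1), fr, "o-")
    ax.set_xlabel("principal component")
    ax.set_ylabel("variance fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def project_effect_direction(model: mstats.CovariateEffectModel,
                             pca: mstats.PCAModel) -> np.ndarray:
    """The regression coefficient vector projected onto PC1-PC2 (unit length)."""
    proj = pca.loadings[:, :2].T @ model.b
    norm = np.linalg.norm(proj)
    return proj / norm if norm > 0 else proj


def figure_pc_scatter(scores: np.ndarray, covariate: np.ndarray,
                      model: mstats.CovariateEffectModel, pca: mstats.PCAModel,
                      path: str | Path) -> None:
    """PC1-PC2 scatter, marker size proportional to the covariate, with the
    direction of maximal covariate increase overlaid."""
    fig, ax = plt.subplots(figsize=(4, 4))
    sizes = 60 * covariate / covariate.max()
    ax.scatter(scores[:, 0], scores[:, 1], s=sizes, alpha=0.6)
    if np.std(covariate) > 0:
        d = project_effect_direction(model, pca)
        span = 0.8 * np.abs(scores[:, :2]).max()
        ax.plot([-span * d[0], span * d[0]], [-span * d[1], span * d[1]], "r-")
    else:
        ax.set_title("constant covariate: no direction")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def figure_reconstruction_row(shape_model: mstats.CovariateEffectModel,
                              texture_model: mstats.CovariateEffectModel,
                              covariate: np.ndarray, frame: MeanFrame,
                              avg_texture: RegisteredTexture, mean_shape: np.ndarray,
                              path: str | Path,
                              sd_multiples: tuple[float, ...] = (-4, -2, 0, 2, 4)) -> None:
    """Rows of reconstructed faces at the covariate mean and +/-2, +/-4 SD:
    shape only (mean texture in reconstructed shape), texture only
    (reconstructed texture in the mean shape), and both together."""
    sd = float(np.std(covariate, ddof=1))
    values = [texture_model.x_mean + m * sd for m in sd_multiples]
    fig, axes = plt.subplots(3, len(values), figsize=(2 * len(values), 6))
    for j, v in enumerate(values):
        shp = shape_model.data_mean + (v - shape_model.x_mean) * shape_model.b
        shp = shp.reshape(-1, 2)
        tex_vec = np.clip(mstats.reconstruct_at(texture_model, v), 0.0, 1.0)
        tex = RegisteredTexture.from_vector(tex_vec, frame)
        panels = [render_shape(avg_texture, frame, shp),
                  tex.channels,
                  render_shape(tex, frame, shp)]
        for i, panel in enumerate(panels):
            axes[i, j].imshow(panel)
            axes[i, j].axis("off")
        axes[0, j].set_title(f"{v:.2f}", fontsize=8)
    for i, lab in enumerate(("shape", "texture", "both")):
        axes[i, 0].set_ylabel(lab)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def figure_channel_panels(texture_model: mstats.CovariateEffectModel,
                          covariate: np.ndarray, frame: MeanFrame,
                          path: str | Path,
                          sd_multiples: tuple[float, ...] = (-2, 0, 2)) -> None:
    """Hue-centered texture predictions shown per color channel.

    Each prediction has its per-pixel brightness removed (channels centered
    within each pixel) so the panels show the association of hue, not
    lightness, with the covariate."""
    sd = float(np.std(covariate, ddof=1))
    values = [texture_model.x_mean + m * sd for m in sd_multiples]
    fig, axes = plt.subplots(3, len(values), figsize=(2 * len(values), 6))
    for j, v in enumerate(values):
        centered = mstats.hue_center(mstats.reconstruct_at(texture_model, v))
        planes = centered.reshape(frame.height, frame.width, 3)
        for i, ch in enumerate("RGB"):
            axes[i, j].imshow(planes[:, :, i], cmap="RdBu_r", vmin=-0.15, vmax=0.15)
            axes[i, j].axis("off")
            if j == 0:
                axes[i, j].set_ylabel(ch)
        axes[0, j].set_title(f"{v:.2f}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
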