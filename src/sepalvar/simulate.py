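"""Synthetic data generator for the sepal-robustness pipeline.

Emulates the structure of the study data so every downstream stage is
testable without any download: per-sepal measurement tables (11 wild-type
control batches, 16 knockout mutants of 39-90 sepals each), a wild-type
expression matrix (genes x 27 individual sepals) with a decreasing
mean-CV^2 trend plus highly variable outlier genes, an optional planted
linear relation between mutant CV^2 and log10 mean wild-type expression,
and rasterized sepal outlines for the morphometrics stage.

Per-sepal values are drawn from gamma distributions parameterized by
(mean, CV^2): strictly positive laws that match exactly the two moments
the analysis uses.  Length and width are drawn independently with a common
per-genotype CV^2 ``c``; area = (pi/4) * length * width and aspect ratio =
length / width are then deterministic per sepal, so for a target area CV^2
``t`` the generator solves (1 + c)^2 - 1 = t, i.e. c = sqrt(1 + t) - 1,
which makes the *true* area CV^2 equal ``t`` exactly.  The true aspect-ratio
CV^2 of the ratio of two independent gammas with equal CV^2 ``c`` has the
closed form c * (2 - c) / (1 - 2 c), recorded in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidConfigError, InvalidInputError

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "MUTANT_LABELS",
    "MUTANT_GENE_IDS",
    "CONTROL_LABEL",
    "gen_expression_matrix",
    "gen_measurement_table",
    "simulate_dataset",
    "gen_sepal_contour",
    "rasterize_contour",
    "write_bundle",
]

#: Genotype label used for wild-type control rows.
CONTROL_LABEL = "col-0"

#: The 16 knockout mutants of cell-wall genes, in a fixed canonical order.
MUTANT_LABELS = (
    "bglu42", "csi1", "cc1", "cesa6", "csld5", "cslg3", "expa15", "pme32",
    "pmei3", "pmr6", "mur4", "cslc8", "xth15", "xth6", "xth9", "galt29a",
)

#: AGI locus identifiers of the corresponding genes.
MUTANT_GENE_IDS = (
    "AT5G36890", "AT2G22125", "AT1G45688", "AT5G64740", "AT1G02730",
    "AT4G23990", "AT2G03090", "AT3G43270", "AT5G20740", "AT3G54920",
    "AT1G30620", "AT2G24630", "AT4G14130", "AT5G65730", "AT4G03210",
    "AT1G08280",
)

PARAMETERS = ("area", "length", "width", "aspect_ratio")

# CV^2 values are floored here to keep gamma shapes finite; at the default
# parameters the floor is never reached.
_CV2_FLOOR = 1e-4

# Mean-CV^2 trend of the background expression cloud (log10-log10 scale).
_TREND_INTERCEPT = -0.3
_TREND_SLOPE = -0.5
_TREND_SCATTER = 0.35
_OUTLIER_FRACTION = 0.05

_MEAN_ASPECT = 2.0  # typical stage-13 sepal: twice as long as wide
_SHAPE_FACTOR = np.pi / 4.0  # ellipse-like area = k * length * width


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the design of the real study: 11 control batches,
    16 mutants with 39-90 sepals each, and a 27-sepal wild-type expression
    matrix.  ``planted_slope`` is the linear coefficient of mutant area
    CV^2 on log10 mean wild-type expression of the knocked-out gene
    (dimensionless CV^2 per decade); ``noise_sd`` is the standard deviation
    of the scatter of true CV^2 around that line; ``effect_scale`` is the
    standard deviation of the relative shift of each mutant's mean area
    from its control batch.
    """

    n_control_batches: int = 11
    n_mutants: int = 16
    sepals_per_genotype_range: tuple[int, int] = (39, 90)
    control_mean_area: float = 2.3     # mm^2
    control_cv2: float = 0.012         # area CV^2 of wild-type batches
    effect_scale: float = 0.10
    planted_slope: float = 0.02
    noise_sd: float = 0.004
    n_expr_sepals: int = 27
    n_expr_genes: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sepals_per_genotype_range
        if lo < 2:
            raise InvalidConfigError("sepals_per_genotype_range lower bound must be >= 2")
        if lo > hi:
            raise InvalidConfigError("sepals_per_genotype_range lower bound exceeds upper bound")
        if self.n_control_batches < 1 or self.n_mutants < 1:
            raise InvalidConfigError("need at least one control batch and one mutant")
        if self.control_mean_area <= 0 or self.control_cv2 <= 0:
            raise InvalidConfigError("control_mean_area and control_cv2 must be positive")
        if self.effect_scale < 0 or self.noise_sd < 0:
            raise InvalidConfigError("effect_scale and noise_sd must be non-negative")
        if self.n_expr_sepals < 2 or self.n_expr_genes < 1:
            raise InvalidConfigError("expression matrix dimensions must be positive (>= 2 sepals)")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for parameter-recovery tests.

    ``genotypes`` has one row per (genotype, batch, parameter) with the true
    mean and true CV^2; ``genes`` one row per gene with true mean expression
    and true expression CV^2; ``planted_slope_realized`` is the OLS slope of
    true area CV^2 on log10 true mean expression over the mutants as
    actually realized (equals the configured slope when ``noise_sd`` is 0).
    """

    genotypes: pd.DataFrame
    genes: pd.DataFrame
    gene_map: pd.DataFrame
    planted_slope_realized: float = field(default=np.nan)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genotypes": self.genotypes.to_dict(orient="records"),
            "genes": self.genes.to_dict(orient="records"),
            "gene_map": self.gene_map.to_dict(orient="records"),
            "planted_slope_realized": self.planted_slope_realized,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gamma(rng: np.random.Generator, mean: float, cv2: float, size: int) -> np.ndarray:
    """Gamma draws with the requested mean and squared coefficient of variation."""
    if cv2 <= 0:
        return np.full(size, float(mean))
    shape = 1.0 / cv2
    return rng.gamma(shape, mean / shape, size)


def _mutant_labels(n: int) -> list[str]:
    labels = list(MUTANT_LABELS[:n])
    labels += [f"mutant{i:02d}" for i in range(len(labels) + 1, n + 1)]
    return labels


def _mutant_gene_ids(n: int) -> list[str]:
    ids = list(MUTANT_GENE_IDS[:n])
    ids += [f"ATSYN{i:05d}" for i in range(len(ids) + 1, n + 1)]
    return ids


def _shared_truth(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Quantities shared between the measurement table and the expression
    matrix (mutant gene means, planted CV^2 levels, batch/mutant shifts).

    Drawn from a dedicated seed stream so that :func:`gen_measurement_table`
    and :func:`gen_expression_matrix` are individually callable yet mutually
    consistent for the same config.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, 0)))
    log10_mu_expr = rng.uniform(1.0, 4.0, cfg.n_mutants)
    cv2_noise = rng.normal(0.0, cfg.noise_sd, cfg.n_mutants) if cfg.noise_sd > 0 else np.zeros(cfg.n_mutants)
    mean_shift = rng.normal(0.0, cfg.effect_scale, cfg.n_mutants) if cfg.effect_scale > 0 else np.zeros(cfg.n_mutants)
    batch_shift = (
        rng.normal(0.0, 0.5 * cfg.effect_scale, cfg.n_control_batches)
        if cfg.effect_scale > 0 else np.zeros(cfg.n_control_batches)
    )
    # planted line, anchored so the lowest-expressed gene sits at the control level
    cv2_area = cfg.control_cv2 + cfg.planted_slope * (log10_mu_expr - 1.0) + cv2_noise
    cv2_area = np.clip(cv2_area, _CV2_FLOOR, None)
    return {
        "log10_mu_expr": log10_mu_expr,
        "cv2_area": cv2_area,
        "mean_shift": np.clip(mean_shift, -0.8, None),
        "batch_shift": np.clip(batch_shift, -0.8, None),
    }


def _component_cv2(area_cv2: np.ndarray | float) -> np.ndarray | float:
    """CV^2 of length and width such that area = k*L*W has CV^2 ``area_cv2``
    when L and W are independent: (1+c)^2 - 1 = t  =>  c = sqrt(1+t) - 1."""
    return np.sqrt(1.0 + np.asarray(area_cv2, dtype=float)) - 1.0


def _aspect_cv2(c: np.ndarray | float) -> np.ndarray | float:
    """Exact CV^2 of the ratio of two independent gammas with CV^2 ``c`` each."""
    c = np.asarray(c, dtype=float)
    return c * (2.0 - c) / (1.0 - 2.0 * c)


def _block_truth(genotype: str, batch: str, mu_l: float, mu_w: float, c: float) -> list[dict]:
    t_area = (1.0 + c) ** 2 - 1.0
    return [
        {"genotype": genotype, "batch": batch, "parameter": "length",
         "true_mean": mu_l, "true_cv2": c},
        {"genotype": genotype, "batch": batch, "parameter": "width",
         "true_mean": mu_w, "true_cv2": c},
        {"genotype": genotype, "batch": batch, "parameter": "area",
         "true_mean": _SHAPE_FACTOR * mu_l * mu_w, "true_cv2": t_area},
        {"genotype": genotype, "batch": batch, "parameter": "aspect_ratio",
         "true_mean": mu_l / (mu_w * (1.0 - c)), "true_cv2": float(_aspect_cv2(c))},
    ]


def gen_measurement_table(cfg: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the per-sepal measurement table.

    One control block per batch (genotype ``col-0``) and one mutant block per
    mutant, each mutant assigned round-robin to one control batch.  Returns
    the tidy table (columns genotype, batch, sepal_id, length, width, area,
    aspect_ratio) and the ground truth.
    """
    shared = _shared_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, 2)))
    lo, hi = cfg.sepals_per_genotype_range

    mu_l0 = float(np.sqrt(cfg.control_mean_area * _MEAN_ASPECT / _SHAPE_FACTOR))
    mu_w0 = mu_l0 / _MEAN_ASPECT
    c_control = float(_component_cv2(cfg.control_cv2))

    labels = _mutant_labels(cfg.n_mutants)
    gene_ids = _mutant_gene_ids(cfg.n_mutants)
    batches = [f"batch{b + 1:02d}" for b in range(cfg.n_control_batches)]

    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    def emit(genotype: str, batch: str, mu_l: float, mu_w: float, c: float) -> None:
        n = int(rng.integers(lo, hi + 1))
        length = _gamma(rng, mu_l, c, n)
        width = _gamma(rng, mu_w, c, n)
        rows.append(pd.DataFrame({
            "genotype": genotype,
            "batch": batch,
            "sepal_id": [f"{genotype}-{batch}-{i + 1:03d}" for i in range(n)],
            "length": length,
            "width": width,
            "area": _SHAPE_FACTOR * length * width,
            "aspect_ratio": length / width,
        }))
        truth_rows.extend(_block_truth(genotype, batch, mu_l, mu_w, c))

    batch_mu_l = {}
    for b, batch in enumerate(batches):
        scale = float(np.sqrt(1.0 + shared["batch_shift"][b]))
        batch_mu_l[batch] = mu_l0 * scale
        emit(CONTROL_LABEL, batch, mu_l0 * scale, mu_w0 * scale, c_control)

    for m, genotype in enumerate(labels):
        batch = batches[m % cfg.n_control_batches]
        scale = float(np.sqrt(1.0 + shared["mean_shift"][m]))
        c = float(_component_cv2(shared["cv2_area"][m]))
        emit(genotype, batch, batch_mu_l[batch] * scale,
             batch_mu_l[batch] * scale / _MEAN_ASPECT, c)

    table = pd.concat(rows, ignore_index=True)

    genotypes = pd.DataFrame(truth_rows)
    genes = pd.DataFrame({
        "gene": gene_ids,
        "true_mean": 10.0 ** shared["log10_mu_expr"],
        "true_cv2": np.nan,
    })
    gene_map = pd.DataFrame({"gene": gene_ids, "genotype": labels})
    truth = SyntheticTruth(genotypes=genotypes, genes=genes, gene_map=gene_map,
                           planted_slope_realized=_realized_slope(shared))
    return table, truth


def _realized_slope(shared: dict[str, np.ndarray]) -> float:
    x = shared["log10_mu_expr"]
    y = shared["cv2_area"]
    if len(x) < 2 or np.ptp(x) == 0:
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def gen_expression_matrix(cfg: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the wild-type expression matrix (genes x individual sepals).

    The first ``n_mutants`` rows are the mutant genes whose means drive the
    planted CV^2 relation; the remaining rows form a background cloud with
    log-uniform means over several orders of magnitude, a decreasing
    mean-CV^2 trend with lognormal scatter, and a fraction of inflated-CV^2
    outlier genes.  Per-sepal values are gamma draws with the gene's (mean,
    CV^2).
    """
    if cfg.n_expr_genes < cfg.n_mutants:
        raise InvalidConfigError("n_expr_genes must be >= n_mutants (mutant genes are included)")
    shared = _shared_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, 1)))

    n_bg = cfg.n_expr_genes - cfg.n_mutants
    log10_mu = np.concatenate([shared["log10_mu_expr"], rng.uniform(-1.0, 4.0, n_bg)])
    log10_cv2 = (_TREND_INTERCEPT + _TREND_SLOPE * log10_mu
                 + rng.normal(0.0, _TREND_SCATTER, cfg.n_expr_genes))
    outliers = rng.random(cfg.n_expr_genes) < _OUTLIER_FRACTION
    log10_cv2 = log10_cv2 + outliers * rng.uniform(0.7, 1.5, cfg.n_expr_genes)

    mu = 10.0 ** log10_mu
    cv2 = np.clip(10.0 ** log10_cv2, _CV2_FLOOR, None)

    gene_ids = _mutant_gene_ids(cfg.n_mutants) + [f"ATBKG{i:05d}" for i in range(1, n_bg + 1)]
    samples = [f"sepal_{j + 1:02d}" for j in range(cfg.n_expr_sepals)]
    values = np.empty((cfg.n_expr_genes, cfg.n_expr_sepals))
    for g in range(cfg.n_expr_genes):
        values[g] = _gamma(rng, mu[g], cv2[g], cfg.n_expr_sepals)

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    genes = pd.DataFrame({"gene": gene_ids, "true_mean": mu, "true_cv2": cv2})
    gene_map = pd.DataFrame({"gene": _mutant_gene_ids(cfg.n_mutants),
                             "genotype": _mutant_labels(cfg.n_mutants)})
    truth = SyntheticTruth(genotypes=pd.DataFrame(), genes=genes, gene_map=gene_map,
                           planted_slope_realized=_realized_slope(shared))
    return matrix, truth


def simulate_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """One consistent bundle: (measurements, expression matrix, gene map, truth)."""
    table, truth_m = gen_measurement_table(cfg)
    matrix, truth_e = gen_expression_matrix(cfg)
    truth = SyntheticTruth(
        genotypes=truth_m.genotypes,
        genes=truth_e.genes,
        gene_map=truth_e.gene_map,
        planted_slope_realized=truth_m.planted_slope_realized,
    )
    return table, matrix, truth.gene_map, truth


# ---------------------------------------------------------------------------
# shape fixtures: superellipse outlines and rasterization
# ---------------------------------------------------------------------------

def gen_sepal_contour(
    length: float,
    width: float,
    tip_sharpness: float = 2.0,
    noise_sd: float = 0.0,
    n_vertices: int = 512,
    seed: int = 0,
) -> np.ndarray:
    """Closed superellipse-like outline with optional multiplicative boundary noise.

    ``tip_sharpness`` is the superellipse exponent: 2.0 gives an exact
    ellipse; larger values give blunter, more sepal-like tips.  The long
    axis lies along y.  Returns an (n_vertices, 2) float array of (x, y)
    vertices in counter-clockwise order; at ``noise_sd`` 0 the polygon is
    simple and its principal-axis extents equal ``length`` and ``width`` up
    to the angular sampling resolution.
    """
    if length <= 0 or width <= 0:
        raise InvalidConfigError("length and width must be positive")
    if length < width:
        raise InvalidConfigError("length must be >= width")
    if n_vertices < 8:
        raise InvalidConfigError("n_vertices must be >= 8")
    if tip_sharpness <= 0:
        raise InvalidConfigError("tip_sharpness must be positive")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be non-negative")

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    e = 2.0 / tip_sharpness
    x = 0.5 * width * np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** e
    y = 0.5 * length * np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** e
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = 1.0 + rng.normal(0.0, noise_sd, n_vertices)
        x, y = x * r, y * r
    return np.column_stack([x, y])


def rasterize_contour(
    polygon: np.ndarray,
    image_size: tuple[int, int],
    scale: float | None = None,
    background: int = 0,
    foreground: int = 255,
) -> np.ndarray:
    """Render a closed polygon as an 8-bit grayscale image (white on black).

    The polygon is centred in the image and scaled by ``scale`` pixels per
    unit (default: fitted to 90% of the smaller image dimension).  Raises if
    the scaled polygon does not fit inside the image or is degenerate.
    """
    from skimage.draw import polygon as _fill_polygon

    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise InvalidInputError("polygon must be an (n>=3, 2) vertex array")
    spans = verts.max(axis=0) - verts.min(axis=0)
    if np.any(spans <= 0):
        raise InvalidInputError("degenerate polygon (zero extent)")

    h, w = int(image_size[0]), int(image_size[1])
    if scale is None:
        scale = 0.9 * min((w - 2) / spans[0], (h - 2) / spans[1])
    centre = (verts.max(axis=0) + verts.min(axis=0)) / 2.0
    # math convention (y up) -> raster convention (row down)
    cols = (verts[:, 0] - centre[0]) * scale + (w - 1) / 2.0
    rows = (h - 1) / 2.0 - (verts[:, 1] - centre[1]) * scale
    if cols.min() < -0.5 or cols.max() > w - 0.5 or rows.min() < -0.5 or rows.max() > h - 0.5:
        raise InvalidInputError("scaled polygon does not fit inside the image")

    img = np.full((h, w), np.uint8(background), dtype=np.uint8)
    rr, cc = _fill_polygon(rows, cols, shape=(h, w))
    img[rr, cc] = np.uint8(foreground)
    return img


def write_bundle(cfg: SimConfig, out_dir: str | Path, images: int = 0) -> dict[str, str]:
    """Write a full synthetic bundle (CSV tables, truth JSON, optional PNGs).

    Returns a dict of logical name -> file path.  With ``images`` > 0, that
    many single-sepal photographs (white shape on black background) are
    rendered from the first rows of the measurement table together with a
    labels CSV for :func:`sepalvar.morphometrics.batch_measure`.
    """
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, matrix, gene_map, truth = simulate_dataset(cfg)

    paths = {
        "measurements": str(out / "measurements.csv"),
        "expression": str(out / "expression.csv"),
        "gene_map": str(out / "gene_map.csv"),
        "truth": str(out / "truth.json"),
    }
    _io.write_measurement_table(table, paths["measurements"])
    _io.write_expression_matrix(matrix, paths["expression"])
    gene_map.to_csv(paths["gene_map"], index=False)
    truth.to_json(paths["truth"])

    if images > 0:
        import imageio.v3 as iio

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        label_rows = []
        sub = table.head(images)
        for i, rec in enumerate(sub.itertuples(index=False)):
            poly = gen_sepal_contour(rec.length, rec.width, tip_sharpness=2.5,
                                     n_vertices=720, seed=cfg.seed + i)
            img = rasterize_contour(poly, (256, 256), scale=200.0 / rec.length)
            name = f"sepal_{i:03d}.png"
            iio.imwrite(img_dir / name, img)
            label_rows.append({"filename": name, "genotype": rec.genotype, "batch": rec.batch})
        pd.DataFrame(label_rows).to_csv(img_dir / "labels.csv", index=False)
        paths["images"] = str(img_dir)
    return paths
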