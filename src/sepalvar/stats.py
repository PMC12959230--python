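"""Per-genotype and per-gene robustness statistics and correlation screens.

The two core statistics:

* squared coefficient of variation, CV^2 = (sd / mean)^2, computed with the
  sample (n-1) standard deviation — a scale-free dispersion measure applied
  both to sepal shape parameters within a genotype and to gene expression
  across individual wild-type sepals;
* relative effect = (mean(mutant) - mean(control batch)) / mean(control
  batch) — the batch-corrected phenotypic shift of a mutant, used in
  absolute value for the correlation screens.

The screens are plain two-sided Pearson tests of each response
(|relative effect| or CV^2, per shape parameter) against each expression
covariate (expression CV^2 or log10 mean expression) across mutants.
log10 is a display convention only: Pearson r and p are invariant to
affine transforms of either variable, so the log base cannot change any
screen's result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)

__all__ = [
    "PARAMETERS",
    "RESPONSES",
    "COVARIATES",
    "ExpressionMatrix",
    "SummaryStats",
    "GeneExpressionSummary",
    "CorrelationResult",
    "ReferenceBand",
    "summarize",
    "relative_effect",
    "summary_table",
    "expression_summary",
    "pearson_test",
    "build_screen_table",
    "run_screens",
    "reference_band",
    "sample_size_confound",
]

log = logging.getLogger(__name__)

PARAMETERS = ("area", "length", "width", "aspect_ratio")
RESPONSES = ("abs_rel_effect", "cv2")
COVARIATES = ("cv2_expr", "log10_mean_expr")

#: Genotype label identifying wild-type control rows.
CONTROL_LABEL = "col-0"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid with a gene-to-mutant map.

    ``values``: DataFrame indexed by gene id, one column per sample, all
    cells non-negative.  ``gene_map``: DataFrame with columns (gene,
    genotype) linking each knocked-out gene to its mutant line.  Unmapped
    genes are retained (background cloud).
    """

    values: pd.DataFrame
    gene_map: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "genotype"]))

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate gene ids in expression matrix")
        if (self.values.values < 0).any():
            raise InvalidInputError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SummaryStats:
    genotype: str
    parameter: str
    n: int
    mean: float
    sd: float
    cv2: float


@dataclass(frozen=True)
class GeneExpressionSummary:
    gene: str
    mean_expr: float
    cv2_expr: float
    log10_mean_expr: float  # NaN when mean_expr == 0


@dataclass(frozen=True)
class CorrelationResult:
    """One two-sided Pearson test."""

    response: str
    covariate: str
    n: int
    r: float
    p: float
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReferenceBand:
    """Mean +/- sd of per-batch wild-type CV^2 for one parameter."""

    parameter: str
    mean_cv2: float
    sd_cv2: float
    n_batches: int


def summarize(values) -> tuple[float, float, float]:
    """(mean, sample sd, CV^2) of a sequence of positive measurements.

    sd uses the n-1 denominator; CV^2 = (sd / mean)^2.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise InvalidInputError("summarize expects a 1-D sequence")
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise InvalidInputError("non-positive mean")
    sd = float(v.std(ddof=1))
    return mean, sd, (sd / mean) ** 2


def relative_effect(mutant_mean: float, control_mean: float) -> tuple[float, float]:
    """(signed relative effect, absolute relative effect) of a mutant mean
    versus its control-batch mean."""
    if control_mean <= 0:
        raise InvalidInputError("control mean must be positive")
    rel = (mutant_mean - control_mean) / control_mean
    return rel, abs(rel)


def summary_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(genotype, batch, parameter) SummaryStats as a tidy DataFrame."""
    rows = []
    for (genotype, batch), grp in measurements.groupby(["genotype", "batch"], sort=True):
        for parameter in PARAMETERS:
            mean, sd, cv2 = summarize(grp[parameter].to_numpy())
            rows.append({"genotype": genotype, "batch": batch, "parameter": parameter,
                         "n": len(grp), "mean": mean, "sd": sd, "cv2": cv2})
    return pd.DataFrame(rows)


def expression_summary(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean, CV^2 and log10 mean over samples.

    Genes with zero mean get ``log10_mean_expr`` NaN and ``zero_mean`` True;
    they are excluded from log-scale screens downstream.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise InsufficientDataError("need at least 2 samples per gene")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, (sd / np.where(mean > 0, mean, 1.0)) ** 2, np.nan)
        log10_mean = np.where(mean > 0, np.log10(np.where(mean > 0, mean, 1.0)), np.nan)
    return pd.DataFrame({
        "gene": values.index.to_numpy(),
        "mean_expr": mean,
        "cv2_expr": cv2,
        "log10_mean_expr": log10_mean,
        "zero_mean": mean == 0,
    })


def pearson_test(
    x,
    y,
    response: str = "y",
    covariate: str = "x",
    excluded: tuple[str, ...] = (),
) -> CorrelationResult:
    """Two-sided Pearson correlation test.

    p is computed from t = r sqrt((n-2) / (1-r^2)) against a t distribution
    with n-2 degrees of freedom (the classic exact null under bivariate
    normality).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and of equal length")
    n = xv.size
    if n < 3:
        raise InsufficientDataError("Pearson test needs n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.NearConstantInputWarning)
        r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(response=response, covariate=covariate, n=n,
                             r=float(r), p=float(p), excluded=tuple(excluded))


def build_screen_table(
    measurements: pd.DataFrame,
    expr: ExpressionMatrix,
    control_label: str = CONTROL_LABEL,
) -> tuple[pd.DataFrame, list[dict]]:
    """Join per-mutant shape statistics with wild-type expression summaries.

    One record per mutant per parameter: sample size, mean, CV^2, signed and
    absolute relative effect versus the mutant's own control batch, and the
    mapped gene's mean expression, log10 mean expression and expression
    CV^2.  Mutants without a mapped gene (or whose batch lacks controls) are
    excluded and reported in the rejects list.
    """
    stats = summary_table(measurements)
    controls = stats[stats["genotype"] == control_label]
    mutants = stats[stats["genotype"] != control_label]
    if mutants.empty:
        raise InvalidInputError("no mutant rows in measurement table")

    expr_sum = expression_summary(expr).set_index("gene")
    gene_by_genotype = dict(zip(expr.gene_map["genotype"], expr.gene_map["gene"]))

    control_means = {
        (rec.batch, rec.parameter): rec.mean for rec in controls.itertuples(index=False)
    }

    rows, rejects = [], []
    for (genotype, batch), grp in mutants.groupby(["genotype", "batch"], sort=True):
        gene = gene_by_genotype.get(genotype)
        if gene is None or gene not in expr_sum.index:
            rejects.append({"genotype": genotype, "reason": "no mapped gene in expression matrix"})
            log.warning("mutant %s has no mapped gene; excluded from screens", genotype)
            continue
        if (batch, "area") not in control_means:
            rejects.append({"genotype": genotype, "reason": f"batch {batch} has no control rows"})
            continue
        g = expr_sum.loc[gene]
        for rec in grp.itertuples(index=False):
            rel, abs_rel = relative_effect(rec.mean, control_means[(batch, rec.parameter)])
            rows.append({
                "genotype": genotype, "batch": batch, "parameter": rec.parameter,
                "n": rec.n, "mean": rec.mean, "sd": rec.sd, "cv2": rec.cv2,
                "rel_effect": rel, "abs_rel_effect": abs_rel,
                "gene": gene, "mean_expr": float(g["mean_expr"]),
                "cv2_expr": float(g["cv2_expr"]),
                "log10_mean_expr": float(g["log10_mean_expr"]),
            })
    return pd.DataFrame(rows), rejects


def run_screens(screen_table: pd.DataFrame, alpha: float = 0.05) -> list[CorrelationResult]:
    """The full correlation-screen grid.

    For every shape parameter, both responses (|relative effect| and CV^2)
    are tested against both covariates (expression CV^2 and log10 mean
    expression): 16 Pearson tests for the four parameters.  Mutants with
    undefined log10 mean expression are dropped from log-scale screens with
    a warning.
    """
    results = []
    for parameter in PARAMETERS:
        sub = screen_table[screen_table["parameter"] == parameter]
        for response in RESPONSES:
            for covariate in COVARIATES:
                s = sub
                if covariate == "log10_mean_expr":
                    bad = s["log10_mean_expr"].isna()
                    if bad.any():
                        log.warning("excluding %d mutant(s) with zero mean expression "
                                    "from log-scale screen", int(bad.sum()))
                        s = s[~bad]
                results.append(pearson_test(
                    s[covariate].to_numpy(), s[response].to_numpy(),
                    response=f"{response}({parameter})", covariate=covariate,
                ))
    return results


def reference_band(
    control_measurements: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
) -> list[ReferenceBand]:
    """Wild-type reference band per parameter: mean and sd (n-1) of the
    per-batch control CV^2 values (the dashed/dotted guide lines of the
    screen plots)."""
    controls = control_measurements[control_measurements["genotype"] == control_label]
    if controls.empty:
        controls = control_measurements
    n_batches = controls["batch"].nunique()
    if n_batches < 2:
        raise InsufficientDataError("reference band needs >= 2 control batches")
    bands = []
    for parameter in PARAMETERS:
        per_batch = [
            summarize(grp[parameter].to_numpy())[2]
            for _, grp in controls.groupby("batch", sort=True)
        ]
        arr = np.asarray(per_batch)
        bands.append(ReferenceBand(parameter=parameter, mean_cv2=float(arr.mean()),
                                   sd_cv2=float(arr.std(ddof=1)), n_batches=n_batches))
    return bands


def sample_size_confound(screen_table: pd.DataFrame) -> list[CorrelationResult]:
    """Per-parameter Pearson test of mutant CV^2 against sample size —
    the check that sample-size differences (39-90 sepals) do not drive the
    CV^2 screens."""
    results = []
    for parameter in PARAMETERS:
        sub = screen_table[screen_table["parameter"] == parameter]
        results.append(pearson_test(
            sub["n"].to_numpy(dtype=float), sub["cv2"].to_numpy(),
            response=f"cv2({parameter})", covariate="n",
        ))
    return results
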