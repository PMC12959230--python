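"""Resilience checks on the expression-variability correlation.

Two complementary experiments probe how stable the headline Pearson
correlation (mutant CV^2 of a shape parameter vs log10 mean wild-type
expression) is:

* **subsampling** — many replicates, each drawing a fixed number of sepals
  per mutant without replacement, recomputing every mutant's CV^2 and the
  correlation; the report records all (r, p) pairs and the fraction of
  replicates significant at alpha;
* **leave-x-out** — exhaustively re-running the correlation after removing
  every possible group of x mutants, optionally after first removing fixed
  outliers (e.g. the pmr6 mutant).

Leave-x-out enumeration defaults to *ordered* selections without
repetition (x-permutations), which for 16 mutants gives 16, 240 and 3360
tests at x = 1, 2, 3 (and 15, 210, 2730 after removing pmr6) — the counts
of the original analysis.  ``ordered=False`` switches to unordered subsets
(C(n, x) tests); the ordered multiset of results equals the unordered one
with every entry repeated x! times.

Subsampling randomness: one master seed spawns an independent substream
per (mutant, replicate), keyed by a stable hash of the mutant label, so
the report is invariant to the row order of the input table.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._errors import InvalidConfigError, InvalidInputError
from .stats import CorrelationResult, pearson_test, summarize

__all__ = [
    "SubsamplingSpec",
    "LeaveXOutSpec",
    "ResilienceReport",
    "DensitySummary",
    "subsample_replicates",
    "leave_x_out",
    "pvalue_distribution",
]


@dataclass(frozen=True)
class SubsamplingSpec:
    """Configuration of one subsampling experiment.

    Defaults follow the original design: 1000 replicates of 30 sepals per
    mutant, drawn without replacement, correlating the parameter's CV^2
    with log10 mean wild-type expression at alpha = 0.05.
    """

    n_subsample: int = 30
    n_replicates: int = 1000
    seed: int = 0
    alpha: float = 0.05
    response: str = "area"
    covariate: str = "log10_mean_expr"

    def __post_init__(self) -> None:
        if self.n_subsample < 3:
            raise InvalidConfigError("n_subsample must be >= 3")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class LeaveXOutSpec:
    """Configuration of one leave-x-out experiment.

    ``fixed_exclusions`` are removed before enumerating the x-subsets
    (the pmr6+x variants use fixed_exclusions=("pmr6",)).
    """

    x: int = 1
    fixed_exclusions: tuple[str, ...] = ()
    response: str = "area"
    covariate: str = "log10_mean_expr"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.x < 0:
            raise InvalidConfigError("x must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")


@dataclass
class ResilienceReport:
    """Per-combination (or per-replicate) correlation results plus the
    fraction of tests significant at alpha."""

    kind: str
    spec: dict
    results: list[CorrelationResult]
    alpha: float

    @property
    def combination_count(self) -> int:
        return len(self.results)

    @property
    def fraction_significant(self) -> float:
        if not self.results:
            return float("nan")
        return sum(res.p < self.alpha for res in self.results) / len(self.results)

    def fraction_significant_at(self, alpha: float) -> float:
        """Significance fraction of the same report at a stricter (or any)
        threshold; monotonically non-increasing as alpha decreases."""
        if not self.results:
            return float("nan")
        return sum(res.p < alpha for res in self.results) / len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"response": res.response, "covariate": res.covariate, "n": res.n,
             "r": res.r, "p": res.p, "excluded": ";".join(res.excluded)}
            for res in self.results
        ])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "spec": self.spec,
            "alpha": self.alpha,
            "combination_count": self.combination_count,
            "fraction_significant": self.fraction_significant,
            "results": [asdict(res) for res in self.results],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _label_hash(label: str) -> int:
    """Stable 31-bit hash of a genotype label (order-insensitive seeding)."""
    digest = hashlib.blake2s(label.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _covariate_by_genotype(screen_table: pd.DataFrame, covariate: str) -> dict[str, float]:
    sub = screen_table.drop_duplicates("genotype")
    return dict(zip(sub["genotype"], sub[covariate].astype(float)))


def subsample_replicates(
    measurements: pd.DataFrame,
    expr_summaries: pd.DataFrame,
    spec: SubsamplingSpec,
    control_label: str = "col-0",
    on_small_sample: str = "fail",
) -> ResilienceReport:
    """Run the subsampling experiment.

    ``measurements`` is the per-sepal table; ``expr_summaries`` any
    DataFrame with one row per mutant genotype carrying the covariate
    column (e.g. the screen table).  Each replicate draws
    ``spec.n_subsample`` sepals per mutant without replacement, recomputes
    the mutant's CV^2 of ``spec.response``, and tests it against the fixed
    covariate.  A mutant with fewer sepals than requested triggers the
    ``on_small_sample`` policy: "fail" (default) or "all" (use every sepal,
    with a warning recorded implicitly by the smaller n).
    """
    if on_small_sample not in ("fail", "all"):
        raise InvalidConfigError("on_small_sample must be 'fail' or 'all'")
    covariate_map = _covariate_by_genotype(
        expr_summaries[expr_summaries["genotype"] != control_label]
        if "genotype" in expr_summaries else expr_summaries,
        spec.covariate,
    )
    mutants = sorted(g for g in measurements["genotype"].unique() if g != control_label)
    missing = [g for g in mutants if g not in covariate_map]
    if missing:
        raise InvalidInputError(f"no covariate value for mutant(s): {missing}")
    # values sorted per mutant so the report is invariant to row order
    values = {
        g: np.sort(measurements.loc[measurements["genotype"] == g, spec.response]
                   .to_numpy(dtype=float))
        for g in mutants
    }
    for g, v in values.items():
        if v.size < spec.n_subsample and on_small_sample == "fail":
            raise InvalidInputError(
                f"mutant {g} has {v.size} sepals < n_subsample={spec.n_subsample}")

    x = np.array([covariate_map[g] for g in mutants])
    master = spec.seed & 0x7FFFFFFF
    results: list[CorrelationResult] = []
    for rep in range(spec.n_replicates):
        cv2 = np.empty(len(mutants))
        for i, g in enumerate(mutants):
            v = values[g]
            if v.size > spec.n_subsample:
                rng = np.random.default_rng(
                    np.random.SeedSequence((master, _label_hash(g), rep)))
                v = rng.choice(v, size=spec.n_subsample, replace=False)
            cv2[i] = summarize(v)[2]
        results.append(pearson_test(
            x, cv2, response=f"cv2({spec.response})", covariate=spec.covariate,
            excluded=(f"replicate={rep}",),
        ))
    return ResilienceReport(kind="subsampling", spec=asdict(spec), results=results,
                            alpha=spec.alpha)


def leave_x_out(
    screen_table: pd.DataFrame,
    spec: LeaveXOutSpec,
    ordered: bool = True,
    response_column: str = "cv2",
) -> ResilienceReport:
    """Exhaustive leave-x-out re-testing of one screen.

    The screen table is restricted to ``spec.response`` (shape parameter);
    after dropping ``spec.fixed_exclusions``, every ordered selection of
    ``spec.x`` distinct mutants (or unordered subset with ``ordered=False``)
    is removed in turn and the Pearson test of ``response_column`` against
    ``spec.covariate`` recomputed on the remainder.
    """
    sub = screen_table[screen_table["parameter"] == spec.response]
    if sub.empty:
        raise InvalidInputError(f"no rows for parameter {spec.response!r}")
    sub = sub.set_index("genotype")
    fixed = [g.lower() for g in spec.fixed_exclusions]
    unknown = [g for g in fixed if g not in sub.index]
    if unknown:
        raise InvalidConfigError(f"fixed exclusions not in table: {unknown}")
    labels = sorted(g for g in sub.index if g not in fixed)
    if len(labels) - spec.x < 3:
        raise InvalidConfigError(
            f"leave-{spec.x}-out on {len(labels)} mutants leaves fewer than 3")

    xall = sub[spec.covariate]
    yall = sub[response_column]
    enum = itertools.permutations if ordered else itertools.combinations
    results: list[CorrelationResult] = []
    for combo in enum(labels, spec.x):
        keep = [g for g in labels if g not in combo]
        results.append(pearson_test(
            xall.loc[keep].to_numpy(), yall.loc[keep].to_numpy(),
            response=f"{response_column}({spec.response})", covariate=spec.covariate,
            excluded=tuple(fixed) + tuple(combo),
        ))
    return ResilienceReport(kind="leave_x_out", spec=asdict(spec), results=results,
                            alpha=spec.alpha)


@dataclass
class DensitySummary:
    """Normalized density of log10 p-values from one resilience report."""

    grid_log10_p: np.ndarray
    density: np.ndarray
    fraction_below_alpha: float
    reference_p: float
    alpha: float
    degenerate: bool = False
    point_mass_at: float | None = None

    def integral(self) -> float:
        if self.degenerate:
            return 1.0
        return float(np.trapezoid(self.density, self.grid_log10_p))


def pvalue_distribution(
    report: ResilienceReport,
    reference_p: float,
    grid_points: int = 2048,
) -> DensitySummary:
    """Normalized density of the report's p-values on a log10 scale.

    Densities from different experiments are directly comparable because
    each integrates to 1 (the area-normalization of the leave-x-out
    figures).  A report whose p-values are all identical is returned as a
    flagged point mass instead of a KDE.
    """
    if not report.results:
        raise InvalidInputError("empty resilience report")
    p = np.array([res.p for res in report.results], dtype=float)
    logp = np.log10(np.clip(p, 1e-300, 1.0))
    frac = float(np.mean(p < report.alpha))
    if np.ptp(logp) == 0:
        return DensitySummary(
            grid_log10_p=np.array([logp[0]]), density=np.array([np.inf]),
            fraction_below_alpha=frac, reference_p=reference_p,
            alpha=report.alpha, degenerate=True, point_mass_at=float(p[0]),
        )
    kde = gaussian_kde(logp)
    bw = kde.factor * logp.std(ddof=1)
    grid = np.linspace(logp.min() - 6 * bw, logp.max() + 6 * bw, grid_points)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)  # exact area normalization
    return DensitySummary(grid_log10_p=grid, density=density,
                          fraction_below_alpha=frac, reference_p=reference_p,
                          alpha=report.alpha)
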