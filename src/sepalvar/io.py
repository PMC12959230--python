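"""Table/config I/O and end-to-end pipeline orchestration.

Canonical formats are plain CSV (UTF-8, header row mandatory, decimal
point `.`), auto-detecting comma/semicolon/tab delimiters on read:

* measurement table — columns genotype, batch, sepal_id, length, width,
  area, aspect_ratio; one row per sepal;
* expression matrix — first column the gene id, remaining columns one per
  sample;
* gene map — columns gene, genotype.

Readers validate rather than coerce: rows violating the schema (missing or
non-positive values) are moved to a rejects table with a reason code, and a
missing required column raises :class:`SchemaError` naming the column.
Genotype and batch labels are matched case-insensitively and stored
lower-case.

:func:`run_all` reproduces the whole analysis from a :class:`RunConfig`:
screens, reference bands, the sample-size confound check, subsampling and
leave-x-out resilience reports with p-value density summaries, plus a
machine-readable manifest.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import InvalidConfigError, SchemaError
from . import resilience as _resilience
from . import stats as _stats
from .resilience import LeaveXOutSpec, SubsamplingSpec

__all__ = [
    "MEASUREMENT_COLUMNS",
    "RunConfig",
    "read_measurement_table",
    "write_measurement_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "run_all",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("genotype", "batch", "sepal_id", "length", "width", "area", "aspect_ratio")
_VALUE_COLUMNS = ("length", "width", "area", "aspect_ratio")


def _read_csv_any_delim(path: str | Path) -> pd.DataFrame:
    """CSV read with delimiter sniffing among comma/semicolon/tab."""
    return pd.read_csv(path, sep=None, engine="python")


def read_measurement_table(
    path: str | Path,
    rejects_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a per-sepal measurement table.

    Returns (table, rejects).  Rejected rows (missing or non-positive
    measurement values) carry a ``reason`` column; if ``rejects_path`` is
    given they are also written there.
    """
    raw = _read_csv_any_delim(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"measurement table missing required column(s): {missing}")
    raw = raw[list(MEASUREMENT_COLUMNS)].copy()
    for c in ("genotype", "batch", "sepal_id"):
        raw[c] = raw[c].astype(str).str.strip().str.lower()

    values = raw[list(_VALUE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad_missing = values.isna().any(axis=1)
    bad_nonpos = (values <= 0).any(axis=1) & ~bad_missing
    reasons = np.where(bad_missing, "missing or non-numeric value",
                       np.where(bad_nonpos, "non-positive value", ""))
    bad = bad_missing | bad_nonpos

    rejects = raw[bad].copy()
    rejects["reason"] = reasons[bad.to_numpy()]
    table = raw[~bad].copy()
    table[list(_VALUE_COLUMNS)] = values[~bad]
    table = table.reset_index(drop=True)
    rejects = rejects.reset_index(drop=True)
    if rejects_path is not None and len(rejects):
        rejects.to_csv(rejects_path, index=False)
    if len(rejects):
        log.warning("rejected %d measurement row(s)", len(rejects))
    return table, rejects


def write_measurement_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)


def read_expression_matrix(
    path: str | Path,
    gene_map_path: str | Path | None = None,
) -> tuple[_stats.ExpressionMatrix, list[dict]]:
    """Read an expression matrix CSV plus optional gene map.

    Returns (matrix, rejects); rejects lists mapped genes absent from the
    matrix.  Duplicate gene ids or negative cells raise SchemaError.
    """
    raw = _read_csv_any_delim(path)
    if raw.shape[1] < 3:
        raise SchemaError("expression matrix needs a gene id column and >= 2 sample columns")
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    raw.index = raw.index.astype(str)
    raw.index.name = "gene"
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate gene id(s): {dupes}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise SchemaError("non-numeric cell(s) in expression matrix")
    if (values.values < 0).any():
        raise SchemaError("negative expression value(s)")

    rejects: list[dict] = []
    gene_map = pd.DataFrame(columns=["gene", "genotype"])
    if gene_map_path is not None:
        gm = _read_csv_any_delim(gene_map_path)
        if not {"gene", "genotype"}.issubset(gm.columns):
            raise SchemaError("gene map must have columns gene, genotype")
        gm = gm[["gene", "genotype"]].copy()
        gm["gene"] = gm["gene"].astype(str).str.strip()
        gm["genotype"] = gm["genotype"].astype(str).str.strip().str.lower()
        present = gm["gene"].isin(values.index)
        for rec in gm[~present].itertuples(index=False):
            rejects.append({"gene": rec.gene, "genotype": rec.genotype,
                            "reason": "mapped gene absent from matrix"})
            log.warning("gene map entry %s (%s) not in matrix; rejected", rec.gene, rec.genotype)
        gene_map = gm[present].reset_index(drop=True)
    return _stats.ExpressionMatrix(values=values, gene_map=gene_map), rejects


def write_expression_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, index=True)


@dataclass
class RunConfig:
    """Inputs, specs and options of one end-to-end run."""

    measurements: str
    expression: str
    gene_map: str
    out_dir: str
    seed: int = 0
    alpha: float = 0.05
    subsampling: SubsamplingSpec | None = None
    leave_x_out: list[LeaveXOutSpec] = field(default_factory=list)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        sub = cfg.pop("subsampling", None)
        lxo = cfg.pop("leave_x_out", [])
        return cls(
            subsampling=SubsamplingSpec(**sub) if sub else None,
            leave_x_out=[LeaveXOutSpec(**spec) if isinstance(spec, dict) else spec
                         for spec in lxo],
            **cfg,
        )


def _corr_frame(results: list[_stats.CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"response": r.response, "covariate": r.covariate, "n": r.n, "r": r.r, "p": r.p}
        for r in results
    ])


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline and write every result under ``out_dir``.

    Outputs: screen_table.csv, screen_correlations.csv,
    reference_bands.csv, sample_size_confound.csv, rejects CSVs, one
    resilience JSON/CSV pair per experiment, pvalue density CSVs, and
    manifest.json.  Raises on missing inputs; determinism: identical
    config + seed means byte-identical CSVs.
    """
    for name in ("measurements", "expression", "gene_map"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    table, meas_rejects = read_measurement_table(config.measurements,
                                                 rejects_path=out / "measurement_rejects.csv")
    expr, expr_rejects = read_expression_matrix(config.expression, config.gene_map)

    screen_table, screen_rejects = _stats.build_screen_table(table, expr)
    screen_table.to_csv(out / "screen_table.csv", index=False)
    if screen_rejects:
        pd.DataFrame(screen_rejects).to_csv(out / "screen_rejects.csv", index=False)
    if expr_rejects:
        pd.DataFrame(expr_rejects).to_csv(out / "expression_rejects.csv", index=False)

    screens = _stats.run_screens(screen_table, alpha=config.alpha)
    _corr_frame(screens).to_csv(out / "screen_correlations.csv", index=False)

    bands = _stats.reference_band(table)
    pd.DataFrame([dataclasses.asdict(b) for b in bands]).to_csv(
        out / "reference_bands.csv", index=False)

    confound = _stats.sample_size_confound(screen_table)
    _corr_frame(confound).to_csv(out / "sample_size_confound.csv", index=False)

    manifest: dict = {
        "inputs": {"measurements": str(config.measurements),
                   "expression": str(config.expression),
                   "gene_map": str(config.gene_map)},
        "seed": config.seed,
        "alpha": config.alpha,
        "n_measurement_rejects": int(len(meas_rejects)),
        "outputs": ["screen_table.csv", "screen_correlations.csv",
                    "reference_bands.csv", "sample_size_confound.csv"],
    }

    if config.subsampling is not None:
        spec = dataclasses.replace(config.subsampling, seed=config.seed,
                                   alpha=config.alpha)
        report = _resilience.subsample_replicates(table, screen_table, spec)
        report.to_json(out / "subsampling_report.json")
        report.to_frame().to_csv(out / "subsampling_results.csv", index=False)
        manifest["outputs"] += ["subsampling_report.json", "subsampling_results.csv"]

    for spec in config.leave_x_out:
        spec = dataclasses.replace(spec, alpha=config.alpha)
        report = _resilience.leave_x_out(screen_table, spec)
        tag = f"leave{spec.x}out"
        if spec.fixed_exclusions:
            tag += "_minus_" + "_".join(spec.fixed_exclusions)
        tag += f"_{spec.response}"
        report.to_json(out / f"{tag}_report.json")
        report.to_frame().to_csv(out / f"{tag}_results.csv", index=False)
        full = _stats.pearson_test(
            screen_table.loc[screen_table["parameter"] == spec.response,
                             spec.covariate].to_numpy(),
            screen_table.loc[screen_table["parameter"] == spec.response, "cv2"].to_numpy())
        dens = _resilience.pvalue_distribution(report, reference_p=full.p)
        if not dens.degenerate:
            pd.DataFrame({"log10_p": dens.grid_log10_p, "density": dens.density}).to_csv(
                out / f"{tag}_pvalue_density.csv", index=False)
            manifest["outputs"].append(f"{tag}_pvalue_density.csv")
        manifest["outputs"] += [f"{tag}_report.json", f"{tag}_results.csv"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
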