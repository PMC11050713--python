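"""Readers and writers: expression TSV/CSV, GMT gene sets, survival tables,
score/call/biomarker outputs with JSON metadata sidecars.

All writers are deterministic (stable column order, full double precision
via Python's shortest-repr float formatting) so identical inputs and config
produce byte-identical files and thresholds reapply exactly after a round
trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DysregulationCalls, SurvivalTable
from .config import RunConfig
from .scoring import ActivationMatrix, ExpressionMatrix, GeneSetCollection
from .simulate import SimulationSpec

__all__ = [
    "read_expression",
    "read_gmt",
    "read_survival",
    "write_activation",
    "read_activation",
    "write_calls",
    "read_calls",
    "write_biomarkers",
    "write_cohort",
    "read_simulation_spec",
]

logger = logging.getLogger("riepath")


class ParseError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    labels_path: str | Path,
    transpose: bool = False,
    log2_transform: bool = False,
    missing: str = "error",
) -> ExpressionMatrix:
    """Load a genes x samples matrix plus a sample -> tumor/normal label table.

    The matrix file has a header row of sample ids and gene ids in the
    first column (``transpose=True`` for samples x genes files). Duplicate
    gene rows keep the first occurrence (logged). ``missing``: ``"error"``
    (default), ``"drop"`` genes with any missing value, or
    ``"impute_median"`` by gene row median. ``log2_transform`` applies
    log2(x + 1); inputs are otherwise assumed already log2-transformed.
    """
    path, labels_path = Path(path), Path(labels_path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"non-numeric cell in column {col!r}, gene {bad.index[0]!r}: "
                    f"{bad[col].iloc[0]!r}"
                )
        df = df.apply(pd.to_numeric)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("duplicate gene ids %s: keeping first occurrence", dup[:5])
        df = df[~df.index.duplicated(keep="first")]
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicate sample ids: {dup[:5]}")

    if df.isna().any().any():
        if missing == "drop":
            n_before = len(df)
            df = df.dropna(axis=0)
            logger.warning("dropped %d genes with missing values", n_before - len(df))
        elif missing == "impute_median":
            df = df.apply(lambda row: row.fillna(row.median()), axis=1)
        else:
            cell = np.argwhere(df.isna().to_numpy())[0]
            raise ParseError(
                f"missing value at gene {df.index[cell[0]]!r}, sample {df.columns[cell[1]]!r}"
            )
    if log2_transform:
        if (df.to_numpy() < 0).any():
            raise ParseError("negative values: cannot apply log2(x + 1)")
        df = np.log2(df + 1.0)

    lab = pd.read_csv(labels_path, sep=_sep_for(labels_path), index_col=0).iloc[:, 0]
    lab = lab.astype(str).str.strip().str.lower()
    unlabeled = [s for s in df.columns if s not in lab.index]
    if unlabeled:
        raise ParseError(f"samples missing from labels file: {unlabeled[:5]}")
    df.index = df.index.astype(str).str.strip()
    return ExpressionMatrix(values=df, labels=lab)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line name, description, then member gene ids."""
    path = Path(path)
    entries: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line needs name, description "
                    f"and at least one gene ({len(fields)} fields)"
                )
            name = fields[0].strip()
            if name in entries:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            entries[name] = [g for g in fields[2:] if g.strip()]
    if not entries:
        logger.warning("GMT file %s is empty", path)
    return GeneSetCollection(entries=entries, provenance=str(path))


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a TSV/CSV with columns sample_id (or first column), time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    return SurvivalTable(data=df[["time", "event"]].astype({"time": float, "event": int}))


# ---------------------------------------------------------------------------
# writers (deterministic; sidecar metadata JSON)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # pandas' default float formatting is repr-based (shortest round-trip),
    # so read-back is bit-exact
    df.to_csv(path, sep="\t")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_activation(
    activation: ActivationMatrix,
    outdir: str | Path,
    config: RunConfig | None = None,
    labels: pd.Series | None = None,
) -> None:
    """Write scores.tsv plus metadata.json (config echo, gene bookkeeping)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(activation.scores, outdir / "scores.tsv")
    meta = {
        "config": (config or RunConfig()).to_dict(),
        "pathways": activation.meta,
        "skipped": activation.skipped,
        "labels": dict(labels.astype(str)) if labels is not None else None,
    }
    _write_json(meta, outdir / "metadata.json")


def read_activation(outdir: str | Path) -> tuple[ActivationMatrix, RunConfig, pd.Series | None]:
    outdir = Path(outdir)
    scores = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col=0, float_precision="round_trip")
    meta = json.loads((outdir / "metadata.json").read_text())
    labels = pd.Series(meta["labels"]) if meta.get("labels") else None
    act = ActivationMatrix(
        scores=scores, meta=meta.get("pathways", {}), skipped=meta.get("skipped", {})
    )
    return act, RunConfig.from_dict(meta["config"]), labels


def write_calls(calls: DysregulationCalls, outdir: str | Path) -> None:
    """Write calls.tsv and thresholds.tsv; reapplying thresholds to stored
    scores reproduces the calls exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(calls.calls, outdir / "calls.tsv")
    _write_tsv(calls.thresholds, outdir / "thresholds.tsv")


def read_calls(outdir: str | Path) -> DysregulationCalls:
    outdir = Path(outdir)
    return DysregulationCalls(
        calls=pd.read_csv(outdir / "calls.tsv", sep="\t", index_col=0),
        thresholds=pd.read_csv(outdir / "thresholds.tsv", sep="\t", index_col=0, float_precision="round_trip"),
    )


def write_biomarkers(result: pd.DataFrame, path: str | Path) -> None:
    """Biomarker table: pathway, statistic, p, p_adj, group sizes, flag."""
    _write_tsv(result, Path(path))


def write_cohort(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    survival: SurvivalTable,
    truth: dict,
    outdir: str | Path,
) -> None:
    """Write a simulated cohort: expression.tsv, labels.tsv, pathways.gmt,
    survival.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(expr.values, outdir / "expression.tsv")
    labels = expr.labels.rename("label").to_frame()
    labels.index.name = "sample_id"
    _write_tsv(labels, outdir / "labels.tsv")
    with (outdir / "pathways.gmt").open("w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, sets.provenance or "synthetic"] + genes) + "\n")
    surv = survival.data.copy()
    surv.index.name = "sample_id"
    _write_tsv(surv, outdir / "survival.tsv")
    truth_out = dict(truth)
    if isinstance(truth_out.get("spec"), SimulationSpec):
        truth_out["spec"] = asdict(truth_out["spec"])
    _write_json(truth_out, outdir / "truth.json")


def read_simulation_spec(path: str | Path) -> SimulationSpec:
    """Load a SimulationSpec from a YAML mapping (field name -> value)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError("simulation spec must be a YAML mapping")
    if "genes_per_pathway" in raw:
        raw["genes_per_pathway"] = tuple(raw["genes_per_pathway"])
    return SimulationSpec(**raw)
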