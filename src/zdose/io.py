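"""Readers/writers for the standard genomics text formats the pipeline touches.

Supported formats: BED6 / minimal GFF3 (genes), ENCODE narrowPeak (ATAC
peaks), Bismark coverage (per-CpG methylation), bedGraph (read depth),
plain TSV (expression matrix, sample sheet) and YAML (run configuration).

Every reader converts to the package's internal convention (0-based,
half-open) and validates the data-model invariants; records on chromosomes
absent from the layout are dropped with a logged count (repeat-rich
chromosomes are routinely excluded from such analyses wholesale).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from zdose.datamodel import (
    ExpressionMatrix,
    GenomeLayout,
    ValidationError,
    validate_genes,
    validate_samples,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file; message carries file and line number."""


def _iter_fields(path, min_fields: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, got {len(fields)}"
                )
            yield lineno, fields


def _drop_unknown_chroms(df: pd.DataFrame, layout: GenomeLayout, what: str,
                         chrom_col: str = "chrom") -> pd.DataFrame:
    known = df[chrom_col].isin(layout.names)
    n_drop = int((~known).sum())
    if n_drop:
        logger.warning("%s: dropped %d records on chromosomes absent from layout",
                       what, n_drop)
    return df.loc[known].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def read_genes_bed(path, layout: GenomeLayout) -> pd.DataFrame:
    """BED6 gene models (0-based half-open, native convention)."""
    rows = []
    for lineno, f in _iter_fields(path, 6):
        try:
            rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = _drop_unknown_chroms(genes, layout, "genes")
    return validate_genes(genes, layout)


def read_genes_gff(path, layout: GenomeLayout) -> pd.DataFrame:
    """Minimal GFF3, gene lines only; 1-based inclusive -> half-open."""
    rows = []
    for lineno, f in _iter_fields(path, 9):
        if f[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: gene line without ID attribute")
        try:
            rows.append((gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = _drop_unknown_chroms(genes, layout, "genes")
    return validate_genes(genes, layout)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# ATAC peaks (ENCODE narrowPeak)
# ---------------------------------------------------------------------------

def read_narrowpeak(path, layout: GenomeLayout, q_scale: str = "neglog10") -> pd.DataFrame:
    """ENCODE narrowPeak. ``height`` = signalValue (fold enrichment),
    ``q`` = qValue column read as -log10 (default) or linear per config."""
    if q_scale not in ("neglog10", "linear"):
        raise ValidationError(f"unknown q_scale {q_scale!r}")
    rows = []
    for lineno, f in _iter_fields(path, 10):
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            height = float(f[6])
            qraw = float(f[8])
            summit = int(f[9])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        q = 10.0 ** (-qraw) if q_scale == "neglog10" else qraw
        rows.append((chrom, start, end, height, q, summit))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "height", "q", "summit"])
    peaks = _drop_unknown_chroms(peaks, layout, "peaks")
    if (peaks["end"] <= peaks["start"]).any():
        raise ValidationError(f"{path}: peak with end <= start")
    if (peaks["height"] <= 0).any():
        raise ValidationError(f"{path}: peak height must be > 0")
    if ((peaks["q"] < 0) | (peaks["q"] > 1)).any():
        raise ValidationError(f"{path}: q values must lie in [0, 1]")
    lengths = layout.lengths
    ends = peaks["chrom"].map(lengths)
    if (peaks["end"] > ends).any():
        raise ValidationError(f"{path}: peak beyond chromosome bounds")
    return peaks


def write_narrowpeak(peaks: pd.DataFrame, path, q_scale: str = "neglog10") -> None:
    q = peaks["q"].to_numpy(dtype=float)
    if q_scale == "neglog10":
        qout = -np.log10(np.clip(q, 1e-300, None))
    else:
        qout = q
    summit = peaks["summit"] if "summit" in peaks else (
        (peaks["end"] - peaks["start"]) // 2
    )
    out = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"],
        "end": peaks["end"],
        "name": [f"peak_{i}" for i in range(len(peaks))],
        "score": 0,
        "strand": ".",
        "signalValue": peaks["height"],
        "pValue": -1,
        "qValue": qout,
        "summit": summit,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# methylation (Bismark coverage)
# ---------------------------------------------------------------------------

def read_bismark_cov(path, layout: GenomeLayout) -> pd.DataFrame:
    """Bismark coverage: chrom, start(1-based), end, %meth, n_meth, n_unmeth.

    Converted to 0-based ``pos``; ``n_total = n_meth + n_unmeth``.
    """
    rows = []
    for lineno, f in _iter_fields(path, 6):
        try:
            chrom, start = f[0], int(f[1])
            n_meth, n_unmeth = int(f[4]), int(f[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if n_meth < 0 or n_unmeth < 0:
            raise ValidationError(f"{path}:{lineno}: negative read counts")
        rows.append((chrom, start - 1, n_meth, n_meth + n_unmeth))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
    calls = _drop_unknown_chroms(calls, layout, "methylation calls")
    if (calls["n_meth"] > calls["n_total"]).any():
        raise ValidationError(f"{path}: n_meth > n_total")
    if calls.duplicated(["chrom", "pos"]).any():
        raise ValidationError(f"{path}: duplicate CpG positions")
    return calls


def write_bismark_cov(calls: pd.DataFrame, path) -> None:
    n_unmeth = calls["n_total"] - calls["n_meth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(
            calls["n_total"] > 0, 100.0 * calls["n_meth"] / calls["n_total"], 0.0
        )
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["pos"] + 1,
        "end": calls["pos"] + 1,
        "pct": pct,
        "n_meth": calls["n_meth"],
        "n_unmeth": n_unmeth,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# coverage (bedGraph)
# ---------------------------------------------------------------------------

def read_bedgraph(path, layout: GenomeLayout) -> pd.DataFrame:
    rows = []
    for lineno, f in _iter_fields(path, 4):
        try:
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    cov = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    cov = _drop_unknown_chroms(cov, layout, "coverage")
    if (cov["depth"] < 0).any():
        raise ValidationError(f"{path}: negative depth")
    return cov


def write_bedgraph(cov: pd.DataFrame, path) -> None:
    cov[["chrom", "start", "end", "depth"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# expression matrix / sample sheet / config
# ---------------------------------------------------------------------------

def read_expression_tsv(path, unit: str, gene_lengths: pd.Series | None = None
                        ) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    return ExpressionMatrix(values=values, unit=unit, gene_lengths=gene_lengths)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_samples_tsv(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    return validate_samples(samples)


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    return cfg


def read_layout(path) -> GenomeLayout:
    cfg = read_config(path)
    return GenomeLayout(
        chromosomes=tuple((c["name"], int(c["length"])) for c in cfg["chromosomes"]),
        sex_chromosome=cfg["sex_chromosome"],
        par=(int(cfg["par"][0]), int(cfg["par"][1])),
    )


def write_layout(layout: GenomeLayout, path) -> None:
    cfg = {
        "chromosomes": [{"name": n, "length": ln} for n, ln in layout.chromosomes],
        "sex_chromosome": layout.sex_chromosome,
        "par": [int(layout.par[0]), int(layout.par[1])],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dataset assembly and reporting
# ---------------------------------------------------------------------------

def load_dataset(paths: dict, layout: GenomeLayout, expression_unit: str = "counts",
                 q_scale: str = "neglog10") -> dict:
    """Load every role present in ``paths`` into the internal data model.

    Recognised roles: ``genes`` (BED6 or .gff/.gff3), ``expression`` (TSV),
    ``samples`` (TSV), ``peaks`` (mapping sample_id -> narrowPeak path),
    ``methylation`` (mapping sample_id -> Bismark coverage path),
    ``coverage`` (mapping sex -> bedGraph path).
    """
    for role, p in paths.items():
        targets = p.values() if isinstance(p, dict) else [p]
        for t in targets:
            if not os.path.exists(t):
                raise FileNotFoundError(f"{role}: {t}")
    data: dict = {"layout": layout}
    if "genes" in paths:
        p = str(paths["genes"])
        reader = read_genes_gff if p.endswith((".gff", ".gff3")) else read_genes_bed
        data["genes"] = reader(p, layout)
    if "samples" in paths:
        data["samples"] = read_samples_tsv(paths["samples"])
    if "expression" in paths:
        lengths = None
        if "genes" in data:
            g = data["genes"]
            lengths = pd.Series(
                (g["end"] - g["start"]).to_numpy(), index=g["gene_id"]
            )
        data["expression"] = read_expression_tsv(
            paths["expression"], unit=expression_unit, gene_lengths=lengths
        )
    if "peaks" in paths:
        data["peaks"] = {
            s: read_narrowpeak(p, layout, q_scale=q_scale)
            for s, p in paths["peaks"].items()
        }
    if "methylation" in paths:
        data["methylation"] = {
            s: read_bismark_cov(p, layout) for s, p in paths["methylation"].items()
        }
    if "coverage" in paths:
        data["coverage"] = {
            sex: read_bedgraph(p, layout) for sex, p in paths["coverage"].items()
        }
    return data


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(results: dict, out_dir, seed: int | None = None,
                 thresholds: dict | None = None) -> dict:
    """Write one TSV per result class plus a JSON manifest.

    ``results`` maps a result name to a DataFrame, a list of
    :class:`RatioEstimate`, or a JSON-serialisable mapping. Re-running with
    the same inputs and seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "seed": seed, "thresholds": thresholds or {}}
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
        elif isinstance(obj, (list, tuple)) and all(
            hasattr(x, "as_dict") for x in obj
        ):
            path = out_dir / f"{name}.tsv"
            pd.DataFrame([x.as_dict() for x in obj]).to_csv(
                path, sep="\t", index=False, float_format="%.10g"
            )
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        manifest["files"][name] = {
            "path": str(path.name),
            "sha256": _file_sha256(path),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
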