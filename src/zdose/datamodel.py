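"""Shared coordinate conventions and core data containers.

All coordinates are 0-based, half-open everywhere inside the package.
Formats with 1-based inclusive conventions (GFF, Bismark coverage) are
converted on read (see :mod:`zdose.io`).

Tabular layers are plain :class:`pandas.DataFrame` objects with documented
column contracts:

* genes:    ``gene_id, chrom, start, end, strand``
* samples:  ``sample_id, sex, tissue`` (+ optional ``library_size``)
* peaks:    per sample ``chrom, start, end, height, q`` (+ optional ``summit``)
* methylation calls: per sample ``chrom, pos, n_meth, n_total``
* coverage: per sex ``chrom, start, end, depth``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths, Z identity and the PAR interval.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    sex_chromosome
        Name of the Z chromosome (must appear in ``chromosomes``).
    par
        Half-open ``[start, end)`` interval of the pseudo-autosomal region
        on the sex chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sex_chromosome: str
    par: tuple[int, int]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has length {length} <= 0")
        if self.sex_chromosome not in names:
            raise ValidationError(
                f"sex chromosome {self.sex_chromosome!r} not in layout"
            )
        s, e = self.par
        if not (0 <= s < e <= self.length(self.sex_chromosome)):
            raise ValidationError(f"PAR {self.par} not contained in sex chromosome")

    # -- convenience accessors -------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def autosomes(self) -> list[str]:
        return [c[0] for c in self.chromosomes if c[0] != self.sex_chromosome]

    def length(self, name: str) -> int:
        for n, ln in self.chromosomes:
            if n == name:
                return ln
        raise KeyError(name)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def is_nonpar_z(self, chrom, pos) -> np.ndarray:
        """Vectorized: True where (chrom, pos) lies on the hemizygous Z."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        on_z = chrom == self.sex_chromosome
        in_par = (pos >= self.par[0]) & (pos < self.par[1])
        return on_z & ~in_par


# Interval of female-heterozygous genotyping SNPs delimiting the crow PAR
# (first and last heterozygous site, bp on the Z).
CROW_HET_SNP_INTERVAL: tuple[int, int] = (27_730, 687_785)

#: End of the crow PAR (bp), taken from the female-heterozygous SNP interval.
CROW_PAR_END: int = CROW_HET_SNP_INTERVAL[1]


def crow_like_layout(
    autosome_lengths: tuple[int, ...] = (150_000_000, 120_000_000),
    z_length: int = 75_000_000,
    par_end: int = CROW_PAR_END,
) -> GenomeLayout:
    """A crow-like genome layout: macro-autosomes plus a 75-Mb Z whose
    first ~688 kb form the still-recombining PAR."""
    chroms = tuple(
        (f"chr{i + 1}", ln) for i, ln in enumerate(autosome_lengths)
    ) + (("chrZ", z_length),)
    return GenomeLayout(chromosomes=chroms, sex_chromosome="chrZ", par=(0, par_end))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit unit.

    ``values`` is indexed by gene_id with sample_id columns. ``unit`` is
    never inferred from the numbers; FPKM vs counts is an explicit flag.
    """

    values: pd.DataFrame
    unit: str  # {"counts", "FPKM"}
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any():
                raise ValidationError("gene_lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise ValidationError("gene lengths must be > 0")


@dataclass(frozen=True)
class RatioEstimate:
    """A labelled ratio (e.g. ``Zf:ZZm``) with a percentile-bootstrap CI."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    n_features: int
    n_boot: int
    scale: str = "linear"  # {"linear", "log2"}

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_features": self.n_features,
            "n_boot": self.n_boot,
            "scale": self.scale,
        }


def validate_genes(genes: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Check the gene-table contract; returns the validated frame."""
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValidationError(f"gene table missing columns: {sorted(missing)}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    if (genes["end"] <= genes["start"]).any():
        bad = genes.loc[genes["end"] <= genes["start"]].iloc[0]
        raise ValidationError(
            f"gene {bad['gene_id']}: end {bad['end']} <= start {bad['start']}"
        )
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValidationError("gene strand must be '+' or '-'")
    if layout is not None:
        lengths = layout.lengths
        for _, row in genes.iterrows():
            if row["chrom"] not in lengths:
                raise ValidationError(f"gene {row['gene_id']} on unknown chromosome")
            if row["end"] > lengths[row["chrom"]]:
                raise ValidationError(
                    f"gene {row['gene_id']} extends beyond chromosome end"
                )
    return genes


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "sex", "tissue"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("sample ids must be unique")
    bad = ~samples["sex"].isin(["F", "M"])
    if bad.any():
        raise ValidationError(
            f"unknown sex label {samples.loc[bad, 'sex'].iloc[0]!r} (expected F/M)"
        )
    return samples


def tss(genes: pd.DataFrame) -> pd.Series:
    """Transcription start site: ``start`` on '+', ``end - 1`` on '-'."""
    plus = genes["strand"] == "+"
    return pd.Series(
        np.where(plus, genes["start"], genes["end"] - 1),
        index=genes.index,
        name="tss",
    )


def tts(genes: pd.DataFrame) -> pd.Series:
    """Transcription termination site: ``end - 1`` on '+', ``start`` on '-'."""
    plus = genes["strand"] == "+"
    return pd.Series(
        np.where(plus, genes["end"] - 1, genes["start"]),
        index=genes.index,
        name="tts",
    )
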