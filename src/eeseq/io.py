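"""Expression containers and file IO.

Matrices are genes x samples TSVs (first column ``gene_id``, header row of
sample ids). Sample metadata is a TSV with columns ``sample_id``, ``litter``,
``treatment`` (EE | B), ``timepoint`` (1h | 4h) and ``sex`` (M | F).
Gene signatures use the GMT format (set name, description, member genes,
tab-separated); the description field carries the expected direction of the
set in enriched animals (``up`` or ``down``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UNITS = ("counts", "TPM", "CPM", "log2")

TREATMENTS = ("EE", "B")
TIMEPOINTS = ("1h", "4h")
SEXES = ("M", "F")


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dup = labels[labels.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with a unit tag.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. Units other than ``log2`` must be non-negative; all values must
    be finite.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.unit != "log2" and (arr < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = set(samples) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values[list(samples)], self.unit)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Raises ``ValueError`` naming the offending gene/line for duplicate ids,
    non-numeric cells or ragged rows; row and column order are preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False, on_bad_lines="error")
    except pd.errors.ParserError as exc:  # ragged rows; pandas names the line
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    _check_unique(df.index, "gene")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (df != "")
    if bad.to_numpy().any():
        g = df.index[bad.any(axis=1)][0]
        c = df.columns[bad.loc[g]][0]
        raise ValueError(f"{path}: non-numeric cell at gene {g!r}, sample {c!r}: "
                         f"{df.loc[g, c]!r}")
    if numeric.isna().to_numpy().any():
        g = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: empty cell in row for gene {g!r}")
    numeric = numeric.astype(float)
    numeric.index = numeric.index.astype(str).rename(None)
    numeric.columns = numeric.columns.astype(str).rename(None)
    return ExpressionMatrix(numeric, unit)


@dataclass
class SampleTable:
    """Per-sample design factors, indexed by sample id."""

    df: pd.DataFrame

    REQUIRED = ("litter", "treatment", "timepoint", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing column(s): {missing}")
        _check_unique(self.df.index, "sample")
        for col, allowed in (("treatment", TREATMENTS), ("timepoint", TIMEPOINTS),
                             ("sex", SEXES)):
            bad = set(self.df[col]) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} value(s) {sorted(bad)}; "
                                 f"allowed: {allowed}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def select(self, treatment: str | None = None,
               timepoint: str | None = None) -> list[str]:
        """Sample ids matching the given factor levels (None = any)."""
        mask = pd.Series(True, index=self.df.index)
        if treatment is not None:
            mask &= self.df["treatment"] == treatment
        if timepoint is not None:
            mask &= self.df["timepoint"] == timepoint
        return list(self.df.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return SampleTable(df)


@dataclass(frozen=True)
class GeneSignature:
    """A named, directed gene set (direction = expected sign in EE vs B)."""

    name: str
    genes: frozenset[str]
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got "
                             f"{self.direction!r}")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def intersect(self, gene_ids: Iterable[str]) -> list[str]:
        """Members present in ``gene_ids`` (order of ``gene_ids`` kept).

        The effective size after intersection is what enters the
        randomisation test; an empty intersection is an error, never silent.
        """
        eff = [g for g in gene_ids if g in self.genes]
        if not eff:
            raise ValueError(f"signature {self.name!r} has no genes in common "
                             "with the analysed matrix")
        if len(eff) < len(self.genes):
            log.info("signature %s: %d of %d genes present in matrix",
                     self.name, len(eff), len(self.genes))
        return eff


def read_signatures(path: str | Path,
                    directions: Mapping[str, str] | None = None
                    ) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    The direction is taken from ``directions[name]`` when provided, else from
    the GMT description field if it is ``up`` or ``down``.
    """
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name, desc = parts[0], parts[1]
            genes = [g for g in parts[2:] if g]
            if directions and name in directions:
                direction = directions[name]
            elif desc in ("up", "down"):
                direction = desc
            else:
                raise ValueError(f"{path}:{lineno}: no direction for signature "
                                 f"{name!r} (description {desc!r} is not "
                                 "'up'/'down' and no mapping was given)")
            sigs.append(GeneSignature(name, frozenset(genes), direction))
    if not sigs:
        raise ValueError(f"{path}: no signatures found")
    return sigs


def write_signatures(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.direction, *sorted(sig.genes)]) + "\n")


def aggregate_transcripts_to_genes(tx: ExpressionMatrix,
                                   tx2gene: Mapping[str, str] | pd.Series
                                   ) -> ExpressionMatrix:
    """Sum transcript-level rows to gene level.

    Applies equally to counts and TPM (both are additive over transcripts of
    a gene). Transcripts absent from the map are dropped, with the count
    logged; gene order follows first appearance in the transcript order.
    """
    mapping = pd.Series(dict(tx2gene)) if not isinstance(tx2gene, pd.Series) else tx2gene
    present = tx.values.index.isin(mapping.index)
    n_unmapped = int((~present).sum())
    if n_unmapped:
        log.warning("dropping %d unmapped transcript(s)", n_unmapped)
    kept = tx.values.loc[present]
    genes = mapping.reindex(kept.index)
    out = kept.groupby(genes, sort=False).sum()
    out.index.name = None
    return ExpressionMatrix(out, tx.unit)


def filter_low_expression(tpm: ExpressionMatrix, samples: SampleTable,
                          threshold: float = 2.0,
                          summary: str = "median") -> list[str]:
    """Retain genes adequately expressed in *both* treatment groups.

    A gene is kept iff its group-summary TPM (median by default, mean
    configurable) is >= ``threshold`` in the EE group AND in the B group,
    pooling both timepoints; genes below the threshold in one or both groups
    are treated as noise and removed. Returns retained gene ids in matrix
    order.
    """
    if tpm.unit != "TPM":
        raise ValueError(f"filter operates on TPM, got unit {tpm.unit!r}")
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    keep = pd.Series(True, index=tpm.values.index)
    for group in TREATMENTS:
        ids = samples.select(treatment=group)
        ids = [s for s in ids if s in tpm.values.columns]
        if not ids:
            raise ValueError(f"no samples in treatment group {group!r}")
        sub = tpm.values[ids]
        stat = sub.median(axis=1) if summary == "median" else sub.mean(axis=1)
        keep &= stat >= threshold
    return list(tpm.values.index[keep])
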