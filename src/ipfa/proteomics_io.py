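"""Matched EV/cell abundance tables and log10 EV:cell ratios.

Label-free mass-spectrometry "area" values for the same proteins measured
in extracellular vesicles (EV) and their producer cells (CELL) are loaded
into an :class:`AbundanceMatrix`.  Missing measurements are recorded as
zero area.  Before any aggregation a pseudocount (default 1) is added to
every raw measurement, which removes zeros while preserving pairwise
differences between samples; replicates are then aggregated within each
compartment and the per-protein ratio

    r = log10( (EV area + c, aggregated) / (CELL area + c, aggregated) )

is computed per dataset (producer cell line).  These ratios are the
background and group distributions for enrichment testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "SampleMeta",
    "AbundanceMatrix",
    "RatioTable",
    "load_abundance",
    "add_pseudocount",
    "compute_log_ratios",
]

COMPARTMENTS = ("EV", "CELL")


@dataclass(frozen=True, order=True)
class SampleMeta:
    """One mass-spectrometry run: which cell line, compartment, replicate."""

    sample_id: str
    dataset: str
    compartment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"compartment must be one of {COMPARTMENTS}, "
                f"got {self.compartment!r} for sample {self.sample_id!r}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"replicate must be >= 1, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class AbundanceMatrix:
    """Protein x sample area matrix with sample metadata.

    ``areas`` is indexed by protein accession with one column per
    sample_id, in input order.  ``pseudocount`` records the constant
    already added to every cell (0.0 means raw data); it exists so the
    pseudocount rule cannot be applied twice by accident.
    """

    areas: pd.DataFrame
    samples: tuple[SampleMeta, ...]
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        by_id = {s.sample_id: s for s in self.samples}
        if len(by_id) != len(self.samples):
            raise ValidationError("duplicate sample_id in metadata")
        keys = {(s.dataset, s.compartment, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValidationError(
                "(dataset, compartment, replicate) must be unique across samples"
            )
        missing = [c for c in self.areas.columns if c not in by_id]
        if missing:
            raise SchemaError(f"columns without sample metadata: {missing}")
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein accessions: {dups}")
        vals = self.areas.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("areas must be finite")
        if (vals < 0).any():
            raise ValidationError("areas must be non-negative")
        for ds in {s.dataset for s in self.samples}:
            comps = {s.compartment for s in self.samples if s.dataset == ds}
            if set(COMPARTMENTS) - comps:
                raise ValidationError(
                    f"dataset {ds!r} lacks compartment(s) {set(COMPARTMENTS) - comps}"
                )

    @property
    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.dataset, None)
        return list(seen)

    @property
    def proteins(self) -> list[str]:
        return list(self.areas.index)

    def columns_for(self, dataset: str, compartment: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.dataset == dataset and s.compartment == compartment
        ]

    def write(self, table_path: str | Path, meta_path: str | Path) -> None:
        out = self.areas.copy()
        out.index.name = "protein_id"
        out.to_csv(table_path, sep="\t")
        meta = pd.DataFrame(
            [
                (s.sample_id, s.dataset, s.compartment, s.replicate)
                for s in self.samples
            ],
            columns=["sample_id", "dataset", "compartment", "replicate"],
        )
        meta.to_csv(meta_path, sep="\t", index=False)


def load_abundance(table: str | Path, meta: str | Path) -> AbundanceMatrix:
    """Load an abundance TSV/CSV and its sample-metadata TSV.

    The table's first column must be ``protein_id``; blanks and NA cells
    are coerced to 0 area.  Every sample column must have a metadata row;
    duplicated accessions and negative areas are rejected.
    """
    table = Path(table)
    sep = "," if table.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(table, sep=sep, dtype={0: str})
    if df.columns[0] != "protein_id":
        raise SchemaError(
            f"first column of {table} must be 'protein_id', got {df.columns[0]!r}"
        )
    df = df.set_index("protein_id")
    df = df.apply(pd.to_numeric, errors="raise").fillna(0.0)

    meta_df = pd.read_csv(meta, sep="\t", dtype={"sample_id": str, "dataset": str})
    required = {"sample_id", "dataset", "compartment", "replicate"}
    if not required.issubset(meta_df.columns):
        raise SchemaError(
            f"metadata {meta} missing columns {sorted(required - set(meta_df.columns))}"
        )
    by_id = {
        row.sample_id: SampleMeta(
            sample_id=row.sample_id,
            dataset=row.dataset,
            compartment=row.compartment,
            replicate=int(row.replicate),
        )
        for row in meta_df.itertuples()
    }
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise SchemaError(f"sample columns without metadata: {missing}")
    samples = tuple(by_id[c] for c in df.columns)
    return AbundanceMatrix(areas=df.astype(float), samples=samples)


def add_pseudocount(matrix: AbundanceMatrix, c: float = 1.0) -> AbundanceMatrix:
    """Add ``c`` to every raw area measurement.

    Applied once, to raw per-replicate measurements, before any
    aggregation: zeros disappear while pairwise distances between samples
    are maintained exactly.  Re-application is refused because the shift
    is not idempotent.
    """
    if c <= 0:
        raise ConfigurationError(f"pseudocount must be > 0, got {c}")
    if matrix.pseudocount != 0.0:
        raise ConfigurationError(
            f"pseudocount {matrix.pseudocount} already applied; "
            "the rule must run exactly once"
        )
    return AbundanceMatrix(
        areas=matrix.areas + c, samples=matrix.samples, pseudocount=c
    )


@dataclass
class RatioTable:
    """One log10 EV:cell ratio per protein per dataset.

    ``ratios`` maps dataset name -> Series indexed by protein accession.
    All values are finite (guaranteed by the pseudocount).
    """

    ratios: dict[str, pd.Series]
    pseudocount: float
    aggregation: str
    log_base: int = 10

    @property
    def datasets(self) -> list[str]:
        return list(self.ratios)

    def __getitem__(self, dataset: str) -> pd.Series:
        return self.ratios[dataset]

    def proteins(self, dataset: str) -> set[str]:
        """Detected-protein set of a dataset (used by the size filter)."""
        return set(self.ratios[dataset].index)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {
                    "dataset": ds,
                    "protein_id": s.index,
                    "log10_ratio": s.to_numpy(),
                }
            )
            for ds, s in self.ratios.items()
        ]
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, pseudocount: float = 1.0, aggregation: str = "mean"
    ) -> "RatioTable":
        df = pd.read_csv(path, sep="\t", dtype={"dataset": str, "protein_id": str})
        ratios = {
            str(ds): sub.set_index("protein_id")["log10_ratio"].astype(float)
            for ds, sub in df.groupby("dataset", sort=False)
        }
        return cls(ratios=ratios, pseudocount=pseudocount, aggregation=aggregation)


def compute_log_ratios(
    matrix: AbundanceMatrix,
    aggregation: str = "mean",
    drop_undetected: bool = False,
) -> RatioTable:
    """Aggregate replicates per compartment and take log10(EV/CELL).

    Requires the pseudocount to be applied already (all values positive,
    so every ratio is finite).  ``drop_undetected`` removes proteins with
    no signal in either compartment of a dataset (their ratio would be
    exactly 0 and they otherwise sit in the background distribution).
    """
    if aggregation not in ("mean", "median"):
        raise ConfigurationError(f"aggregation must be mean or median, got {aggregation!r}")
    if matrix.pseudocount <= 0:
        raise ValidationError(
            "compute_log_ratios requires pseudocounted areas; call add_pseudocount first"
        )
    agg = np.mean if aggregation == "mean" else np.median
    out: dict[str, pd.Series] = {}
    for ds in matrix.datasets:
        ev_cols = matrix.columns_for(ds, "EV")
        cell_cols = matrix.columns_for(ds, "CELL")
        ev = agg(matrix.areas[ev_cols].to_numpy(dtype=float), axis=1)
        cell = agg(matrix.areas[cell_cols].to_numpy(dtype=float), axis=1)
        r = pd.Series(
            np.log10(ev / cell), index=matrix.areas.index, name="log10_ratio"
        )
        if drop_undetected:
            cols = ev_cols + cell_cols
            raw_all_zero = (
                matrix.areas[cols].to_numpy(dtype=float) == matrix.pseudocount
            ).all(axis=1)
            r = r[~raw_all_zero]
        out[ds] = r
    return RatioTable(
        ratios=out, pseudocount=matrix.pseudocount, aggregation=aggregation
    )
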