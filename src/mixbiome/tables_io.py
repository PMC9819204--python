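"""Reading, writing, and preprocessing of sample × taxon abundance tables.

The working object is :class:`AbundanceTable`: a nonnegative samples × taxa
matrix with an attached taxonomy map (taxon → phylum/family/genus) and a
per-sample metadata table.  Preprocessing follows the usual amplicon
pipeline order: prevalence-filter raw counts first, then convert to
relative abundances, so each row sums to 1 *over the retained taxa*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "read_taxonomy",
    "read_metadata",
    "write_abundance_table",
    "prevalence_filter",
    "to_relative_abundance",
]

TAXONOMY_RANKS = ("phylum", "family", "genus")

_REL_ROWSUM_TOL = 1e-6


@dataclass
class AbundanceTable:
    """A samples × taxa abundance matrix with taxonomy and sample metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per taxon.  Values
        must be nonnegative with no missing cells.
    mode:
        ``"counts"`` for raw (or arbitrary-scale) abundances, ``"relative"``
        once each row has been closed to sum 1.
    taxonomy:
        DataFrame indexed by taxon id with columns ``phylum``, ``family``,
        ``genus`` (optionally ``species``).  Missing ranks are stored as
        ``"unclassified"``.  If omitted, a fully unclassified taxonomy is
        generated so every taxon always has an entry.
    metadata:
        DataFrame indexed by sample id holding covariates and (optionally)
        an outcome column.  Defaults to an empty frame over the samples.
    """

    data: pd.DataFrame
    mode: str = "counts"
    taxonomy: pd.DataFrame = None
    metadata: pd.DataFrame = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.data = self.data.astype(float)
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                "unclassified", index=self.data.columns, columns=list(TAXONOMY_RANKS)
            )
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.data.index)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def validate(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("abundance table contains missing cells")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        missing_tax = self.data.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"taxa missing from taxonomy: {list(missing_tax[:5])}")
        if self.mode == "relative":
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_ROWSUM_TOL
            if bad.any():
                raise ValueError(
                    f"relative-mode rows must sum to 1; offending samples: "
                    f"{list(self.data.index[bad][:5])}"
                )
        self._validated = True

    def with_data(self, data: pd.DataFrame, mode: str | None = None) -> "AbundanceTable":
        """Return a copy with a new data matrix (taxonomy/metadata subset to match)."""
        return AbundanceTable(
            data=data,
            mode=self.mode if mode is None else mode,
            taxonomy=self.taxonomy.loc[data.columns].copy(),
            metadata=self.metadata.loc[data.index].copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"malformed numeric cell in column {col!r}, row {row!r} of {path}"
        )
    return df


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Parse the JSON dialect of the BIOM format (rows = observations/taxa)."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    # BIOM stores observations as rows; our convention is samples as rows
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def read_abundance_table(
    path,
    format: str = "tsv",
    orientation: str = "samples-rows",
    mode: str = "counts",
    taxonomy_path=None,
    metadata_path=None,
) -> AbundanceTable:
    """Read an abundance matrix from TSV/CSV/BIOM-JSON into an AbundanceTable.

    ``orientation`` names the layout of the *file*; the returned table is
    always samples × taxa.  BIOM files carry their own orientation
    (observations are rows) and ignore the ``orientation`` argument.
    Optional sidecar files attach taxonomy and sample metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_delimited(path, "\t")
    elif format == "csv":
        df = _read_delimited(path, ",")
    elif format == "biom-json":
        df = _read_biom_json(path)
        orientation = "samples-rows"
    else:
        raise ValueError(f"unknown format {format!r}")
    if orientation == "taxa-rows":
        df = df.T
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    metadata = read_metadata(metadata_path) if metadata_path else None
    if metadata is not None:
        metadata = metadata.loc[df.index]
    return AbundanceTable(data=df, mode=mode, taxonomy=taxonomy, metadata=metadata)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV with columns taxon_id, phylum, family, genus[, species]."""
    tax = pd.read_csv(path, sep="\t", index_col="taxon_id", dtype=str)
    for rank in TAXONOMY_RANKS:
        if rank not in tax.columns:
            tax[rank] = "unclassified"
    return tax.fillna("unclassified")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV keyed by a sample_id column."""
    return pd.read_csv(path, index_col="sample_id")


def write_abundance_table(table: AbundanceTable, path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: AbundanceTable, min_nonzero_fraction: float = 0.10
) -> AbundanceTable:
    """Drop taxa detected (nonzero) in fewer than ``min_nonzero_fraction`` of samples.

    The default 0.10 keeps taxa present in at least 10% of samples, i.e.
    removes any taxon with zero abundance in more than 90% of samples.
    Taxon order is preserved; the sample set is unchanged.  On a
    relative-mode table the retained rows are re-closed to sum 1, keeping
    the invariant that relative abundances are taken over retained taxa.
    """
    if not (0 < min_nonzero_fraction <= 1):
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    frac_nonzero = (table.data.to_numpy() > 0).mean(axis=0)
    keep = frac_nonzero >= min_nonzero_fraction
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every taxon; lower min_nonzero_fraction"
        )
    data = table.data.loc[:, table.data.columns[keep]]
    if table.mode == "relative":
        sums = data.sum(axis=1)
        if (sums == 0).any():
            bad = list(sums.index[sums == 0][:5])
            raise ValueError(f"filtering left all-zero sample row(s): {bad}")
        data = data.div(sums, axis=0)
    return table.with_data(data)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample row to sum 1 (idempotent on relative-mode input).

    Run *after* :func:`prevalence_filter`: relative abundances are computed
    over the retained taxa, so filtering order changes the row sums.
    """
    if table.mode == "relative":
        return table
    sums = table.data.sum(axis=1)
    zero_rows = sums[sums == 0]
    if len(zero_rows):
        raise ValueError(f"all-zero sample row(s): {list(zero_rows.index[:5])}")
    rel = table.data.div(sums, axis=0)
    return table.with_data(rel, mode="relative")
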