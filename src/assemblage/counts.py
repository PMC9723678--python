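"""Count-table data model, TSV/CSV I/O, multi-rarefaction normalisation,
Hill diversity, and sample filtering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger

METADATA_COLUMNS = (
    "sample_id", "microcosm_id", "regime_code", "disturbance_at_sampling",
    "capacity", "replicate", "day", "period",
)


@dataclass
class CountTable:
    """Taxa x samples abundance matrix.

    Integer raw counts before normalisation; real-valued after averaged
    rarefaction. Backed by a pandas DataFrame with taxon ids as the index
    (named ``OTU_ID``) and sample ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        if df.size and (df.values < 0).any():
            r, c = np.argwhere(df.values < 0)[0]
            raise ValidationError(
                f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        df.index = df.index.astype(str)
        df.index.name = "OTU_ID"
        df.columns = df.columns.astype(str)

    @property
    def taxa(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def drop_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.drop(columns=list(sample_ids)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, path, provenance: str | None = None) -> None:
    """Write as TSV: first column OTU_ID, one column per sample.

    Optional provenance string is written as a leading '#' comment line and
    skipped on read.
    """
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.data.to_csv(fh, sep="\t", float_format="%.12g")


def read_count_table(path) -> CountTable:
    """Read a TSV count table, validating ids and non-negativity."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed count table {path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValidationError(
            f"non-numeric count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.size and np.allclose(numeric.values, np.round(numeric.values)):
        numeric = numeric.round().astype(np.int64)
    return CountTable(numeric)


def write_metadata(metadata: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        metadata.to_csv(fh, index=False)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, comment="#", keep_default_na=False,
                     dtype={"disturbance_at_sampling": str, "capacity": str,
                            "regime_code": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    return md


def validate_pairing(table: CountTable, metadata: pd.DataFrame) -> None:
    """Samples in table and metadata must match 1:1 (order-insensitive)."""
    t, m = set(table.samples), set(metadata["sample_id"])
    if t != m:
        raise ValidationError(
            f"table/metadata sample mismatch: {sorted(t - m)[:3]} only in table, "
            f"{sorted(m - t)[:3]} only in metadata"
        )


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy_mean(table: CountTable, depth: int = 10_000, n_rep: int = 1000,
                seed: int = 0) -> CountTable:
    """Normalise by averaging ``n_rep`` without-replacement rarefactions.

    Each sample is subsampled to exactly ``depth`` reads (multivariate
    hypergeometric draw) ``n_rep`` times and the draws averaged elementwise,
    so every retained output column sums to exactly ``depth``. Samples with
    fewer than ``depth`` total reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValidationError(f"depth must be > 0, got {depth}")
    if n_rep <= 0:
        raise ValidationError(f"n_rep must be > 0, got {n_rep}")
    values = table.data.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValidationError("rarefaction requires integer counts")
        values = np.round(values).astype(np.int64)

    totals = values.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.samples, keep) if not k]
        logger.warning("rarefy_mean: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if not keep.any():
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")

    rng = np.random.default_rng(seed)
    out = {}
    for j, sample in enumerate(table.samples):
        if not keep[j]:
            continue
        draws = rng.multivariate_hypergeometric(values[:, j], depth, size=n_rep)
        out[sample] = draws.mean(axis=0)
    result = pd.DataFrame(out, index=table.data.index)
    return CountTable(result)


# ---------------------------------------------------------------------------
# Hill diversity
# ---------------------------------------------------------------------------

def hill_diversity(counts: np.ndarray, q: float) -> float:
    """Effective number of taxa of order q.

    ``(sum p_i^q)^(1/(1-q))`` for q != 1 and ``exp(-sum p_i ln p_i)`` at q = 1,
    with p_i over the nonzero taxa. q = 0 is richness, q = 1 exponential
    Shannon, q = 2 inverse Simpson.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.all(counts == 0):
        raise ValidationError("Hill diversity is undefined for an all-zero vector")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if q < 0:
        raise ValidationError(f"order q must be >= 0, got {q}")
    p = counts[counts > 0]
    p = p / p.sum()
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def hill_profile(table: CountTable, orders=(0, 1, 2)) -> pd.DataFrame:
    """Hill diversity per sample for several orders (rows: samples)."""
    rows = {
        s: {f"hill_q{q:g}": hill_diversity(table.sample_counts(s), q) for q in orders}
        for s in table.samples
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_samples(table: CountTable, metadata: pd.DataFrame,
                   rule: str | list | None) -> tuple[CountTable, pd.DataFrame]:
    """Remove samples matching an exclusion rule from table and metadata.

    ``rule`` is either a pandas query string evaluated on the metadata
    (samples matching it are REMOVED), an explicit list of sample ids, or
    None/empty for the identity.
    """
    validate_pairing(table, metadata)
    if rule is None or (isinstance(rule, (list, tuple)) and not rule) or rule == "":
        return table, metadata
    if isinstance(rule, str):
        try:
            matched = metadata.query(rule)["sample_id"].tolist()
        except Exception as exc:
            raise ValidationError(f"invalid exclusion rule {rule!r}: {exc}") from exc
    else:
        unknown = [s for s in rule if s not in set(metadata["sample_id"])]
        if unknown:
            raise ValidationError(f"exclusion list names unknown samples: {unknown[:5]}")
        matched = list(rule)
    if len(matched) == len(metadata):
        raise ValidationError("exclusion rule removes every sample")
    logger.info("filter_samples: removing %d of %d samples", len(matched), len(metadata))
    kept_md = metadata[~metadata["sample_id"].isin(matched)].reset_index(drop=True)
    return table.drop_samples(matched), kept_md


__all__ = [
    "CountTable", "METADATA_COLUMNS", "read_count_table", "write_count_table",
    "read_metadata", "write_metadata", "validate_pairing", "rarefy_mean",
    "hill_diversity", "hill_profile", "filter_samples",
]
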