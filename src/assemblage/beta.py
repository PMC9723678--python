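"""Beta diversity: pairwise similarity indices, the replicate-similarity
time series (the response variable of the assembly model), principal
coordinates analysis, and PERMANOVA effect sizes."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger
from .counts import CountTable, validate_pairing
from .simulate import INOCULUM_REGIME

SIMILARITY_INDICES = ("bray_curtis", "sorensen")


# ---------------------------------------------------------------------------
# pairwise indices
# ---------------------------------------------------------------------------

def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must be 1-D and equal length, got {x.shape}, {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValidationError("similarity is undefined for two all-zero vectors")
    return x, y


def bray_curtis_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    x, y = _check_pair(x, y)
    return float(1.0 - np.abs(x - y).sum() / (x + y).sum())


def sorensen_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Presence/absence index 2a / (2a + b + c); equals Bray-Curtis on
    binarised vectors."""
    x, y = _check_pair(x, y)
    xb, yb = x > 0, y > 0
    a = int(np.sum(xb & yb))
    b = int(np.sum(xb & ~yb))
    c = int(np.sum(~xb & yb))
    return float(2 * a / (2 * a + b + c))


_INDEX_FUNCS = {"bray_curtis": bray_curtis_similarity, "sorensen": sorensen_similarity}


# ---------------------------------------------------------------------------
# replicate-similarity series
# ---------------------------------------------------------------------------

def replicate_similarity_series(table: CountTable, metadata: pd.DataFrame,
                                index: str = "bray_curtis") -> pd.DataFrame:
    """Similarity between every unordered pair of replicate microcosms of the
    same regime at each sampling day.

    Returns a long-format frame with one row per (regime, day, replicate pair):
    columns comparison_id, regime_code, disturbance_at_sampling, capacity,
    day, period, centered_day, index, similarity.  ``centered_day`` is the
    day minus the mean day of the records within the same period (the records
    entering one model fit), so it averages to ~0 within each period.
    """
    if index not in _INDEX_FUNCS:
        raise ValidationError(f"unknown similarity index {index!r}; choose from {SIMILARITY_INDICES}")
    validate_pairing(table, metadata)
    func = _INDEX_FUNCS[index]
    md = metadata[metadata["regime_code"] != INOCULUM_REGIME]

    rows = []
    for (regime, day), grp in md.groupby(["regime_code", "day"], sort=True):
        grp = grp.sort_values("replicate")
        if len(grp) < 2:
            logger.warning("replicate_similarity_series: %s day %s has %d replicate(s); skipped",
                           regime, day, len(grp))
            continue
        for a, b in itertools.combinations(grp.itertuples(), 2):
            r1, r2 = sorted([str(a.replicate), str(b.replicate)])
            rows.append({
                "comparison_id": f"{regime}:r{r1}-r{r2}",
                "regime_code": regime,
                "disturbance_at_sampling": a.disturbance_at_sampling,
                "capacity": a.capacity,
                "day": float(day),
                "period": int(a.period),
                "index": index,
                "similarity": func(table.sample_counts(a.sample_id),
                                   table.sample_counts(b.sample_id)),
            })
    records = pd.DataFrame(rows)
    if records.empty:
        raise ValidationError("no regime/day group has two or more replicates")
    records["centered_day"] = records["day"] - records.groupby("period")["day"].transform("mean")
    cols = ["comparison_id", "regime_code", "disturbance_at_sampling", "capacity",
            "day", "period", "centered_day", "index", "similarity"]
    return records[cols]


def dissimilarity_matrix(table: CountTable, index: str = "bray_curtis") -> pd.DataFrame:
    """Square symmetric sample x sample dissimilarity (1 - similarity) matrix."""
    func = _INDEX_FUNCS[index]
    samples = table.samples
    n = len(samples)
    d = np.zeros((n, n))
    cols = [table.sample_counts(s) for s in samples]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - func(cols[i], cols[j])
    return pd.DataFrame(d, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _check_dissimilarity(d) -> np.ndarray:
    d = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) else d.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"dissimilarity matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    if np.any(d < -1e-12):
        raise ValidationError("dissimilarities must be non-negative")
    return d


def pcoa(dissimilarity) -> tuple[np.ndarray, np.ndarray]:
    """Classical (metric) multidimensional scaling.

    Double-centres the Gower matrix -D^2/2, eigendecomposes it, and returns
    coordinates (eigenvectors scaled by sqrt(eigenvalue)) for the positive
    eigenvalues, axes ordered by decreasing eigenvalue.  All eigenvalues
    (including negative ones, which get no axis) are returned alongside.
    """
    d = _check_dissimilarity(dissimilarity)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return coords, eigval


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared dissimilarities and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_within, ss_total


def permanova(dissimilarity, labels, n_perm: int = 999,
              seed: int = 0) -> dict[str, float]:
    """One-way PERMANOVA: pseudo-F, R^2 effect size, permutation p-value.

    R^2 = SS_between / SS_total computed from pairwise dissimilarities;
    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under free
    permutation of the labels.
    """
    d = _check_dissimilarity(dissimilarity)
    labels = np.asarray(labels)
    if len(labels) != d.shape[0]:
        raise ValidationError("labels must align with the dissimilarity matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if np.any(counts == 0):
        raise ValidationError("every group must be non-empty")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")

    n, a = d.shape[0], len(groups)
    d2 = d ** 2

    def pseudo_f(lab):
        ss_w, ss_t = _permanova_ss(d2, lab)
        ss_b = ss_t - ss_w
        if ss_w <= 0:
            return np.inf
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    ss_w, ss_t = _permanova_ss(d2, labels)
    ss_b = ss_t - ss_w
    f_obs = pseudo_f(labels)
    r2 = ss_b / ss_t if ss_t > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return {"pseudo_f": float(f_obs), "r2": float(r2), "p_value": float(p),
            "n_perm": int(n_perm)}


def write_similarity_records(records: pd.DataFrame, path,
                             provenance: str | None = None) -> None:
    """Long-format CSV contract between beta diversity and the assembly model."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        records.to_csv(fh, index=False)


def read_similarity_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, comment="#")
    needed = {"comparison_id", "regime_code", "disturbance_at_sampling", "capacity",
              "day", "period", "centered_day", "index", "similarity"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"similarity records missing columns: {sorted(missing)}")
    return records


__all__ = [
    "bray_curtis_similarity", "sorensen_similarity", "replicate_similarity_series",
    "dissimilarity_matrix", "pcoa", "permanova", "SIMILARITY_INDICES",
    "write_similarity_records", "read_similarity_records",
]
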