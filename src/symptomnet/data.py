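"""Dataset container, I/O, inclusion filtering and scale-level descriptives.

The central object is :class:`ItemDataset`: a subjects x items integer
matrix tied to an :class:`~symptomnet.schema.ItemSchema`.  Helpers implement
the euthymia inclusion rule (total-score caps on the depression and mania
scales), removal of sex-specific items, and scale descriptives (totals,
Spearman correlations between scale totals, McDonald's omega).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .schema import ItemSchema, SchemaError

MISSING_MARKERS = {"", "NA", "NaN", "nan", "N/A"}


class ValidationError(ValueError):
    """Raised when data values violate the schema."""


@dataclass(frozen=True)
class ItemDataset:
    """Subjects x items integer matrix with schema and subject attributes.

    ``values`` is float64 so that missing entries can be carried as NaN;
    all non-missing entries are integral and lie within their item's
    level range (enforced at construction).
    """

    schema: ItemSchema
    values: np.ndarray
    subject_ids: tuple[str, ...] = ()
    sex: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if vals.shape[1] != len(self.schema):
            raise ValidationError(
                f"values has {vals.shape[1]} columns but schema has "
                f"{len(self.schema)} items"
            )
        object.__setattr__(self, "values", vals)
        if not self.subject_ids:
            object.__setattr__(
                self, "subject_ids", tuple(f"S{k:05d}" for k in range(vals.shape[0]))
            )
        if len(self.subject_ids) != vals.shape[0]:
            raise ValidationError("subject_ids length does not match values")
        if self.sex is not None and len(self.sex) != vals.shape[0]:
            raise ValidationError("sex length does not match values")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        vals = self.values
        finite = np.isfinite(vals)
        if not np.array_equal(vals[finite], np.round(vals[finite])):
            bad = np.argwhere(finite & (vals != np.round(vals)))
            r, c = bad[0]
            raise ValidationError(
                f"non-integer value {vals[r, c]!r} for subject "
                f"{self.subject_ids[r]!r}, item {self.schema.item_ids[c]!r}"
            )
        lo = self.schema.min_levels
        hi = self.schema.max_levels
        out = finite & ((vals < lo) | (vals > hi))
        if out.any():
            r, c = np.argwhere(out)[0]
            it = self.schema.items[c]
            raise ValidationError(
                f"value {int(vals[r, c])} out of range "
                f"[{it.min_level}, {it.max_level}] for subject "
                f"{self.subject_ids[r]!r}, item {it.item_id!r}"
            )

    # ------------------------------------------------------------ accessors
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return self.schema.item_ids

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=self.item_ids
        )
        df.index.name = "subject_id"
        return df

    def scale_total(self, scale: str) -> np.ndarray:
        """Row sums over the items of one scale (NaN if any item missing)."""
        cols = [self.schema.index(i) for i in self.schema.scale_item_ids(scale)]
        if not cols:
            raise SchemaError(f"schema has no {scale!r} items")
        return self.values[:, cols].sum(axis=1)

    # ----------------------------------------------------------- transforms
    def select_subjects(self, mask: np.ndarray) -> "ItemDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            values=self.values[idx],
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            sex=None if self.sex is None else tuple(self.sex[i] for i in idx),
        )

    def select_items(self, item_ids: Sequence[str]) -> "ItemDataset":
        sub = self.schema.subset(item_ids)
        cols = [self.schema.index(i) for i in sub.item_ids]
        return replace(self, schema=sub, values=self.values[:, cols])

    def drop_missing(self) -> "ItemDataset":
        """Listwise deletion: drop subjects with any missing item."""
        keep = ~np.isnan(self.values).any(axis=1)
        return self.select_subjects(keep)

    def counts_matrix(self) -> np.ndarray:
        """Complete-case integer matrix (raises if missing values remain)."""
        if self.has_missing:
            raise ValidationError(
                "dataset contains missing values; call drop_missing() first"
            )
        return self.values.astype(np.int64)


# ---------------------------------------------------------------------- I/O
def read_dataset(
    csv_path,
    schema_path=None,
    schema: Optional[ItemSchema] = None,
    sex_column: str = "sex",
) -> ItemDataset:
    """Read a subjects x items CSV against a JSON schema.

    The CSV header must name every schema item (any order; extra columns
    named ``subject_id`` or ``sex`` are used as attributes).  Cells are
    integers; an empty cell or ``NA`` marks a missing response.
    """
    if schema is None:
        if schema_path is None:
            raise SchemaError("either schema_path or schema must be given")
        schema = ItemSchema.from_json(schema_path)
    df = pd.read_csv(
        csv_path, dtype=str, keep_default_na=False, na_values=[], skipinitialspace=True
    )
    if "subject_id" in df.columns:
        subject_ids = tuple(df["subject_id"].astype(str))
        df = df.drop(columns=["subject_id"])
    else:
        subject_ids = ()
    sex = None
    if sex_column in df.columns:
        sex = tuple(df[sex_column].astype(str))
        df = df.drop(columns=[sex_column])
    unknown = [c for c in df.columns if c not in set(schema.item_ids)]
    if unknown:
        raise SchemaError(f"CSV columns not in schema: {unknown}")
    absent = [c for c in schema.item_ids if c not in set(df.columns)]
    if absent:
        raise SchemaError(f"schema items missing from CSV: {absent}")
    vals = np.full((len(df), len(schema)), np.nan)
    for j, item_id in enumerate(schema.item_ids):
        col = df[item_id].str.strip()
        present = ~col.isin(MISSING_MARKERS)
        try:
            vals[present.to_numpy(), j] = col[present].astype(int).to_numpy()
        except ValueError as exc:
            raise ValidationError(
                f"non-integer cell in column {item_id!r}: {exc}"
            ) from exc
    return ItemDataset(schema=schema, values=vals, subject_ids=subject_ids, sex=sex)


def write_dataset(ds: ItemDataset, csv_path) -> None:
    """Write a dataset as UTF-8 CSV (missing values as empty cells)."""
    df = ds.to_frame()
    out = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    if ds.sex is not None:
        out.insert(0, "sex", list(ds.sex))
    out.to_csv(csv_path, encoding="utf-8")


# ----------------------------------------------------------------- filters
def euthymia_filter(
    ds: ItemDataset, madrs_max: float = 10, ymrs_max: float = 12
) -> ItemDataset:
    """Retain subjects in the euthymic range of both mood scales.

    Euthymia is operationalized by total-score caps: MADRS total <=
    ``madrs_max`` and YMRS total <= ``ymrs_max`` (both inclusive; the
    liberal defaults are 10 and 12).  Thresholds are configurable for
    sensitivity analyses with more conservative cutoffs.
    """
    if not ds.schema.scale_item_ids("MADRS") or not ds.schema.scale_item_ids("YMRS"):
        raise SchemaError("euthymia filter requires MADRS and YMRS items in schema")
    madrs = ds.scale_total("MADRS")
    ymrs = ds.scale_total("YMRS")
    keep = (madrs <= madrs_max) & (ymrs <= ymrs_max)
    keep &= ~np.isnan(madrs) & ~np.isnan(ymrs)
    return ds.select_subjects(keep)


def drop_sex_specific(ds: ItemDataset, sex: str) -> ItemDataset:
    """Remove items that are not administered to subjects of ``sex``."""
    sub = ds.schema.for_sex(sex)
    return ds.select_items(sub.item_ids)


# ------------------------------------------------------------ descriptives
@dataclass(frozen=True)
class ScaleDescriptives:
    """Scale totals, their Spearman correlations, omega, and level counts."""

    totals: pd.DataFrame
    spearman: pd.DataFrame
    omega: dict[str, float]
    level_counts: pd.DataFrame


def one_factor_ml(S: np.ndarray, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood one-factor decomposition of a covariance matrix.

    Returns loadings ``lam`` and uniquenesses ``psi`` with
    ``S ~ lam lam' + diag(psi)``.  The likelihood is profiled over the
    loadings: for fixed psi the optimal loading direction is the leading
    eigenvector of psi^{-1/2} S psi^{-1/2}, and the discrepancy reduces to
    a function of the remaining eigenvalues, minimized over log psi.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    d = np.diag(S).copy()
    if np.any(d <= 0):
        raise ValidationError("covariance matrix has non-positive diagonal")

    def split(log_psi):
        psi = np.exp(np.clip(log_psi, np.log(d) - 14.0, np.log(d) + 3.0))
        isq = 1.0 / np.sqrt(psi)
        M = S * np.outer(isq, isq)
        theta, vecs = linalg.eigh(M)
        return psi, theta, vecs

    def objective(log_psi):
        _, theta, _ = split(log_psi)
        # discrepancy from all but the leading eigenvalue
        th = np.clip(theta[:-1], 1e-12, None)
        return float(np.sum(th - np.log(th) - 1.0))

    # start from squared-multiple-correlation style uniquenesses
    start = np.log(np.clip(d * 0.5, 1e-6, None))
    bounds = [(lo - 14.0, lo + 3.0) for lo in np.log(d)]  # Heywood guard
    res = optimize.minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    psi, theta, vecs = split(res.x)
    lead = max(theta[-1], 1.0)
    lam = np.sqrt(psi) * vecs[:, -1] * np.sqrt(lead - 1.0)
    if lam.sum() < 0:
        lam = -lam
    return lam, psi


def omega_from_covariance(S: np.ndarray) -> float:
    """McDonald's omega-total from a one-factor ML fit of a covariance."""
    lam, psi = one_factor_ml(np.asarray(S, dtype=float))
    num = lam.sum() ** 2
    return float(num / (num + psi.sum()))


def mcdonalds_omega(values: np.ndarray) -> float:
    """McDonald's omega-total for a complete-case items matrix.

    Loadings come from a one-factor maximum-likelihood fit of the Pearson
    covariance; omega = (sum lam)^2 / ((sum lam)^2 + sum psi).
    """
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("omega requires at least 3 subjects")
    S = np.cov(X, rowvar=False)
    return omega_from_covariance(S)


def scale_descriptives(ds: ItemDataset) -> ScaleDescriptives:
    """Totals per scale, Spearman correlations between totals, omega.

    Spearman uses average ranks for ties (the standard convention for
    heavily tied ordinal data).  A zero-variance total yields NaN in the
    correlation matrix rather than a spurious 0.
    """
    ds = ds.drop_missing()
    scales = ds.schema.scales
    totals = pd.DataFrame(
        {sc: ds.scale_total(sc) for sc in scales}, index=list(ds.subject_ids)
    )
    k = len(scales)
    corr = np.full((k, k), np.nan)
    np.fill_diagonal(corr, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            x, y = totals.iloc[:, a], totals.iloc[:, b]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # undefined under zero variance
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(x, y).statistic
            corr[a, b] = corr[b, a] = rho
    spearman = pd.DataFrame(corr, index=scales, columns=scales)

    omega: dict[str, float] = {}
    for sc in scales:
        cols = ds.schema.scale_item_ids(sc)
        if len(cols) < 3:
            omega[sc] = float("nan")
            continue
        sub = ds.select_items(cols)
        try:
            omega[sc] = mcdonalds_omega(sub.values)
        except (ValidationError, linalg.LinAlgError):
            omega[sc] = float("nan")

    counts = []
    for j, it in enumerate(ds.schema.items):
        col = ds.values[:, j]
        for lev in range(it.min_level, it.max_level + 1):
            counts.append(
                {
                    "item_id": it.item_id,
                    "scale": it.scale,
                    "level": lev,
                    "count": int((col == lev).sum()),
                }
            )
    level_counts = pd.DataFrame(counts)
    return ScaleDescriptives(
        totals=totals, spearman=spearman, omega=omega, level_counts=level_counts
    )
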