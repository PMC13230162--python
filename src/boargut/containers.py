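"""Core data containers shared by every pipeline stage.

All tabular containers wrap :class:`pandas.DataFrame` objects with samples on
the rows and taxa on the columns, indexed by string ids.  Validation happens
at construction so downstream stages can assume well-formed inputs.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: row total of a TPM-normalised abundance table
TPM_TOTAL = 1_000_000.0

#: average read length (bp) converting reads-per-base into fold coverage
DEFAULT_READ_LENGTH = 151

#: boar developmental stages, in age order
AGE_STAGES = ("young", "mid", "aged")

#: default stage boundaries: 12 months = 365 days, 36 months = 1095 days
YOUNG_MAX_DAYS = 365
MID_MAX_DAYS = 1095


def assign_age_stage(age_days, young_max_days: int = YOUNG_MAX_DAYS,
                     mid_max_days: int = MID_MAX_DAYS):
    """Map age in days onto the three boar developmental stages.

    ``young`` covers up to 12 months, ``mid`` 12-36 months and ``aged``
    everything older.  Accepts a scalar or an array; nonpositive ages are
    rejected.

    Parameters
    ----------
    age_days : int or array-like of int
        Age(s) in days, must be >= 1.
    young_max_days, mid_max_days : int
        Upper bounds (inclusive) of the young and mid stages.

    Returns
    -------
    str or numpy.ndarray of str
    """
    arr = np.asarray(age_days)
    if arr.size == 0:
        return np.asarray([], dtype=object)
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError("age_days must be numeric")
    if (arr <= 0).any():
        raise ValueError("age_days must be positive")
    if not (0 < young_max_days < mid_max_days):
        raise ValueError("stage boundaries must satisfy 0 < young < mid")
    out = np.where(arr <= young_max_days, AGE_STAGES[0],
                   np.where(arr <= mid_max_days, AGE_STAGES[1], AGE_STAGES[2]))
    if arr.ndim == 0:
        return str(out[()])
    return out.astype(object)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicated {what} ids: {dups}")


def _as_string_index(index: pd.Index) -> pd.Index:
    return pd.Index([str(x) for x in index], name=index.name)


class AbundanceTable:
    """Samples x taxa abundance matrix, conventionally on the TPM scale.

    Values are nonnegative reals; a normalised table has every row summing to
    ``TPM_TOTAL`` (1e6).  ``taxonomy`` optionally maps each taxon id to a
    7-rank semicolon-delimited lineage string.
    """

    def __init__(self, data, taxonomy: pd.Series | None = None):
        data = pd.DataFrame(data).astype(float)
        data.index = _as_string_index(data.index)
        data.columns = _as_string_index(data.columns)
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "taxon")
        values = data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if (values < 0).any():
            raise ValueError("abundance values must be nonnegative")
        self.data = data
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy).astype(str)
            taxonomy.index = _as_string_index(taxonomy.index)
            missing = set(data.columns) - set(taxonomy.index)
            if missing:
                raise ValueError(f"taxonomy missing for taxa: {sorted(missing)[:5]}")
            taxonomy = taxonomy.reindex(data.columns)
        self.taxonomy = taxonomy

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
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

    @property
    def is_normalized(self) -> bool:
        """True when every row sums to TPM_TOTAL within 1e-4 relative."""
        sums = self.values.sum(axis=1)
        return bool(np.all(np.abs(sums - TPM_TOTAL) <= 1e-4 * TPM_TOTAL))

    def require_normalized(self) -> "AbundanceTable":
        if not self.is_normalized:
            raise ValueError("abundance table is not TPM-normalised; "
                             "call abundance.normalize_tpm first")
        return self

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (rows sum to 1)."""
        sums = self.values.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums.ravel()) if t == 0]
            raise ValueError(f"all-zero samples: {bad[:5]}")
        return pd.DataFrame(self.values / sums, index=self.data.index,
                            columns=self.data.columns)

    # -- subsetting ----------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.taxonomy)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        taxon_ids = list(taxon_ids)
        taxonomy = None if self.taxonomy is None else self.taxonomy.loc[taxon_ids]
        return AbundanceTable(self.data.loc[:, taxon_ids], taxonomy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        norm = "TPM" if self.is_normalized else "raw"
        return (f"<AbundanceTable {self.n_samples} samples x {self.n_taxa} "
                f"taxa ({norm})>")


class CoverageStats:
    """Per (sample, taxon) reads-per-base, paired with an abundance table.

    Effective fold coverage is reads-per-base times the average read length.
    """

    def __init__(self, data, read_length: int = DEFAULT_READ_LENGTH):
        data = pd.DataFrame(data).astype(float)
        data.index = _as_string_index(data.index)
        data.columns = _as_string_index(data.columns)
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "taxon")
        values = data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("reads-per-base values must be finite")
        if (values < 0).any():
            raise ValueError("reads-per-base values must be nonnegative")
        read_length = int(read_length)
        if read_length <= 0:
            raise ValueError("read_length must be positive")
        self.data = data
        self.read_length = read_length

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def check_axes_match(self, tab: AbundanceTable) -> None:
        if list(self.data.index) != tab.sample_ids or \
                list(self.data.columns) != tab.taxon_ids:
            raise ValueError("coverage and abundance tables have different axes")

    def select_samples(self, sample_ids: Sequence[str]) -> "CoverageStats":
        return CoverageStats(self.data.loc[list(sample_ids)], self.read_length)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CoverageStats {self.data.shape[0]} samples x "
                f"{self.data.shape[1]} taxa, read_length={self.read_length}>")


class SampleMetadata:
    """Per-sample design information: breed, farm, company, batch and age.

    The developmental stage column ``age_stage`` is derived from ``age_days``
    at construction (or validated against it when already present).
    """

    REQUIRED = ("breed", "farm", "company", "batch", "age_days")

    def __init__(self, frame: pd.DataFrame,
                 stage_boundaries: tuple[int, int] = (YOUNG_MAX_DAYS, MID_MAX_DAYS)):
        frame = pd.DataFrame(frame).copy()
        if frame.index.name != "sample_id" and "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        frame.index = _as_string_index(frame.index)
        frame.index.name = "sample_id"
        _check_unique(frame.index, "sample")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        frame["age_days"] = frame["age_days"].astype(int)
        if (frame["age_days"] <= 0).any():
            bad = frame.index[frame["age_days"] <= 0].tolist()[:5]
            raise ValueError(f"nonpositive age_days for samples: {bad}")
        for col in ("breed", "farm", "company", "batch"):
            frame[col] = frame[col].astype(str)
        young_max, mid_max = stage_boundaries
        derived = assign_age_stage(frame["age_days"].to_numpy(), young_max, mid_max)
        if "age_stage" in frame.columns:
            given = frame["age_stage"].astype(str).to_numpy()
            if not np.array_equal(given, derived):
                bad = frame.index[given != derived].tolist()[:5]
                raise ValueError(
                    f"age_stage inconsistent with age_days for samples: {bad}")
        frame["age_stage"] = derived
        self.frame = frame
        self.stage_boundaries = (int(young_max), int(mid_max))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def align_to(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        """Subset and reorder to ``sample_ids``; missing ids raise KeyError."""
        sample_ids = [str(s) for s in sample_ids]
        missing = set(sample_ids) - set(self.frame.index)
        if missing:
            raise KeyError(f"samples absent from metadata: {sorted(missing)[:5]}")
        return SampleMetadata(self.frame.loc[sample_ids], self.stage_boundaries)

    def groups(self, by: str) -> pd.Series:
        if by not in self.frame.columns:
            raise KeyError(f"unknown metadata column: {by!r}")
        return self.frame[by]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SampleMetadata {len(self.frame)} samples>"


class PresenceMatrix:
    """Boolean samples x taxa matrix recording called presence.

    ``provenance`` records the thresholds used for the call so downstream
    set analyses can report them.
    """

    def __init__(self, data, provenance: dict | None = None):
        data = pd.DataFrame(data).astype(bool)
        data.index = _as_string_index(data.index)
        data.columns = _as_string_index(data.columns)
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "taxon")
        self.data = data
        self.provenance = dict(provenance or {})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        return PresenceMatrix(self.data.loc[list(sample_ids)], self.provenance)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PresenceMatrix {self.data.shape[0]} samples x "
                f"{self.data.shape[1]} taxa>")
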