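"""Data containers and I/O for paired-informant binary questionnaires.

The analyses in this package operate on a respondent × item matrix of
binary (endorsed / not endorsed) responses from one informant, together
with an item → syndrome membership table.  Two such matrices with aligned
respondents and items — e.g. a parent report and the child's self report
on the same instrument — form a :class:`PairedDataset`.

Raw checklist responses are trichotomous (0 = not true, 1 = somewhat true,
2 = very true); :func:`dichotomize` collapses the two positive categories.
Missing responses are carried as ``NaN`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SYNDROME_ORDER: tuple[str, ...] = ("AB", "AD", "AP", "RBB", "SC", "SP", "TP", "WD")
INTERNALIZING: frozenset[str] = frozenset({"AD", "WD", "SC"})
EXTERNALIZING: frozenset[str] = frozenset({"RBB", "AB"})

NO_SYNDROME = "none"


class DataFormatError(ValueError):
    """Malformed input file or matrix (bad categories, duplicate ids, ...)."""


class AlignmentError(ValueError):
    """Two inputs that must share respondent/item ids do not."""


def _as_str_list(labels: Sequence) -> list[str]:
    return [str(x) for x in labels]


@dataclass
class ResponseMatrix:
    """Binary respondent × item response matrix with an explicit missing mask.

    Parameters
    ----------
    values : ndarray of shape (n_respondents, n_items)
        Float array with entries in {0.0, 1.0} or ``NaN`` for missing.
    respondent_ids, item_ids : sequences of unique labels.
    informant : {"parent", "self", "other"}
    """

    values: np.ndarray
    respondent_ids: list[str]
    item_ids: list[str]
    informant: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("response matrix must be 2-dimensional")
        self.respondent_ids = _as_str_list(self.respondent_ids)
        self.item_ids = _as_str_list(self.item_ids)
        n, p = self.values.shape
        if len(self.respondent_ids) != n or len(self.item_ids) != p:
            raise DataFormatError("id lengths do not match matrix shape")
        if len(set(self.respondent_ids)) != n:
            raise DataFormatError("respondent ids are not unique")
        if len(set(self.item_ids)) != p:
            raise DataFormatError("item ids are not unique")
        if self.informant not in ("parent", "self", "other"):
            raise DataFormatError(f"unknown informant tag {self.informant!r}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isnan(self.values) & ~np.isin(self.values, (0.0, 1.0)))
            k, i = bad[0]
            raise DataFormatError(
                f"non-binary entry {self.values[k, i]!r} at respondent "
                f"{self.respondent_ids[k]!r}, item {self.item_ids[i]!r}"
            )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the response is missing."""
        return np.isnan(self.values)

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in _as_str_list(item_ids)]
        return ResponseMatrix(
            self.values[:, idx], self.respondent_ids, [self.item_ids[j] for j in idx],
            self.informant,
        )


@dataclass
class SyndromeMap:
    """Item → syndrome assignment with a canonical syndrome ordering.

    Items may legitimately belong to no syndrome; those carry the
    assignment ``"none"`` and are excluded from syndrome-level summaries.
    """

    assignments: dict[str, str]
    syndrome_order: tuple[str, ...] = SYNDROME_ORDER

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}
        known = set(self.syndrome_order) | {NO_SYNDROME}
        for item, syn in self.assignments.items():
            if syn not in known:
                raise DataFormatError(f"item {item!r} assigned unknown syndrome {syn!r}")

    def syndrome_of(self, item_id: str) -> str:
        return self.assignments.get(str(item_id), NO_SYNDROME)

    def members(self, syndrome: str) -> list[str]:
        return [i for i, s in self.assignments.items() if s == syndrome]

    def labels_with_members(self) -> list[str]:
        return [s for s in self.syndrome_order if self.members(s)]


@dataclass
class PairedDataset:
    """Two informants' response matrices on the same respondents and items."""

    a: ResponseMatrix
    b: ResponseMatrix
    syndromes: SyndromeMap

    def __post_init__(self) -> None:
        if self.a.item_ids != self.b.item_ids:
            raise AlignmentError("item ids of the two instruments differ")
        if self.a.respondent_ids != self.b.respondent_ids:
            raise AlignmentError("respondent ids of the two instruments differ")


def dichotomize(
    raw: np.ndarray | pd.DataFrame,
    respondent_ids: Sequence[str] | None = None,
    item_ids: Sequence[str] | None = None,
    informant: str = "other",
) -> ResponseMatrix:
    """Collapse trichotomous responses {0, 1, 2} to binary {0, 1}.

    0 maps to 0; the two positive categories 1 and 2 both map to 1; missing
    entries (NaN) are preserved.  Idempotent on already-binary input.
    """
    if isinstance(raw, pd.DataFrame):
        respondent_ids = respondent_ids if respondent_ids is not None else list(raw.index)
        item_ids = item_ids if item_ids is not None else list(raw.columns)
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    if respondent_ids is None:
        respondent_ids = [str(k) for k in range(raw.shape[0])]
    if item_ids is None:
        item_ids = [str(i) for i in range(raw.shape[1])]
    observed = ~np.isnan(raw)
    bad = observed & ~np.isin(raw, (0.0, 1.0, 2.0))
    if bad.any():
        k, i = np.argwhere(bad)[0]
        raise DataFormatError(
            f"invalid category {raw[k, i]!r} at row {respondent_ids[k]!r}, "
            f"column {item_ids[i]!r}: expected 0, 1, 2 or missing"
        )
    values = np.where(observed, (raw > 0).astype(float), np.nan)
    return ResponseMatrix(values, list(respondent_ids), list(item_ids), informant)


def positive_rate(m: ResponseMatrix) -> float:
    """Mean proportion of positive responses over non-missing cells."""
    obs = m.values[~m.missing_mask]
    if obs.size == 0:
        raise DataFormatError("positive_rate of an all-missing matrix is undefined")
    return float(obs.mean())


def positive_rate_summary(paired: PairedDataset) -> dict[str, float]:
    """Per-informant positive-response rates of a paired dataset."""
    return {
        paired.a.informant: positive_rate(paired.a),
        paired.b.informant: positive_rate(paired.b),
    }


# ---------------------------------------------------------------------------
# File I/O.  Wide CSV/TSV: header row = item ids, first column = respondent
# id.  Missing marker configurable (default "NA").

def read_response_matrix(
    path: str | Path,
    informant: str = "other",
    missing_token: str = "NA",
    sep: str = ",",
) -> ResponseMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise DataFormatError(f"{path}: duplicate respondent or item ids")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        is_missing = raw == missing_token
        try:
            parsed = np.where(is_missing, "nan", raw).astype(float)
        except ValueError as exc:
            raise DataFormatError(
                f"{path}: unparseable entry in column {col!r} "
                f"(missing token is {missing_token!r}): {exc}"
            ) from exc
        values[:, j] = parsed
    return ResponseMatrix(values, list(df.index), list(df.columns), informant)


def write_response_matrix(
    m: ResponseMatrix, path: str | Path, missing_token: str = "NA", sep: str = ","
) -> None:
    df = pd.DataFrame(m.values, index=m.respondent_ids, columns=m.item_ids)
    # integers, not 0.0/1.0, so that round-trips are textually stable
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.index.name = "respondent_id"
    out.to_csv(path, sep=sep)


def read_syndrome_map(path: str | Path, sep: str = ",") -> SyndromeMap:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (item_id, syndrome)")
    items = df.iloc[:, 0].tolist()
    if len(set(items)) != len(items):
        dupes = sorted({i for i in items if items.count(i) > 1})
        raise DataFormatError(f"{path}: duplicate item ids {dupes}")
    return SyndromeMap(dict(zip(items, df.iloc[:, 1].tolist())))


def write_syndrome_map(syn: SyndromeMap, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        {"item_id": list(syn.assignments), "syndrome": list(syn.assignments.values())}
    ).to_csv(path, sep=sep, index=False)


def read_paired_dataset(
    path_a: str | Path,
    path_b: str | Path,
    path_syndromes: str | Path,
    informant_a: str = "parent",
    informant_b: str = "self",
    missing_token: str = "NA",
    sep: str = ",",
) -> PairedDataset:
    """Read and align two response files plus a syndrome table.

    Rows and columns are harmonized by id, not position: instrument b is
    reindexed to instrument a's respondent and item order.
    """
    a = read_response_matrix(path_a, informant_a, missing_token, sep)
    b = read_response_matrix(path_b, informant_b, missing_token, sep)
    only_a = sorted(set(a.item_ids) - set(b.item_ids))
    only_b = sorted(set(b.item_ids) - set(a.item_ids))
    if only_a or only_b:
        raise AlignmentError(
            f"item ids differ between files: only in a={only_a}, only in b={only_b}"
        )
    if set(a.respondent_ids) != set(b.respondent_ids):
        raise AlignmentError("respondent ids differ between files; pre-match the files")
    col = [b.item_ids.index(i) for i in a.item_ids]
    row = [b.respondent_ids.index(k) for k in a.respondent_ids]
    b = ResponseMatrix(b.values[np.ix_(row, col)], a.respondent_ids, a.item_ids, b.informant)
    syn = read_syndrome_map(path_syndromes, sep)
    return PairedDataset(a, b, syn)
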