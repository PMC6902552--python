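"""Loading, normalization and QC of the mice × metabolites table.

The GC/MS workflow spikes every plasma sample with a known amount of
2-isopropylmalic acid; dividing each metabolite signal by that mouse's
internal-standard signal removes per-sample measurement-efficiency
variation.  Mice with any unmeasurable metabolite are dropped whole (no
imputation), mirroring how failed samples are handled upstream.

Feature scaling is deliberately *not* done here: z-scoring belongs to the
predictor, computed on training folds only, so that held-out mice never
leak into the statistics used to model them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyCohortError, NormalizationError, ParseError

logger = logging.getLogger(__name__)

INTERNAL_STANDARD = "2-isopropylmalic acid"


@dataclass
class MetabolomeMatrix:
    """Mice × metabolites concentrations.

    ``data`` is indexed by mouse_id with one column per metabolite; missing
    measurements are NaN and exposed through :attr:`missing_mask`.
    ``internal_standard`` names the spiked-compound column if the table has
    not been normalized yet; ``normalized`` records whether
    internal-standard normalization has been applied (or was declared
    unnecessary for pre-normalized input).
    """

    data: pd.DataFrame
    internal_standard: str | None = INTERNAL_STANDARD
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate mouse ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate metabolite names: {dup}")
        values = self.data.to_numpy(float)
        if np.any(values[np.isfinite(values)] < 0):
            bad = self.data.columns[(self.data < 0).any(axis=0)].tolist()
            raise ParseError(f"negative concentrations in columns {bad}")
        if self.internal_standard is not None and self.internal_standard not in self.data.columns:
            self.internal_standard = None

    @property
    def mouse_ids(self) -> list[str]:
        return [str(m) for m in self.data.index]

    @property
    def metabolite_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def features(self) -> pd.DataFrame:
        """Feature columns (everything except the internal standard)."""
        if self.internal_standard is None:
            return self.data
        return self.data.drop(columns=[self.internal_standard])


def _check_header(path: Path) -> None:
    """Reject empty files and duplicate metabolite names before pandas
    silently renames duplicated header entries."""
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n")
                break
    if header is None:
        raise ParseError(f"{path}: empty file")
    try:
        delim = csv.Sniffer().sniff(header).delimiter
    except csv.Error:
        delim = ","
    names = header.split(delim)[1:]
    dup = sorted({n for n in names if names.count(n) > 1})
    if dup:
        raise ParseError(f"{path}: duplicate metabolite names: {dup}")


def load_metabolome(
    path: str | Path,
    internal_standard: str | None = INTERNAL_STANDARD,
    normalized: bool = False,
) -> MetabolomeMatrix:
    """Parse a wide tabular-text file (CSV/TSV, delimiter sniffed).

    First column is the mouse id; the header row names the metabolites.
    Blank cells become entries in the missing mask.
    """
    path = Path(path)
    _check_header(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ParseError(f"{path}: need a mouse-id column and at least one metabolite column")
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df.index = df.index.astype(str)
    df.index.name = "mouse_id"
    return MetabolomeMatrix(data=df, internal_standard=internal_standard, normalized=normalized)


def normalize_to_internal_standard(m: MetabolomeMatrix) -> MetabolomeMatrix:
    """Divide every metabolite by the mouse's internal-standard value.

    The internal-standard column is removed from the feature set.  If the
    matrix is flagged as already normalized this is a no-op (supports
    pre-normalized deposited tables).
    """
    if m.normalized:
        return m
    if m.internal_standard is None:
        raise NormalizationError("no internal-standard column present; pass normalized=True for pre-normalized data")
    is_col = m.data[m.internal_standard]
    bad = is_col.index[is_col.isna() | (is_col == 0)].tolist()
    if bad:
        raise NormalizationError(f"missing or zero internal-standard value for mice: {bad}")
    out = m.data.drop(columns=[m.internal_standard]).div(is_col, axis=0)
    return MetabolomeMatrix(data=out, internal_standard=None, normalized=True)


def log2_transform(m: MetabolomeMatrix, eps: float = 1e-6) -> MetabolomeMatrix:
    """Optional log2(x + eps) transform of the feature values (default off
    in the pipeline; concentrations are modeled on the linear scale)."""
    out = np.log2(m.data + eps)
    shifted = out - out.min().min()  # keep the nonnegativity contract
    return MetabolomeMatrix(data=shifted, internal_standard=m.internal_standard, normalized=m.normalized)


def exclude_incomplete_mice(m: MetabolomeMatrix) -> tuple[MetabolomeMatrix, list[str]]:
    """Drop every mouse with at least one missing metabolite.

    Returns the surviving matrix (row order preserved) and the excluded
    mouse ids.  Raises :class:`EmptyCohortError` if nobody survives.
    """
    incomplete = m.data.isna().any(axis=1)
    excluded = [str(i) for i in m.data.index[incomplete]]
    kept = m.data.loc[~incomplete]
    logger.info("exclude_incomplete_mice: retained %d mice, excluded %d (%s)", len(kept), len(excluded), excluded)
    if kept.shape[0] == 0:
        raise EmptyCohortError("all mice have missing metabolite values")
    return MetabolomeMatrix(data=kept, internal_standard=m.internal_standard, normalized=m.normalized), excluded
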