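"""Expression and clinical data handling.

Loads probe-by-sample expression matrices (plain TSV or GEO Series Matrix
dialect) and clinical tables, standardizes expression per gene, bins
standardized values into LOW / TYPICAL / HIGH categories against a central
reference interval, and turns clinical records into binary phenotype labels.

Conventions
-----------
Expression matrices are ``pandas.DataFrame`` objects with gene/probe ids on
the index and sample ids on the columns, values float64.  Binned matrices use
the integer codes ``LOW = -1``, ``TYPICAL = 0``, ``HIGH = +1``.  Phenotype
vectors are ``pandas.Series`` of the string labels ``EVENT``, ``NO_EVENT``,
``EXCLUDED`` indexed by sample id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("binsig")

# Phenotype labels
EVENT = "EVENT"
NO_EVENT = "NO_EVENT"
EXCLUDED = "EXCLUDED"

# Bin codes
LOW = -1
TYPICAL = 0
HIGH = 1

#: default reference-interval coverage for binning
DEFAULT_BIN_LEVEL = 0.95
#: default clinical horizon for event binarization (10 years, in months)
DEFAULT_HORIZON_MONTHS = 120.0
#: divisor convention for the per-gene standard deviation (sample sd)
STANDARDIZE_DDOF = 1

VALID_RCB_CLASSES = ("0", "I", "II", "III")
RESPONDER_CLASSES = ("0", "I")

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


class ExpressionFormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates an invariant."""


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up time (months) and event indicator for one sample."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: follow-up time must be finite "
                f"and positive, got {self.time}"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """Post-treatment residual cancer burden class for one sample."""

    sample_id: str
    rcb_class: str

    def __post_init__(self):
        if self.rcb_class not in VALID_RCB_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: RCB class must be one of "
                f"{VALID_RCB_CLASSES}, got {self.rcb_class!r}"
            )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _validate_matrix(m: pd.DataFrame, impute_missing: bool = False) -> pd.DataFrame:
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if m.columns.has_duplicates:
        dups = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    if m.shape[0] < 1 or m.shape[1] < 2:
        raise ValidationError(
            f"matrix must have at least 1 gene and 2 samples, got {m.shape}"
        )
    if m.isna().any().any():
        if impute_missing:
            means = m.mean(axis=1)
            m = m.apply(lambda row: row.fillna(means[row.name]), axis=1)
            logger.warning("imputed missing cells with per-gene means")
        else:
            n = int(m.isna().sum().sum())
            raise ValidationError(
                f"{n} missing expression cells (pass impute_missing=True "
                "to impute with per-gene means)"
            )
    return m.astype(float)


def read_expression_matrix(
    path, format_hint: str | None = None, impute_missing: bool = False
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Two dialects are supported: plain tab-delimited text (header row of
    sample ids, first column gene ids) and the GEO Series Matrix layout,
    where metadata lines start with ``!`` and the data block sits between
    the table-begin/table-end sentinel lines with quoted identifiers.

    Parameters
    ----------
    path : str or Path
        Input file.
    format_hint : {"tsv", "series_matrix", None}
        Force a dialect; ``None`` sniffs it (a leading ``!`` line means
        Series Matrix).
    impute_missing : bool
        Replace missing cells with per-gene means instead of rejecting.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ExpressionFormatError(f"{path}: empty file")

    if format_hint is None:
        format_hint = "series_matrix" if lines[0].startswith("!") else "tsv"
    if format_hint == "series_matrix":
        try:
            begin = next(
                i for i, ln in enumerate(lines) if ln.strip().lower() == _TABLE_BEGIN
            )
            end = next(
                i for i, ln in enumerate(lines) if ln.strip().lower() == _TABLE_END
            )
        except StopIteration:
            raise ExpressionFormatError(
                f"{path}: missing series-matrix table sentinel lines"
            ) from None
        data_lines = lines[begin + 1 : end]
        offset = begin + 1
    elif format_hint == "tsv":
        data_lines = [ln for ln in lines if ln.strip()]
        offset = 0
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")

    if len(data_lines) < 2:
        raise ExpressionFormatError(f"{path}: no data rows")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.split("\t")]

    header = split(data_lines[0])
    sample_ids = header[1:]
    ncol = len(header)
    gene_ids, rows = [], []
    for k, line in enumerate(data_lines[1:], start=offset + 2):
        fields = split(line)
        if len(fields) != ncol:
            raise ExpressionFormatError(
                f"{path}: line {k}: expected {ncol} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for j, f in enumerate(fields[1:]):
            if f in ("", "NA", "null", "NaN"):
                row.append(np.nan)
                continue
            try:
                row.append(float(f))
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}: line {k}: non-numeric cell {f!r} "
                    f"(sample {sample_ids[j]!r})"
                ) from None
        rows.append(row)

    m = pd.DataFrame(rows, index=pd.Index(gene_ids, name="ID"), columns=sample_ids)
    return _validate_matrix(m, impute_missing=impute_missing)


def write_expression_matrix(m: pd.DataFrame, path) -> None:
    """Write a matrix in the plain TSV dialect the loader reads back."""
    out = m.copy()
    out.index.name = "ID"
    out.to_csv(path, sep="\t")


def read_clinical_table(
    path, mapping: dict, kind: str = "survival"
) -> list[SurvivalRecord] | list[ResponseRecord]:
    """Read a tab-delimited clinical table under a declared column mapping.

    ``mapping`` names the columns to use: ``sample_id`` plus, for
    ``kind="survival"``, ``time`` and ``event``; for ``kind="response"``,
    ``rcb``.  Rows with unparseable time values are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"survival": ("sample_id", "time", "event"),
              "response": ("sample_id", "rcb")}.get(kind)
    if needed is None:
        raise ValueError(f"unknown clinical table kind {kind!r}")
    missing = [c for c in needed if mapping.get(c) not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: column mapping for {missing} not found in header "
            f"{list(df.columns)}"
        )

    records: list = []
    if kind == "survival":
        for _, row in df.iterrows():
            sid = row[mapping["sample_id"]]
            raw_t, raw_e = row[mapping["time"]], row[mapping["event"]]
            try:
                t = float(raw_t)
            except (TypeError, ValueError):
                t = np.nan
            if not np.isfinite(t):
                logger.warning("dropping sample %s: unparseable time %r", sid, raw_t)
                continue
            ev = str(raw_e).strip().lower() in ("1", "true", "yes", "event")
            records.append(SurvivalRecord(str(sid), t, ev))
    else:
        for _, row in df.iterrows():
            sid = row[mapping["sample_id"]]
            rcb = str(row[mapping["rcb"]]).strip().upper()
            records.append(ResponseRecord(str(sid), rcb))
    return records


def write_clinical_table(records, path) -> None:
    """Write survival or response records in the TSV layout the reader expects."""
    if records and isinstance(records[0], SurvivalRecord):
        df = pd.DataFrame(
            {"sample_id": [r.sample_id for r in records],
             "time": [r.time for r in records],
             "event": [int(r.event) for r in records]}
        )
    else:
        df = pd.DataFrame(
            {"sample_id": [r.sample_id for r in records],
             "rcb": [r.rcb_class for r in records]}
        )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Standardization and binning
# ---------------------------------------------------------------------------

def standardize(
    m: pd.DataFrame, drop_constant: bool = True, ddof: int = STANDARDIZE_DDOF
) -> pd.DataFrame:
    """Z-transform each gene to mean 0 and standard deviation 1.

    The sample standard deviation (divisor ``n - ddof``) is used.  Constant
    genes have no meaningful z-score; they are removed with a warning when
    ``drop_constant`` is true and rejected otherwise.
    """
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        if not drop_constant:
            raise ValidationError(
                f"{int(constant.sum())} constant gene(s), e.g. "
                f"{m.index[constant][:3].tolist()}"
            )
        logger.warning("removing %d constant gene(s)", int(constant.sum()))
        m = m.loc[~constant]
        values = values[~constant]
        sd = sd[~constant]
    mean = values.mean(axis=1)
    z = (values - mean[:, None]) / sd[:, None]
    return pd.DataFrame(z, index=m.index, columns=m.columns)


def bin_threshold(level: float = DEFAULT_BIN_LEVEL) -> float:
    """Standard-normal quantile bounding the central ``level`` interval."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return float(stats.norm.ppf((1 + level) / 2))


def bin_expression(z: pd.DataFrame, level: float = DEFAULT_BIN_LEVEL) -> pd.DataFrame:
    """Categorize standardized expression as LOW / TYPICAL / HIGH.

    A value is HIGH when it strictly exceeds the upper bound of the central
    ``level`` reference interval of the standard normal (+1.959964 for 0.95)
    and LOW when strictly below the lower bound; boundary values are TYPICAL.
    """
    thr = bin_threshold(level)
    values = z.to_numpy(dtype=float)
    codes = np.zeros(values.shape, dtype=np.int8)
    codes[values > thr] = HIGH
    codes[values < -thr] = LOW
    return pd.DataFrame(codes, index=z.index, columns=z.columns)


# ---------------------------------------------------------------------------
# Phenotype binarization
# ---------------------------------------------------------------------------

def binarize_survival(
    records: list[SurvivalRecord], horizon_months: float = DEFAULT_HORIZON_MONTHS
) -> pd.Series:
    """Label samples by event status within a clinical horizon.

    Events at or before the horizon are EVENT; samples followed event-free
    to the horizon (or with a later event) are NO_EVENT; samples censored
    event-free before the horizon are EXCLUDED — their status at the horizon
    is unknown, so they cannot inform feature scoring (they still enter
    time-to-event analyses with their full follow-up).
    """
    if horizon_months <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_months}")
    if not records:
        raise ValidationError("no clinical records")
    labels = {}
    for r in records:
        if r.event and r.time <= horizon_months:
            labels[r.sample_id] = EVENT
        elif r.time >= horizon_months or r.event:
            labels[r.sample_id] = NO_EVENT
        else:
            labels[r.sample_id] = EXCLUDED
    return pd.Series(labels, name="phenotype")


def binarize_response(
    records: list[ResponseRecord], adverse: str = "non_responder"
) -> pd.Series:
    """Label samples as responders (RCB 0/I) vs non-responders (RCB II/III).

    ``adverse`` selects which group carries the EVENT label; by default
    non-response is the adverse outcome.
    """
    if adverse not in ("non_responder", "responder"):
        raise ValueError(f"adverse must be responder/non_responder, got {adverse!r}")
    if not records:
        raise ValidationError("no clinical records")
    labels = {}
    for r in records:
        responder = r.rcb_class in RESPONDER_CLASSES
        adverse_sample = (not responder) if adverse == "non_responder" else responder
        labels[r.sample_id] = EVENT if adverse_sample else NO_EVENT
    return pd.Series(labels, name="phenotype")


def align_phenotype(m: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Restrict labels to the matrix samples, requiring full coverage."""
    missing = [s for s in m.columns if s not in labels.index]
    if missing:
        raise ValidationError(f"samples without phenotype label: {missing[:5]}")
    return labels.loc[list(m.columns)]


def random_split(sample_ids, fraction: float = 0.5, seed: int | None = None):
    """Randomly partition sample ids into two cohorts.

    Returns ``(a, b)`` with ``len(a) = round(fraction * n)``; reproducible
    under a fixed seed.
    """
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 samples to split")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    k = int(round(fraction * len(ids)))
    a = [ids[i] for i in sorted(perm[:k])]
    b = [ids[i] for i in sorted(perm[k:])]
    return a, b
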