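"""Cohort ingestion: file readers, sample join, and endpoint grouping.

Reads the expression / clinical / metadata triplet, restricts to the
samples present in both expression and clinical data (keeping only those
whose diagnostic TURBT pathology ID carries the literal ``SR-`` prefix),
and derives the grouped clinical endpoints used downstream:

* therapy response dichotomized to response (codes 0, 1 -> 0) versus
  disease (codes 2, 3 -> 1);
* histology reduced to five groups (neuroendocrine, urothelial, squamous,
  micropapillary, other) with the secondary histology as the main
  discriminator, resolved by the precedence
  neuroendocrine > squamous > micropapillary > other > urothelial;
* AJCC T-stage mapped to stage groups 0-IV and dichotomized at T2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError
from .simulate import CLINICAL_COLUMNS, T_STAGE_LABELS

RESPONSE_CODES = {0: "PR", 1: "CR", 2: "SD", 3: "PD"}
HISTOLOGY_CODES = {
    1: "urothelial", 2: "squamous", 3: "neuroendocrine", 4: "plasmacytoid",
    5: "adeno", 6: "micropapillary", 7: "papillary", 8: "other",
}
HISTOLOGY_GROUPS = ("neuroendocrine", "urothelial", "squamous",
                    "micropapillary", "other")

_STAGE_MAP = {
    "Ta": "0", "Tis": "0",
    "T1": "I",
    "T2": "II", "T2a": "II", "T2b": "II",
    "T3": "III", "T3a": "III", "T3b": "III", "T4a": "III",
    "T4": "III",
    "T4b": "IV",
}
_LT_T2 = {"Ta", "Tis", "T1"}


@dataclass
class Cohort:
    """Expression matrix joined with clinical endpoints and derived groups."""

    expression: pd.DataFrame   # genes x samples
    clinical: pd.DataFrame     # indexed by sample_id; includes derived columns

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    def endpoint(self, name: str) -> pd.Series:
        """Binary endpoint labels: ``response`` or ``progression``."""
        if name == "response":
            return self.clinical["response_binary"]
        if name == "progression":
            return self.clinical["progression_event"].astype(int)
        raise DomainError(f"unknown endpoint {name!r}; use 'response' or 'progression'")

    def survival_data(self) -> pd.DataFrame:
        """Time/event pairs for survival analysis.

        Samples with a missing time-to-event fall back to the follow-up
        time as a censoring time; samples missing both are excluded from
        survival analyses (but retained for classification).
        """
        clin = self.clinical
        time = clin["time_to_event_days"].astype(float).copy()
        event = clin["progression_event"].astype(float).copy()
        missing_t = time.isna()
        time[missing_t] = clin.loc[missing_t, "followup_days"].astype(float)
        event[missing_t] = 0
        keep = time.notna()
        return pd.DataFrame({"time": time[keep], "event": event[keep].astype(int)})


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column ``gene_id``)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed expression file {path}: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise FormatError(f"expression file {path} must start with a 'gene_id' column")
    df = df.set_index("gene_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate gene IDs in {path}: {dup}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise FormatError(f"duplicate sample columns in {path}: {dup_cols}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            raise FormatError(
                f"non-numeric or missing value in column {col!r}, rows {bad[:5]}"
            )
        df[col] = numeric.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise FormatError(f"non-finite expression value in {path}")
    return df


def parse_secondary(value: object) -> frozenset[int]:
    """Parse a '+'-separated secondary-histology code list ('' = missing)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    codes = set()
    for part in text.split("+"):
        code = int(part)
        if code not in HISTOLOGY_CODES:
            raise DomainError(f"secondary histology code {code} outside 1..8")
        codes.add(code)
    return frozenset(codes)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample clinical CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "turbt_path": str,
                                  "secondary_histology": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical file {path} missing columns {missing}")
    df = df.set_index("sample_id")
    bad_codes = sorted(set(df["therapy_response_code"]) - set(RESPONSE_CODES))
    if bad_codes:
        raise DomainError(f"unknown therapy response codes {bad_codes}")
    bad_stage = sorted(set(df["t_stage"]) - set(T_STAGE_LABELS))
    if bad_stage:
        raise DomainError(f"unknown T-stage labels {bad_stage}")
    df["secondary_histology"] = df["secondary_histology"].map(parse_secondary)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the external-ID to expression-column (CEL file) join table."""
    df = pd.read_csv(path, dtype=str)
    for col in ("external_id", "cel_file"):
        if col not in df.columns:
            raise FormatError(f"metadata file {path} missing column {col!r}")
    if df["cel_file"].duplicated().any():
        dup = df.loc[df["cel_file"].duplicated(), "cel_file"].tolist()
        raise FormatError(f"metadata maps multiple external IDs to columns {dup}")
    return df


def dichotomize_response(code: int) -> int:
    """Therapy-response codes to binary endpoint: PR/CR -> 0, SD/PD -> 1."""
    code = int(code)
    if code in (0, 1):
        return 0
    if code in (2, 3):
        return 1
    raise DomainError(f"unknown therapy response code {code}")


def group_histology(predominant: str, secondary: frozenset[int] | set[int]) -> str:
    """Reduce predominant + secondary histology to one of five groups.

    Secondary histology is the main discriminator; combinations resolve by
    the precedence neuroendocrine > squamous > micropapillary > other >
    urothelial.  An empty secondary set means only the predominant
    histology was recorded.
    """
    if predominant not in ("urothelial", "neuroendocrine"):
        raise DomainError(f"unknown predominant histology {predominant!r}")
    secondary = frozenset(int(c) for c in secondary)
    bad = sorted(secondary - set(HISTOLOGY_CODES))
    if bad:
        raise DomainError(f"secondary histology codes {bad} outside 1..8")
    if predominant == "neuroendocrine" or 3 in secondary:
        return "neuroendocrine"
    if 2 in secondary:
        return "squamous"
    if 6 in secondary:
        return "micropapillary"
    if secondary & {4, 5, 7, 8}:
        return "other"
    return "urothelial"


def map_stage(t_stage: str) -> str:
    """AJCC T-stage label to stage group 0/I/II/III/IV."""
    try:
        return _STAGE_MAP[t_stage]
    except KeyError:
        raise DomainError(f"unknown T-stage label {t_stage!r}") from None


def dichotomize_stage(t_stage: str) -> str:
    """T-stage dichotomy at muscle invasion: ``<T2`` vs ``>=T2``."""
    if t_stage not in _STAGE_MAP:
        raise DomainError(f"unknown T-stage label {t_stage!r}")
    return "<T2" if t_stage in _LT_T2 else ">=T2"


def join_cohort(expression: pd.DataFrame, clinical: pd.DataFrame,
                metadata: pd.DataFrame) -> Cohort:
    """Join expression and clinical data into a :class:`Cohort`.

    Expression columns are renamed to external IDs via the metadata map,
    the sample set is restricted to the intersection with the clinical
    table, samples whose ``turbt_path`` lacks the case-sensitive ``SR-``
    prefix are excluded, and the derived endpoint columns are populated.
    """
    cel_to_ext = dict(zip(metadata["cel_file"], metadata["external_id"]))
    expr = expression.rename(columns=cel_to_ext)
    common = [sid for sid in expr.columns if sid in clinical.index]
    keep = [sid for sid in common
            if str(clinical.loc[sid, "turbt_path"]).startswith("SR-")]
    if not keep:
        raise DomainError("empty intersection of expression and clinical samples")
    expr = expr[keep]
    clin = clinical.loc[keep].copy()
    clin["response_binary"] = clin["therapy_response_code"].map(dichotomize_response)
    clin["secondary_histology"] = clin["secondary_histology"].map(
        lambda s: s if isinstance(s, frozenset) else parse_secondary(s)
    )
    clin["histology_group"] = [
        group_histology(p, s)
        for p, s in zip(clin["predominant_histology"], clin["secondary_histology"])
    ]
    clin["stage_group"] = clin["t_stage"].map(map_stage)
    clin["t2_binary"] = clin["t_stage"].map(dichotomize_stage)
    return Cohort(expression=expr, clinical=clin)


def load_cohort(expression_path: str | Path, clinical_path: str | Path,
                metadata_path: str | Path) -> Cohort:
    """Read the three files and join them."""
    return join_cohort(
        read_expression(expression_path),
        read_clinical(clinical_path),
        read_metadata(metadata_path),
    )
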