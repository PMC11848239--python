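"""Reading, validation and pivoting of the tidy isotope and PLFA tables.

On-disk format is long/tidy CSV (UTF-8, "." decimal, header row):

amino-acid table columns
    sample_id, role, species, ecological_group, litter_treatment,
    replicate, amino_acid, value
PLFA table columns
    sample_id, substrate, fatty_acid, nmol_per_g

Missing amino-acid values are empty cells, never sentinel numbers:
real CSIA datasets have genuine gaps (e.g. amino acids too dilute for
a reliable delta15N measurement). ``ω`` in fatty-acid names is written
as ``w`` so files stay ASCII; both spellings are accepted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .plfa import PLFATable, normalize_fatty_acid

#: Canonical 3-letter codes of the amino acids measured by GC-C-IRMS.
AMINO_ACIDS = ("Ala", "Asp", "Glu", "Gly", "Ile", "Leu", "Met", "Phe", "Thr", "Val")

#: Essential amino acids — inherited from the basal resource, hence the
#: fingerprinting substrate.
ESSENTIAL_AAS = ("Ile", "Leu", "Met", "Phe", "Thr", "Val")

#: The five-eAA panel used for fingerprinting (Met dropped: unreliable
#: chromatography in practice, Lys not measured).
FINGERPRINT_PANEL = ("Ile", "Leu", "Phe", "Thr", "Val")

ROLES = ("consumer", "source", "litter", "soil")
ECO_GROUPS = ("epigeic", "anecic", "endogeic", "na")
LITTER_TREATMENTS = ("wheat_straw", "horse_manure", "legume", "rape", "initial", "na")
ELEMENTS = ("C13", "N15")

META_COLUMNS = (
    "sample_id",
    "role",
    "species",
    "ecological_group",
    "litter_treatment",
    "replicate",
)
AA_LONG_COLUMNS = META_COLUMNS + ("amino_acid", "value")
PLFA_LONG_COLUMNS = ("sample_id", "substrate", "fatty_acid", "nmol_per_g")

_AA_LOOKUP = {a.lower(): a for a in AMINO_ACIDS}


def normalize_amino_acid(code: str) -> str:
    """Map a case-insensitive 3-letter code to its canonical spelling."""
    key = str(code).strip().lower()
    if key not in _AA_LOOKUP:
        raise SchemaError(f"unknown amino-acid code {code!r}; expected one of {AMINO_ACIDS}")
    return _AA_LOOKUP[key]


@dataclass
class AAMatrix:
    """Per-sample amino-acid isotope values for one element.

    Attributes
    ----------
    values : DataFrame
        Samples x amino acids, per-mil values; NaN marks a missing cell.
    meta : DataFrame
        One row per sample (index = sample_id) with role, species,
        ecological_group, litter_treatment, replicate.
    element : str
        ``"C13"`` or ``"N15"``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    element: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise SchemaError(f"element must be one of {ELEMENTS}, got {self.element!r}")
        if not self.values.index.equals(self.meta.index):
            raise SchemaError("values and meta must be indexed by the same sample_ids")
        _validate_meta(self.meta)
        finite = self.values.to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise ValidationError("isotope values must be finite where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def amino_acids(self) -> list[str]:
        return list(self.values.columns)

    def is_essential(self, amino_acid: str) -> bool:
        return amino_acid in ESSENTIAL_AAS

    def subset(self, panel: tuple[str, ...]) -> "AAMatrix":
        """Restrict to the given amino-acid panel (columns must exist)."""
        missing = [a for a in panel if a not in self.values.columns]
        if missing:
            raise SchemaError(f"amino acids not in matrix: {missing}")
        return AAMatrix(self.values[list(panel)].copy(), self.meta.copy(), self.element)

    def select(self, **criteria: object) -> "AAMatrix":
        """Filter samples by metadata equality, e.g. ``select(role='consumer')``."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in criteria.items():
            if col not in self.meta.columns:
                raise SchemaError(f"unknown metadata column {col!r}")
            mask &= self.meta[col] == val
        return AAMatrix(self.values.loc[mask].copy(), self.meta.loc[mask].copy(), self.element)


def _validate_meta(meta: pd.DataFrame) -> None:
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample_ids: {dups}")
    bad_role = set(meta["role"]) - set(ROLES)
    if bad_role:
        raise SchemaError(f"unknown roles {sorted(bad_role)}; expected {ROLES}")
    bad_grp = set(meta["ecological_group"]) - set(ECO_GROUPS)
    if bad_grp:
        raise SchemaError(f"unknown ecological groups {sorted(bad_grp)}")
    bad_trt = set(meta["litter_treatment"]) - set(LITTER_TREATMENTS)
    if bad_trt:
        raise SchemaError(f"unknown litter treatments {sorted(bad_trt)}")
    consumers = meta[meta["role"] == "consumer"]
    nameless = consumers.index[(consumers["species"] == "") | consumers["species"].isna()]
    if len(nameless):
        raise SchemaError(f"consumer samples need a species: {list(nameless)}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc


def read_aa_table(path, element: str, column_map: dict[str, str] | None = None) -> AAMatrix:
    """Read a long-format amino-acid isotope table into a wide :class:`AAMatrix`.

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``sample_id, role, species, ecological_group,
        litter_treatment, replicate, amino_acid, value``.
    element : str
        ``"C13"`` or ``"N15"`` — which isotope system the values are.
    column_map : dict, optional
        Adapter mapping external column names onto this schema (for
        third-party exports such as the deposited study tables); applied
        as a rename before validation.
    """
    df = _read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in AA_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"amino-acid table missing columns {missing}")

    df = df.copy()
    df["amino_acid"] = [
        _normalize_aa_row(code, i) for i, code in enumerate(df["amino_acid"], start=2)
    ]
    values = np.empty(len(df), dtype=float)
    for pos, (line_no, raw) in enumerate(zip(range(2, len(df) + 2), df["value"])):
        raw = raw.strip()
        if raw == "":
            values[pos] = np.nan
            continue
        try:
            values[pos] = float(raw)
        except ValueError:
            raise ParseError(f"non-numeric value {raw!r} on line {line_no}") from None
    df["value"] = values

    dup = df.duplicated(subset=["sample_id", "amino_acid"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "amino_acid"]].drop_duplicates()
        raise SchemaError(
            "duplicate (sample_id, amino_acid) pairs: "
            + ", ".join(f"({r.sample_id}, {r.amino_acid})" for r in pairs.itertuples())
        )

    meta = df[list(META_COLUMNS)].drop_duplicates(subset="sample_id").set_index("sample_id")
    incons = df.groupby("sample_id")[list(META_COLUMNS[1:])].nunique()
    if (incons > 1).any().any():
        bad = incons.index[(incons > 1).any(axis=1)].tolist()
        raise SchemaError(f"inconsistent metadata for samples: {bad}")
    meta["replicate"] = [_parse_replicate(r) for r in meta["replicate"]]

    wide = df.pivot(index="sample_id", columns="amino_acid", values="value")
    order = [a for a in AMINO_ACIDS if a in wide.columns]
    wide = wide[order].loc[meta.index]
    wide.columns.name = None
    wide.index.name = "sample_id"
    return AAMatrix(wide, meta, element)


def _normalize_aa_row(code: str, line_no: int) -> str:
    try:
        return normalize_amino_acid(code)
    except SchemaError:
        raise SchemaError(
            f"unknown amino-acid code {code!r} on line {line_no}"
        ) from None


def _parse_replicate(raw: str) -> object:
    raw = str(raw).strip()
    if raw in ("", "na", "NA"):
        return pd.NA
    try:
        rep = int(raw)
    except ValueError:
        raise ParseError(f"replicate must be a positive integer, got {raw!r}") from None
    if rep < 1:
        raise ValidationError(f"replicate must be positive, got {rep}")
    return rep


def write_aa_table(matrix: AAMatrix, path) -> None:
    """Serialize an :class:`AAMatrix` to long CSV at full float precision.

    ``read_aa_table(write_aa_table(M)) == M`` bit-exactly: values are
    written with ``repr``-level precision and missing cells as empty.
    """
    rows = []
    for sid in matrix.sample_ids:
        m = matrix.meta.loc[sid]
        rep = "" if pd.isna(m["replicate"]) else str(int(m["replicate"]))
        for aa in matrix.amino_acids:
            v = matrix.values.at[sid, aa]
            rows.append(
                {
                    "sample_id": sid,
                    "role": m["role"],
                    "species": m["species"],
                    "ecological_group": m["ecological_group"],
                    "litter_treatment": m["litter_treatment"],
                    "replicate": rep,
                    "amino_acid": aa,
                    "value": "" if pd.isna(v) else repr(float(v)),
                }
            )
    pd.DataFrame(rows, columns=list(AA_LONG_COLUMNS)).to_csv(path, index=False)


def read_plfa_table(path, column_map: dict[str, str] | None = None) -> PLFATable:
    """Read a long-format PLFA abundance table.

    Fatty-acid names are normalized (``w``/``ω`` interchangeable,
    cis/trans suffixes dropped for the monounsaturated markers);
    negative abundances are rejected.
    """
    df = _read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PLFA_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"PLFA table missing columns {missing}")

    bad_sub = set(df["substrate"]) - {"litter", "soil"}
    if bad_sub:
        raise SchemaError(f"unknown substrate values {sorted(bad_sub)}; expected litter/soil")

    out = df[list(PLFA_LONG_COLUMNS)].copy()
    out["fatty_acid"] = [normalize_fatty_acid(f) for f in out["fatty_acid"]]
    vals = np.empty(len(out), dtype=float)
    for pos, (line_no, raw) in enumerate(zip(range(2, len(out) + 2), out["nmol_per_g"])):
        try:
            vals[pos] = float(str(raw).strip())
        except ValueError:
            raise ParseError(f"non-numeric abundance {raw!r} on line {line_no}") from None
    if (vals < 0).any() or not np.isfinite(vals).all():
        bad = out.loc[(vals < 0) | ~np.isfinite(vals), "fatty_acid"].tolist()
        raise ValidationError(f"PLFA abundances must be finite and non-negative: {bad}")
    out["nmol_per_g"] = vals
    return PLFATable(out)


def write_plfa_table(table: PLFATable, path) -> None:
    """Serialize a :class:`PLFATable` to long CSV at full precision."""
    df = table.rows.copy()
    df["nmol_per_g"] = [repr(float(v)) for v in df["nmol_per_g"]]
    df.to_csv(path, index=False)


def load_column_map(path) -> dict[str, str]:
    """Load a column-name adapter config (YAML mapping external -> schema)."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError("column map must be a YAML mapping of column names")
    return {str(k): str(v) for k, v in mapping.items()}
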