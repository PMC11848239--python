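"""PLFA biomarker bookkeeping.

Phospholipid fatty acids are membrane lipids whose structures mark
microbial groups: 18:2w6,9 for fungi, the branched saturated acids
i15:0/a15:0/i16:0/i17:0 for Gram-positive bacteria, and the cyclopropyl
and monounsaturated acids cy17:0/cy19:0/16:1w7/18:1w7 for Gram-negative
bacteria. This module filters acids by mole percent, sums marker
groups, and forms fungal-to-bacterial ratios per sample.

Order of operations is fixed: the mole-percent filter runs first and
marker group sums are taken on the filtered table, while total
abundance is reported from the unfiltered table (all detected acids).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

_ISOMER_SUFFIX = re.compile(r"^(.*w\d+(?:,\d+)*)[ct]$")


def normalize_fatty_acid(name: str) -> str:
    """Canonicalize a fatty-acid name.

    ``ω`` becomes ``w`` (ASCII-safe files) and cis/trans suffixes on
    monounsaturated acids are dropped (``16:1w7c`` -> ``16:1w7``), so
    the nomenclature dialects of different labs map to one spelling.
    """
    s = str(name).strip().replace("ω", "w").replace(" ", "")
    m = _ISOMER_SUFFIX.match(s)
    if m:
        s = m.group(1)
    return s


@dataclass(frozen=True)
class MarkerSet:
    """Marker fatty acids per microbial group; the sets must be disjoint."""

    fungal: frozenset = frozenset({"18:2w6,9"})
    gram_pos: frozenset = frozenset({"i15:0", "a15:0", "i16:0", "i17:0"})
    gram_neg: frozenset = frozenset({"cy17:0", "cy19:0", "16:1w7", "18:1w7"})

    def __post_init__(self) -> None:
        groups = [self.fungal, self.gram_pos, self.gram_neg]
        if sum(len(g) for g in groups) != len(frozenset().union(*groups)):
            raise ValidationError("marker groups must be disjoint")

    @property
    def bacterial(self) -> frozenset:
        return self.gram_pos | self.gram_neg


DEFAULT_MARKERS = MarkerSet()


@dataclass
class PLFATable:
    """Long table of (sample_id, substrate, fatty_acid, nmol_per_g) rows."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "substrate", "fatty_acid", "nmol_per_g"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"PLFATable missing columns {sorted(missing)}")
        vals = self.rows["nmol_per_g"].to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValidationError("PLFA abundances must be finite and non-negative")
        dup = self.rows.duplicated(subset=["sample_id", "fatty_acid"])
        if dup.any():
            pairs = self.rows.loc[dup, ["sample_id", "fatty_acid"]].drop_duplicates()
            raise ValidationError(
                "duplicate (sample, fatty acid) rows: "
                + ", ".join(f"({r.sample_id}, {r.fatty_acid})" for r in pairs.itertuples())
            )
        self.rows = self.rows.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["sample_id"]))


def mole_percent_filter(table: PLFATable, threshold_pct: float = 0.2) -> PLFATable:
    """Drop, per sample, acids at or below ``threshold_pct`` mole percent.

    The inequality is strict — an acid is retained only when
    100 * abundance / sample_total is *higher than* the threshold, so an
    acid at exactly 0.2% is dropped. Samples with zero total abundance
    are excluded with a warning.
    """
    rows = table.rows
    kept = []
    for sid, grp in rows.groupby("sample_id", sort=False):
        total = math.fsum(grp["nmol_per_g"])
        if total <= 0:
            warnings.warn(f"sample {sid!r} has zero total PLFA; excluded", stacklevel=2)
            continue
        pct = 100.0 * grp["nmol_per_g"].to_numpy(dtype=float) / total
        kept.append(grp.loc[pct > threshold_pct])
    if not kept:
        out = rows.iloc[0:0]
    else:
        out = pd.concat(kept, axis=0)
    return PLFATable(out.reset_index(drop=True))


def summarize_markers(
    table: PLFATable,
    markers: MarkerSet = DEFAULT_MARKERS,
    totals_table: PLFATable | None = None,
) -> pd.DataFrame:
    """Per-sample marker-group sums and the fungal:bacterial ratio.

    Parameters
    ----------
    table : PLFATable
        The (typically mole-percent filtered) table the group sums are
        taken from. Missing marker acids contribute 0.
    markers : MarkerSet
        Which acids count toward each group.
    totals_table : PLFATable, optional
        Table used for ``total_abund``; pass the unfiltered table to
        report absolute abundance over all detected acids while group
        sums respect the filter. Defaults to ``table`` itself.

    Returns
    -------
    DataFrame indexed by sample_id with columns fungal_abund,
    gram_pos_abund, gram_neg_abund, bacterial_abund, total_abund,
    fb_ratio, fb_defined, n_acids_retained. ``fb_ratio`` is NaN with
    ``fb_defined=False`` when the bacterial sum is zero.
    """
    totals_src = (totals_table or table).rows
    out = []
    for sid, grp in table.rows.groupby("sample_id", sort=False):
        acids = grp["fatty_acid"]
        ab = grp["nmol_per_g"].to_numpy(dtype=float)
        fungal = math.fsum(ab[acids.isin(markers.fungal)])
        gpos = math.fsum(ab[acids.isin(markers.gram_pos)])
        gneg = math.fsum(ab[acids.isin(markers.gram_neg)])
        bacterial = gpos + gneg
        tot_rows = totals_src.loc[totals_src["sample_id"] == sid, "nmol_per_g"]
        out.append(
            {
                "sample_id": sid,
                "fungal_abund": fungal,
                "gram_pos_abund": gpos,
                "gram_neg_abund": gneg,
                "bacterial_abund": bacterial,
                "total_abund": math.fsum(tot_rows),
                "fb_ratio": fungal / bacterial if bacterial > 0 else float("nan"),
                "fb_defined": bacterial > 0,
                "n_acids_retained": len(grp),
            }
        )
    return pd.DataFrame(out).set_index("sample_id")


def plfa_summary(
    table: PLFATable,
    threshold_pct: float = 0.2,
    markers: MarkerSet = DEFAULT_MARKERS,
) -> pd.DataFrame:
    """Filter then summarize: the standard analysis path.

    Total abundance is computed from all detected acids (before the
    filter); marker group sums from the filtered table.
    """
    filtered = mole_percent_filter(table, threshold_pct)
    return summarize_markers(filtered, markers, totals_table=table)
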