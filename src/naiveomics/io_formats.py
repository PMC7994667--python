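"""Tabular I/O for the pipeline: expression matrices, phosphosite tables,
sample designs, and GMT gene-set collections.

Conventions follow MaxQuant output where applicable: 1-based residue
positions, odd-length sequence windows centered on the phosphosite, and
flag columns ("Reverse", "Potential contaminant", "Only identified by
site") marked with "+". Missing values are written as "NA" (empty fields
are also accepted on read) and held as NaN internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed treatment tokens.  ``SL`` is the serum/LIF reference state at
#: timepoint 0; ``2i`` is Mek1/2+Gsk3 inhibition; ``Cdk8i`` is Cdk8/19
#: inhibition.
TREATMENTS = ("SL", "2i", "Cdk8i")

DESIGN_COLUMNS = ("sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate")

#: MaxQuant proteinGroups flag columns recognised by the protein_groups dialect,
#: mapped to the internal row-attribute name.
MAXQUANT_FLAGS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_identified_by_site",
}

MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A file violated the expected dialect or a table-level invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata: cell line, treatment, timepoint, plex and replicate.

    The underlying table is a DataFrame with one row per sample.  Invariants
    enforced at construction: unique sample ids, known treatment tokens,
    non-negative timepoints, and every non-reference sample having an S/L
    reference channel in the same plex.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"design is missing required column(s): {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicated sample_id(s): {dup}")
        bad = sorted(set(t["treatment"]) - set(TREATMENTS))
        if bad:
            raise FormatError(
                f"unknown treatment token(s) {bad}; allowed values are {list(TREATMENTS)}"
            )
        if (t["timepoint"].astype(float) < 0).any():
            raise FormatError("timepoints must be non-negative")
        if (t["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be >= 1")
        sl_plexes = set(t.loc[t["treatment"] == "SL", "plex"])
        orphan = t.loc[(t["treatment"] != "SL") & (~t["plex"].isin(sl_plexes))]
        if len(orphan):
            raise FormatError(
                "every treated sample needs a same-plex S/L reference; plex(es) "
                f"without one: {sorted(set(orphan['plex']))}"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        wanted = list(sample_ids)
        sub = self.table.set_index("sample_id").loc[wanted].reset_index()
        return SampleDesign(sub)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Features x samples grid of log2 abundances or log2 ratios.

    ``values`` rows are feature ids (unique, order preserved), columns are
    sample ids matching ``design``.  ``layer`` is one of protein / phospho /
    metabolite / mrna.  ``row_attrs`` optionally carries per-feature flags
    (e.g. MaxQuant reverse/contaminant markers).
    """

    values: pd.DataFrame
    design: SampleDesign
    layer: str = "protein"
    row_attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.sample_ids:
            raise FormatError(
                "matrix columns must equal the design sample_ids, in order"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicated feature id(s): {dup}")
        if self.row_attrs is not None and not self.row_attrs.index.equals(self.values.index):
            raise FormatError("row_attrs index must equal the feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def copy_with(self, values: pd.DataFrame, layer: str | None = None) -> "ExpressionMatrix":
        attrs = None
        if self.row_attrs is not None:
            attrs = self.row_attrs.loc[values.index]
        return ExpressionMatrix(values, self.design.subset(values.columns),
                                layer or self.layer, attrs)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PhosphoSiteTable:
    """One row per (phosphosite, peptidoform multiplicity).

    ``table`` columns: protein, position (1-based), residue, localization_prob,
    multiplicity, window (odd-length, centered on the site), plus one column
    per sample in ``design``.  The row index is a unique site id.
    """

    table: pd.DataFrame
    design: SampleDesign

    SITE_COLUMNS = ("protein", "position", "residue", "localization_prob",
                    "multiplicity", "window")

    def __post_init__(self) -> None:
        missing = [c for c in self.SITE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"phospho table missing column(s): {missing}")
        for win, res in zip(self.table["window"], self.table["residue"]):
            _check_window(win, res)
        probs = self.table["localization_prob"].astype(float)
        if ((probs < 0) | (probs > 1)).any():
            raise FormatError("localization probabilities must lie in [0, 1]")
        if self.table.index.duplicated().any():
            raise FormatError("duplicated phosphosite row ids")

    @property
    def sample_columns(self) -> list[str]:
        return self.design.sample_ids

    def values_matrix(self, layer: str = "phospho") -> ExpressionMatrix:
        """Per-sample values as an ExpressionMatrix keyed by site id."""
        vals = self.table[self.sample_columns].astype(float)
        return ExpressionMatrix(vals, self.design, layer)


def _check_window(window: str, residue: str) -> None:
    if len(window) % 2 != 1:
        raise FormatError(f"sequence window {window!r} must have odd length")
    center = window[len(window) // 2]
    if center not in "STY":
        raise FormatError(
            f"window center residue {center!r} is not a phosphorylatable S/T/Y"
        )
    if residue != center:
        raise FormatError(
            f"row residue {residue!r} disagrees with window center {center!r}"
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_any_sep(path: str | Path) -> pd.DataFrame:
    """Read a header-carrying table, tab- or comma-separated."""
    path = Path(path)
    sep = "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        sep = ","
    return pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN, ""],
                       keep_default_na=True, float_precision="round_trip")


def read_design(path: str | Path) -> SampleDesign:
    """Read and validate a sample-design table (TSV/CSV)."""
    df = _read_any_sep(path)
    return SampleDesign(df)


def read_expression_table(path: str | Path, dialect: str = "generic",
                          design: SampleDesign | None = None) -> ExpressionMatrix:
    """Read a features x samples abundance table.

    The first column holds feature ids; remaining columns must match the
    design's sample ids (extra non-sample columns are MaxQuant flags in the
    ``protein_groups`` dialect, otherwise ignored with a warning).  Rows
    flagged reverse / contaminant / only-identified-by-site are retained here
    with boolean row attributes; filtering is a downstream policy decision.
    """
    if design is None:
        raise FormatError("a SampleDesign is required to map sample columns")
    if dialect not in ("protein_groups", "generic"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = _read_any_sep(path)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise FormatError(f"duplicated feature id(s): {dup}")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df.index.name = "feature"

    sample_ids = design.sample_ids
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise FormatError(f"design sample column(s) absent from table: {missing}")

    attrs = None
    extra = [c for c in df.columns if c not in sample_ids]
    if dialect == "protein_groups":
        flag_cols = [c for c in extra if c in MAXQUANT_FLAGS]
        attrs = pd.DataFrame(
            {MAXQUANT_FLAGS[c]: df[c].astype(str).str.strip().eq("+") for c in flag_cols},
            index=df.index,
        )
        extra = [c for c in extra if c not in MAXQUANT_FLAGS]
    orphan = [c for c in extra if c not in sample_ids]
    if dialect == "generic" and orphan:
        # generic dialect: any unexplained column is an error naming the orphan
        raise FormatError(f"column(s) {orphan} not present in the sample design")
    if orphan:
        logger.warning("ignoring %d unrecognised column(s): %s", len(orphan), orphan)

    values = df[sample_ids].astype(float)
    return ExpressionMatrix(values, design, layer="protein", row_attrs=attrs)


PHOSPHO_COLUMN_MAP = {
    "Protein": "protein",
    "Position": "position",
    "Amino acid": "residue",
    "Localization prob": "localization_prob",
    "Sequence window": "window",
    "Multiplicity": "multiplicity",
}


def read_phospho_table(path: str | Path, design: SampleDesign) -> PhosphoSiteTable:
    """Read a phosphosite table (MaxQuant Phospho(STY)Sites-style columns)."""
    df = _read_any_sep(path)
    missing = [c for c in PHOSPHO_COLUMN_MAP if c not in df.columns]
    if missing:
        raise FormatError(f"phospho table missing column(s): {missing}")
    df = df.rename(columns=PHOSPHO_COLUMN_MAP)
    missing_samples = [s for s in design.sample_ids if s not in df.columns]
    if missing_samples:
        raise FormatError(f"design sample column(s) absent from table: {missing_samples}")
    df["position"] = df["position"].astype(int)
    df["multiplicity"] = df["multiplicity"].astype(int)
    df.index = pd.Index(
        [f"{p}_{r}{pos}_M{m}" for p, r, pos, m in
         zip(df["protein"], df["residue"], df["position"], df["multiplicity"])],
        name="site_id",
    )
    cols = list(PhosphoSiteTable.SITE_COLUMNS) + design.sample_ids
    return PhosphoSiteTable(df[cols], design)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, fields name, description, members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    if not sets:
        raise FormatError("GMT file contains no gene sets")
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def _as_frame(result: object) -> pd.DataFrame:
    """Coerce any pipeline result into a flat DataFrame for writing."""
    from dataclasses import asdict, is_dataclass

    if isinstance(result, ExpressionMatrix):
        return result.values.reset_index()
    if isinstance(result, PhosphoSiteTable):
        return result.table.reset_index()
    if isinstance(result, SampleDesign):
        return result.table
    if isinstance(result, pd.DataFrame):
        out = result
        if out.index.name is not None or not isinstance(out.index, pd.RangeIndex):
            out = out.reset_index()
        return out
    if isinstance(result, pd.Series):
        return result.rename_axis("key").reset_index()
    if is_dataclass(result) and not isinstance(result, type):
        flat = {k: v for k, v in asdict(result).items()
                if np.isscalar(v) or v is None}
        return pd.DataFrame([flat])
    if isinstance(result, Mapping):
        return pd.DataFrame([dict(result)])
    raise FormatError(f"cannot serialise object of type {type(result).__name__}")


def write_table(result: object, path: str | Path) -> None:
    """Write any tabular result as TSV; write-then-read is value-stable.

    Floats are written with 17 significant digits so that a round trip
    reproduces the original values to better than 1e-12.
    """
    frame = _as_frame(result)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
                 float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV reader matching :func:`write_table` output."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN, ""],
                       float_precision="round_trip")
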