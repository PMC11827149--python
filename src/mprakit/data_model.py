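"""Core tables and wide-frame construction for barcode-level MPRA analysis.

The canonical interchange format is a long, tab-separated barcode count
table with one record per (replicate, barcode): columns ``replicate``,
``barcode``, ``oligo``, ``dna_count``, ``rna_count``.  A secondary dialect
accepts one count file per replicate plus a barcode-to-oligo assignment
file, matching common count-pipeline layouts.

Modeling consumes *wide* frames in which every barcode slot is a separate
sample column.  Columns are grouped by technical replicate (the blocking
vector) and, in variant mode, carry a 0/1 reference/alternative allele
indicator.  Slots unused by a given row (sequences have varying numbers of
barcodes) are marked missing and later receive zero weight — counts are
never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["replicate", "barcode", "oligo", "dna_count", "rna_count"]

__all__ = [
    "BarcodeCountTable",
    "VariantMap",
    "LabelTable",
    "WideCountFrame",
    "FormatError",
    "ValidationError",
    "read_count_table",
    "read_count_table_split",
    "read_variant_map",
    "read_label_table",
    "create_variant_frame",
    "create_element_frame",
    "aggregate_frame",
    "write_results",
]


class FormatError(ValueError):
    """Malformed input file (wrong header / wrong dialect)."""


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


# ----------------------------------------------------------------------
# long tables
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BarcodeCountTable:
    """Long-format per-barcode DNA/RNA counts with oligo assignment.

    Invariants: (replicate, barcode) pairs are unique, counts are
    non-negative integers, and every barcode maps to exactly one oligo
    across all replicates.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "BarcodeCountTable":
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"count table missing columns: {missing}")
        df = df[COUNT_COLUMNS].reset_index(drop=True).copy()
        df["replicate"] = df["replicate"].astype(str)
        df["barcode"] = df["barcode"].astype(str)
        df["oligo"] = df["oligo"].astype(str)
        for col in ("dna_count", "rna_count"):
            vals = df[col]
            arr = pd.to_numeric(vals, errors="coerce")
            if arr.isna().any():
                raise ValidationError(f"non-numeric values in {col}")
            if (arr < 0).any():
                raise ValidationError(f"negative values in {col}")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError(f"non-integer values in {col}")
            df[col] = arr.astype(np.int64)
        if validate:
            if df.duplicated(["replicate", "barcode"]).any():
                raise ValidationError("duplicate (replicate, barcode) records")
            per_bc = df[["barcode", "oligo"]].drop_duplicates()
            dup = per_bc["barcode"].duplicated()
            if dup.any():
                bad = per_bc.loc[dup, "barcode"].head(5).tolist()
                raise ValidationError(f"barcodes assigned to multiple oligos, e.g. {bad}")
        return cls(df)

    # -- convenience views -------------------------------------------------
    @property
    def replicates(self) -> list[str]:
        return sorted(self.df["replicate"].unique())

    @property
    def oligos(self) -> list[str]:
        return sorted(self.df["oligo"].unique())

    @property
    def n_barcodes(self) -> int:
        return self.df["barcode"].nunique()

    def barcode_multiplicity(self) -> pd.Series:
        """Distinct barcodes per oligo."""
        return self.df.groupby("oligo")["barcode"].nunique()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class VariantMap:
    """variant_id -> (reference oligo, alternative oligo)."""

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariantMap":
        cols = ["variant_id", "ref_oligo", "alt_oligo"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"variant map missing columns: {missing}")
        df = df[cols].astype(str).reset_index(drop=True)
        if df["variant_id"].duplicated().any():
            raise ValidationError("duplicate variant_id in variant map")
        if (df["ref_oligo"] == df["alt_oligo"]).any():
            raise ValidationError("ref_oligo equals alt_oligo for some variant")
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class LabelTable:
    """oligo -> free-text group label (one label per oligo)."""

    series: pd.Series  # index oligo, values label

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelTable":
        if not {"oligo", "label"}.issubset(df.columns):
            raise FormatError("label table needs columns oligo, label")
        df = df[["oligo", "label"]].astype(str)
        if df["oligo"].duplicated().any():
            raise ValidationError("multiple labels for one oligo")
        return cls(df.set_index("oligo")["label"])


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------
def read_count_table(path) -> BarcodeCountTable:
    """Read the canonical long TSV (replicate, barcode, oligo, dna_count, rna_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return BarcodeCountTable.from_frame(df)


def read_count_table_split(replicate_files: dict, assignment_path) -> BarcodeCountTable:
    """Read per-replicate count files plus a barcode→oligo assignment file.

    Each count file is a TSV with columns ``barcode``, ``dna_count``,
    ``rna_count``; the assignment file has columns ``barcode``, ``oligo``.
    Barcodes without an oligo assignment are dropped (count logged).
    """
    assign = pd.read_csv(assignment_path, sep="\t", dtype=str)
    if not {"barcode", "oligo"}.issubset(assign.columns):
        raise FormatError("assignment file needs columns barcode, oligo")
    assign = assign[["barcode", "oligo"]]
    parts = []
    for rep, path in sorted(replicate_files.items()):
        sub = pd.read_csv(path, sep="\t", dtype=str)
        if not {"barcode", "dna_count", "rna_count"}.issubset(sub.columns):
            raise FormatError(f"count file for replicate {rep} has wrong header")
        sub = sub[["barcode", "dna_count", "rna_count"]].copy()
        sub["replicate"] = str(rep)
        parts.append(sub)
    long = pd.concat(parts, ignore_index=True)
    merged = long.merge(assign, on="barcode", how="left")
    unknown = merged["oligo"].isna()
    if unknown.any():
        log.info("dropping %d records for %d unassigned barcodes",
                 int(unknown.sum()), merged.loc[unknown, "barcode"].nunique())
        merged = merged[~unknown]
    return BarcodeCountTable.from_frame(merged)


def read_variant_map(path) -> VariantMap:
    return VariantMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def read_label_table(path) -> LabelTable:
    return LabelTable.from_frame(pd.read_csv(path, sep="\t", dtype=str))


# ----------------------------------------------------------------------
# wide frames
# ----------------------------------------------------------------------
@dataclass
class WideCountFrame:
    """Rows = sequences or variants; columns = replicate × barcode slots.

    ``block`` gives each column's replicate (the blocking vector); columns
    are contiguous, equal-width groups per replicate.  ``allele`` is 0 for
    reference slots and 1 for alternative slots (None in element mode).
    ``missing_mask`` is True where a row does not use a slot.
    """

    row_ids: np.ndarray
    dna: np.ndarray
    rna: np.ndarray
    block: np.ndarray
    allele: np.ndarray | None
    missing_mask: np.ndarray
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_rows(self) -> int:
        return self.dna.shape[0]

    @property
    def n_cols(self) -> int:
        return self.dna.shape[1]

    @property
    def blocks(self) -> list[str]:
        seen: list[str] = []
        for b in self.block:
            if b not in seen:
                seen.append(b)
        return seen

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_width(self) -> int:
        return self.n_cols // self.n_blocks

    def design(self) -> np.ndarray:
        """Column-level design matrix: [1, allele] in variant mode, [1] else."""
        if self.allele is None:
            return np.ones((self.n_cols, 1))
        return np.column_stack([np.ones(self.n_cols), self.allele.astype(float)])


def _barcode_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """Unique (oligo, barcode) pairs with a lexicographic within-oligo rank."""
    pairs = (
        df[["oligo", "barcode"]]
        .drop_duplicates()
        .sort_values(["oligo", "barcode"], kind="mergesort")
        .reset_index(drop=True)
    )
    pairs["slot"] = pairs.groupby("oligo").cumcount()
    return pairs


def create_variant_frame(counts: BarcodeCountTable, vmap: VariantMap) -> WideCountFrame:
    """Build the variant-mode wide frame: one row per variant.

    For each replicate the reference barcode slots come first, then the
    alternative slots; slot widths are the maximum barcode multiplicity over
    all reference (resp. alternative) oligos, shorter sides padded with
    missing slots.  Barcodes fill slots in lexicographic order.
    """
    df = counts.df
    present = set(df["oligo"].unique())
    wanted = pd.concat([vmap.df["ref_oligo"], vmap.df["alt_oligo"]])
    absent = sorted(set(wanted) - present)
    if absent:
        raise LookupError(f"oligos in variant map absent from counts: {absent[:10]}"
                          + (" ..." if len(absent) > 10 else ""))

    reps = counts.replicates
    pairs = _barcode_ranks(df)
    mult = pairs.groupby("oligo").size()
    # both allele sides share one slot width: the maximum barcode
    # multiplicity over all mapped oligos (shorter sides padded missing)
    m_ref = m_alt = int(max(mult.loc[vmap.df["ref_oligo"]].max(),
                            mult.loc[vmap.df["alt_oligo"]].max()))
    width = m_ref + m_alt
    n_rows, n_cols = len(vmap), len(reps) * width

    dna = np.zeros((n_rows, n_cols))
    rna = np.zeros((n_rows, n_cols))
    missing = np.ones((n_rows, n_cols), dtype=bool)
    rep_index = {r: i for i, r in enumerate(reps)}
    rep_idx_col = df["replicate"].map(rep_index).to_numpy()

    for side, offset in (("ref_oligo", 0), ("alt_oligo", m_ref)):
        side_map = vmap.df[["variant_id", side]].rename(columns={side: "oligo"})
        side_map = side_map.reset_index(names="row")
        sub = df.assign(_rep=rep_idx_col).merge(side_map, on="oligo", how="inner")
        sub = sub.merge(pairs, on=["oligo", "barcode"], how="left")
        rows = sub["row"].to_numpy()
        cols = sub["_rep"].to_numpy() * width + offset + sub["slot"].to_numpy()
        dna[rows, cols] = sub["dna_count"].to_numpy()
        rna[rows, cols] = sub["rna_count"].to_numpy()
        missing[rows, cols] = False

    block = np.repeat(np.array(reps, dtype=object), width)
    allele = np.tile(np.array([0] * m_ref + [1] * m_alt), len(reps))
    meta = pd.DataFrame(
        {
            "n_barcodes": (
                mult.loc[vmap.df["ref_oligo"]].to_numpy()
                + mult.loc[vmap.df["alt_oligo"]].to_numpy()
            )
        },
        index=pd.Index(vmap.df["variant_id"], name="id"),
    )
    return WideCountFrame(
        row_ids=vmap.df["variant_id"].to_numpy(),
        dna=dna, rna=rna, block=block, allele=allele,
        missing_mask=missing, row_meta=meta,
    )


def create_element_frame(counts: BarcodeCountTable,
                         labels: LabelTable | None = None) -> WideCountFrame:
    """Build the element-mode wide frame: one row per oligo, intercept-only."""
    df = counts.df
    reps = counts.replicates
    pairs = _barcode_ranks(df)
    mult = pairs.groupby("oligo").size()
    oligos = mult.index.to_numpy()
    width = int(mult.max())
    n_rows, n_cols = len(oligos), len(reps) * width

    dna = np.zeros((n_rows, n_cols))
    rna = np.zeros((n_rows, n_cols))
    missing = np.ones((n_rows, n_cols), dtype=bool)
    rep_index = {r: i for i, r in enumerate(reps)}
    row_index = {o: i for i, o in enumerate(oligos)}

    sub = df.merge(pairs, on=["oligo", "barcode"], how="left")
    rows = sub["oligo"].map(row_index).to_numpy()
    cols = sub["replicate"].map(rep_index).to_numpy() * width + sub["slot"].to_numpy()
    dna[rows, cols] = sub["dna_count"].to_numpy()
    rna[rows, cols] = sub["rna_count"].to_numpy()
    missing[rows, cols] = False

    meta = pd.DataFrame({"n_barcodes": mult.to_numpy()},
                        index=pd.Index(oligos, name="id"))
    if labels is not None:
        unknown = sorted(set(labels.series.index) - set(oligos))
        if unknown:
            warnings.warn(f"labels for {len(unknown)} unknown oligos ignored, "
                          f"e.g. {unknown[:5]}", stacklevel=2)
        meta["label"] = labels.series.reindex(oligos).to_numpy()
    block = np.repeat(np.array(reps, dtype=object), width)
    return WideCountFrame(
        row_ids=oligos, dna=dna, rna=rna, block=block, allele=None,
        missing_mask=missing, row_meta=meta,
    )


def aggregate_frame(frame: WideCountFrame) -> WideCountFrame:
    """Sum barcode-slot counts per (replicate, allele) column.

    This reproduces the classical aggregated analysis: each technical
    replicate contributes one column per allele (or one column total in
    element mode).  A collapsed cell is missing only when every
    contributing slot was missing.
    """
    R, B, W = frame.n_rows, frame.n_blocks, frame.block_width
    nm = ~frame.missing_mask
    dna3 = (frame.dna * nm).reshape(R, B, W)
    rna3 = (frame.rna * nm).reshape(R, B, W)
    nm3 = nm.reshape(R, B, W)
    if frame.allele is None:
        groups = [np.ones(W, dtype=bool)]
        new_allele = None
    else:
        pat = frame.allele[:W]
        groups = [pat == 0, pat == 1]
        new_allele = np.tile(np.arange(len(groups)), B)
    dna = np.stack([dna3[:, :, g].sum(axis=2) for g in groups], axis=2).reshape(R, -1)
    rna = np.stack([rna3[:, :, g].sum(axis=2) for g in groups], axis=2).reshape(R, -1)
    miss = np.stack([~nm3[:, :, g].any(axis=2) for g in groups], axis=2).reshape(R, -1)
    block = np.repeat(np.array(frame.blocks, dtype=object), len(groups))
    return WideCountFrame(
        row_ids=frame.row_ids, dna=dna, rna=rna, block=block,
        allele=new_allele, missing_mask=miss, row_meta=frame.row_meta,
    )


# ----------------------------------------------------------------------
# results output
# ----------------------------------------------------------------------
def write_results(fit, path) -> None:
    """Write a fit result as a TSV (id, logFC/activity, t, p_value,
    adj_p_value, n_barcodes) in input row order."""
    fit.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
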