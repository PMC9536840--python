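"""Readers and writers for the tabular and interval formats the pipeline
consumes and emits.

Conventions
-----------
* On disk, interval files are BED-dialect: 0-based, half-open.
* In memory, all coordinates are 1-based, inclusive; conversion between
  the two is exact (``start_bp = start + 1``, ``end_bp = end``).
* Summary statistics are whitespace/tab-delimited with a header; one file
  carries all metabolites as ``beta_<met>/se_<met>/p_<met>`` triplets.
* If no genetic-map column is present, positions are mapped at a flat
  1 cM/Mb (``cm = pos_bp * 1e-6``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("metpleio")

VARIANT_COLUMNS = ["variant_id", "chrom", "pos_bp", "cm", "effect_allele", "other_allele"]

#: accepted aliases for mandatory sumstats columns (case-insensitive)
_COLUMN_ALIASES = {
    "variant_id": ["variant_id", "snp", "id", "rsid"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos_bp": ["pos_bp", "pos", "bp", "position"],
    "cm": ["cm", "cM", "genetic_pos"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea"],
    "other_allele": ["other_allele", "a2", "allele0", "allele2", "oa"],
}

_TRIPLET_ALIASES = {
    "beta": ["beta", "b"],
    "se": ["se", "stderr"],
    "p": ["p", "p_bolt_lmm", "pval", "pvalue"],
}


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


@dataclass
class SumstatsTable:
    """Per-variant, per-metabolite association table.

    ``df`` columns: the six variant columns plus ``beta_<m>``, ``se_<m>``,
    ``p_<m>`` for every metabolite ``m`` in ``metabolites``.
    """

    df: pd.DataFrame
    metabolites: list[str]
    n_rejected: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {missing}")
        for m in self.metabolites:
            for stat in ("beta", "se", "p"):
                if f"{stat}_{m}" not in self.df.columns:
                    raise FormatError(f"missing mandatory column: {stat}_{m}")
        if self.df["variant_id"].duplicated().any():
            dupes = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise FormatError(f"duplicate variant ids: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def triplet(self, metabolite: str) -> pd.DataFrame:
        """(beta, se, p) columns for one metabolite, renamed to plain names."""
        cols = {f"{s}_{metabolite}": s for s in ("beta", "se", "p")}
        return self.df[list(cols)].rename(columns=cols)


@dataclass
class GeneTable:
    """Gene intervals (1-based inclusive) with type and pathway attributes."""

    df: pd.DataFrame

    COLUMNS = (
        "gene_id",
        "chrom",
        "start_bp",
        "end_bp",
        "gene_type",
        "pathways",
        "relevant_metabolites",
    )
    GENE_TYPES = ("enzyme", "transporter", "tf", "general", "unknown")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"gene table missing column(s): {missing}")
        if (self.df["start_bp"] > self.df["end_bp"]).any():
            raise FormatError("gene with start_bp > end_bp")
        if self.df["gene_id"].duplicated().any():
            raise FormatError("duplicate gene ids")
        bad = set(self.df["gene_type"]) - set(self.GENE_TYPES)
        if bad:
            raise FormatError(f"unknown gene types: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def by_id(self, gene_id: str) -> pd.Series:
        hit = self.df[self.df["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(gene_id)
        return hit.iloc[0]


def _resolve_column(header: list[str], aliases: list[str]) -> str | None:
    lower = {h.lower(): h for h in header}
    for a in aliases:
        if a.lower() in lower:
            return lower[a.lower()]
    return None


def read_sumstats(path: str | Path, metabolite_names: list[str] | None = None) -> SumstatsTable:
    """Read a whitespace-delimited summary-statistics file.

    Rows violating the table invariants (se <= 0, p outside (0, 1],
    pos_bp < 1) are dropped with a logged count.  A missing mandatory
    column or a non-numeric beta/se/p value raises :class:`FormatError`.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    header = list(raw.columns)

    rename: dict[str, str] = {}
    missing_optional: list[str] = []
    for canonical, aliases in _COLUMN_ALIASES.items():
        found = _resolve_column(header, aliases)
        if found is None:
            if canonical in ("cm", "effect_allele", "other_allele"):
                missing_optional.append(canonical)  # cm derived; alleles placeholder
                continue
            raise FormatError(f"missing mandatory column: {canonical}")
        rename[found] = canonical
    df = raw.rename(columns=rename)
    for canonical in missing_optional:
        if canonical != "cm":
            df[canonical] = "N"

    if metabolite_names is None:
        metabolite_names = sorted(
            c[len("beta_"):] for c in df.columns if c.startswith("beta_")
        )
        if not metabolite_names:
            raise FormatError("no beta_<metabolite> columns found")

    for m in metabolite_names:
        for stat, aliases in _TRIPLET_ALIASES.items():
            cands = [f"{a}_{m}" for a in aliases]
            found = _resolve_column(list(df.columns), cands)
            if found is None:
                raise FormatError(f"missing mandatory column: {stat}_{m}")
            if found != f"{stat}_{m}":
                df = df.rename(columns={found: f"{stat}_{m}"})

    numeric = ["pos_bp"] + (["cm"] if "cm" in df.columns else [])
    for m in metabolite_names:
        numeric += [f"beta_{m}", f"se_{m}", f"p_{m}"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after header
            raise FormatError(f"non-numeric value in column {col!r} at line {line}")
        # astype is correctly rounded (to_numeric's fast path is not)
        df[col] = df[col].astype(np.float64)
    if df[numeric].isna().any().any():
        col = df[numeric].columns[df[numeric].isna().any()][0]
        raise FormatError(f"missing values in column {col!r}")

    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    if "cm" not in df.columns:
        df["cm"] = df["pos_bp"] * 1e-6

    ok = pd.Series(True, index=df.index)
    ok &= df["pos_bp"] >= 1
    for m in metabolite_names:
        ok &= df[f"se_{m}"] > 0
        ok &= (df[f"p_{m}"] > 0) & (df[f"p_{m}"] <= 1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("read_sumstats: rejected %d row(s) failing invariants", n_rejected)
    df = df[ok].reset_index(drop=True)

    order = VARIANT_COLUMNS + [f"{s}_{m}" for m in metabolite_names for s in ("beta", "se", "p")]
    return SumstatsTable(df[order], list(metabolite_names), n_rejected)


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- interval files ----------------------------------------------------------


def _check_bed_interval(start: int, end: int, line: int) -> None:
    if start >= end:
        raise FormatError(f"interval with start >= end on disk at line {line}")


def read_genes(path: str | Path) -> GeneTable:
    """Read a BED-like gene file.

    Columns: chrom, start (0-based), end (half-open), gene_id, gene_type,
    pathways (comma-joined or '.'), relevant_metabolites (comma-joined
    or '.').  Overlapping intervals are preserved as-is.
    """
    rows = []
    with open(path) as fh:
        for i, raw_line in enumerate(fh, start=1):
            raw_line = raw_line.strip()
            if not raw_line or raw_line.startswith(("#", "track", "browser")):
                continue
            parts = raw_line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"gene BED line {i}: expected >= 4 fields")
            chrom, start, end, gene_id = parts[:4]
            start, end = int(start), int(end)
            _check_bed_interval(start, end, i)
            gene_type = parts[4] if len(parts) > 4 else "unknown"
            pathways = _split_set(parts[5]) if len(parts) > 5 else frozenset()
            relevant = _split_set(parts[6]) if len(parts) > 6 else frozenset()
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start_bp": start + 1,
                    "end_bp": end,
                    "gene_type": gene_type,
                    "pathways": pathways,
                    "relevant_metabolites": relevant,
                }
            )
    return GeneTable(pd.DataFrame(rows, columns=list(GeneTable.COLUMNS)))


def write_genes(genes: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, g in genes.df.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(g["chrom"]),
                        str(int(g["start_bp"]) - 1),
                        str(int(g["end_bp"])),
                        g["gene_id"],
                        g["gene_type"],
                        _join_set(g["pathways"]),
                        _join_set(g["relevant_metabolites"]),
                    ]
                )
                + "\n"
            )


def _split_set(text: str) -> frozenset:
    return frozenset() if text in (".", "") else frozenset(text.split(","))


def _join_set(values) -> str:
    return ",".join(sorted(values)) if values else "."


def read_blocks(path: str | Path) -> list[tuple[str, int, int]]:
    """Read LD-block intervals (BED) into 1-based inclusive tuples."""
    blocks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            _check_bed_interval(start, end, i)
            blocks.append((chrom, start + 1, end))
    return blocks


def write_blocks(blocks: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start_bp, end_bp in blocks:
            fh.write(f"{chrom}\t{start_bp - 1}\t{end_bp}\n")


# -- small TSV tables --------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result DataFrame as TSV (17-digit floats: lossless)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pair_rg(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    need = {"met_a", "met_b", "rg", "se"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"pair-rg table missing column(s): {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise FormatError("pair-rg table has non-positive SEs")
    # estimates may slightly exceed 1, but not by much
    if (df["rg"].abs() > 1.25).any():
        raise FormatError("pair-rg table has |rg| > 1.25")
    return df


def read_block_stats(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    need = {"chrom", "start_bp", "end_bp", "h2_a", "var_h2_a", "h2_b", "var_h2_b", "cov_ab", "var_cov"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"block-stats table missing column(s): {sorted(missing)}")
    return df


def read_ld_pairs(path: str | Path) -> dict[frozenset, float]:
    """Read a sparse r-squared table (columns id_a, id_b, r2)."""
    df = read_table(path)
    need = {"id_a", "id_b", "r2"}
    if need - set(df.columns):
        raise FormatError(f"LD pair table must have columns {sorted(need)}")
    return {
        frozenset((a, b)): float(r)
        for a, b, r in zip(df["id_a"], df["id_b"], df["r2"])
    }


def write_ld_pairs(pairs: dict[frozenset, float], path: str | Path) -> None:
    rows = sorted((tuple(sorted(k)), v) for k, v in pairs.items())
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\n")
        for (a, b), r in rows:
            fh.write(f"{a}\t{b}\t{r:.17g}\n")
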