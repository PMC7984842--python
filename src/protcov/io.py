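"""Readers, writers and validated in-memory containers.

All tabular artifacts are plain TSV/CSV; gene sets are GMT; results round-trip
through TSV or JSON. Missing intensities are encoded as empty cells or ``NA``
on disk and as NaN in memory — a measured zero is a legal intensity and is
never treated as missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "PeptideTable",
    "ProteinMatrix",
    "GeneSetCollection",
    "SchemaError",
    "DataError",
    "read_design",
    "read_peptide_table",
    "write_peptide_table",
    "read_gmt",
    "read_protein_matrix",
    "write_protein_matrix",
    "write_results",
]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


class DataError(ValueError):
    """Input file is schema-conformant but carries invalid values."""


@dataclass
class SampleDesign:
    """Per-sample metadata driving normalization scopes and model design.

    One row per sample: mixture (TMT plex / MS run), channel, genotype and
    subcellular fraction (both empty for pooled-QC samples), and an SPQC flag.
    ``condition`` is genotype × fraction for biological samples.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "mixture", "channel", "genotype", "fraction", "is_spqc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        t = self.table.copy()
        t["is_spqc"] = t["is_spqc"].astype(bool)
        for col in ("sample_id", "mixture", "channel", "genotype", "fraction"):
            t[col] = t[col].fillna("").astype(str)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise SchemaError(f"duplicate sample_id: {dup!r}")
        pairs = t[["mixture", "channel"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise SchemaError(f"duplicate (mixture, channel) pair: {pairs[pairs.duplicated()].iloc[0]}")
        bio = t[~t["is_spqc"]]
        bad = bio[(bio["genotype"] == "") | (bio["fraction"] == "")]
        if len(bad):
            raise SchemaError(
                f"non-SPQC sample {bad['sample_id'].iloc[0]!r} lacks genotype or fraction"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def biological(self) -> pd.DataFrame:
        return self.table[~self.table["is_spqc"]]

    @property
    def spqc(self) -> pd.DataFrame:
        return self.table[self.table["is_spqc"]]

    def condition(self) -> pd.Series:
        """genotype.fraction label per biological sample, indexed by sample_id."""
        bio = self.biological
        return pd.Series(
            (bio["genotype"] + "." + bio["fraction"]).values, index=bio["sample_id"].values
        )

    def samples_of_mixture(self, mixture: str) -> list[str]:
        return list(self.table.loc[self.table["mixture"] == mixture, "sample_id"])

    @property
    def mixtures(self) -> list[str]:
        return list(dict.fromkeys(self.table["mixture"]))


@dataclass
class PeptideTable:
    """Peptide-level intensities with protein accession mapping.

    ``data`` holds one row per peptide: ``peptide_id``, ``accessions`` (list of
    tokens) and one float column per sample (NaN = missing).
    """

    data: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.data["peptide_id"].duplicated().any():
            dup = self.data.loc[self.data["peptide_id"].duplicated(), "peptide_id"].iloc[0]
            raise SchemaError(f"duplicate peptide_id: {dup!r}")
        if (self.data["accessions"].map(len) == 0).any():
            raise SchemaError("peptide with empty accession list")
        vals = self.data[self.sample_ids].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            r, c = np.argwhere(np.nan_to_num(vals) < 0)[0]
            raise DataError(
                f"negative intensity at peptide {self.data['peptide_id'].iloc[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data.set_index("peptide_id")[self.sample_ids]

    def with_intensities(self, values: pd.DataFrame) -> "PeptideTable":
        out = self.data.copy()
        out.loc[:, self.sample_ids] = values[self.sample_ids].to_numpy()
        return PeptideTable(out, self.sample_ids)

    def subset(self, keep: pd.Series | np.ndarray) -> "PeptideTable":
        return PeptideTable(self.data.loc[keep].reset_index(drop=True), self.sample_ids)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ProteinMatrix:
    """Proteins × samples intensity matrix after summarization.

    ``values``: DataFrame indexed by accession with sample_id columns (NaN =
    missing). ``n_peptides``: unique-peptide count per retained accession.
    """

    values: pd.DataFrame
    n_peptides: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.n_peptides is None:
            self.n_peptides = pd.Series(1, index=self.values.index)
        self.n_peptides = self.n_peptides.reindex(self.values.index)
        if (self.n_peptides < 1).any():
            raise DataError("n_peptides < 1 for a retained accession")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.n_peptides.copy())


@dataclass
class GeneSetCollection:
    sets: dict[str, set]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> set:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return out


# ---------------------------------------------------------------------------
# readers


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype=str)
    if "is_spqc" not in df.columns:
        raise SchemaError("design table missing 'is_spqc' column")
    df["is_spqc"] = df["is_spqc"].str.lower().isin({"true", "1", "yes"})
    return SampleDesign(df)


def read_peptide_table(path, design: SampleDesign) -> PeptideTable:
    """Read a peptide quantification TSV/CSV validated against a design.

    Columns: ``peptide_id``, ``accessions`` (semicolon-delimited), then one
    intensity column per sample in the design. Blank cells and ``NA`` parse as
    missing (NaN), never as zero. Unknown intensity columns are a schema
    error; negative intensities are a data error.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#", na_values=["NA"], keep_default_na=True)
    for col in ("peptide_id", "accessions"):
        if col not in df.columns:
            raise SchemaError(f"peptide table missing column {col!r}")
    value_cols = [c for c in df.columns if c not in ("peptide_id", "accessions")]
    unknown = sorted(set(value_cols) - set(design.sample_ids))
    if unknown:
        raise SchemaError(f"intensity columns not in design: {unknown}")
    absent = sorted(set(design.sample_ids) - set(value_cols))
    if absent:
        raise SchemaError(f"design samples absent from peptide table: {absent}")
    df["accessions"] = df["accessions"].astype(str).map(
        lambda s: [a for a in s.split(";") if a]
    )
    for c in design.sample_ids:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return PeptideTable(df[["peptide_id", "accessions"] + design.sample_ids], design.sample_ids)


def write_peptide_table(table: PeptideTable, path, seed: int | None = None) -> None:
    out = table.data.copy()
    out["accessions"] = out["accessions"].map(";".join)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members; tab-separated).

    Duplicate members within a set are deduplicated. A line with fewer than
    three fields is a format error reported with its line number.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise SchemaError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise SchemaError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def read_protein_matrix(path, n_peptides_path=None) -> ProteinMatrix:
    df = pd.read_csv(path, sep=_sep(path), comment="#", na_values=["NA"], index_col=0)
    npep = None
    if n_peptides_path is not None:
        npep = pd.read_csv(n_peptides_path, sep="\t", index_col=0).iloc[:, 0]
    return ProteinMatrix(df.astype(float), npep)


def write_protein_matrix(matrix: ProteinMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# results writers


def _results_frame(results) -> pd.DataFrame:
    from dataclasses import asdict, is_dataclass

    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in results]
    return pd.DataFrame(rows)


def write_results(results, path, format: str = "tsv", graph=None, partition=None) -> None:
    """Write a result collection (contrasts, enrichment rows, or a partition).

    Column order is deterministic; floats are written at 6 significant
    digits. A partition export additionally emits a per-module edge list
    ``<path>.edges.tsv`` (source, target, weight) when ``graph`` is given.
    """
    path = Path(path)
    from .network import Partition  # local import to avoid a cycle

    if isinstance(results, Partition):
        rows = pd.DataFrame(
            {"node": results.nodes, "module": [results.module_of[n] for n in results.nodes]}
        )
        if format == "json":
            path.write_text(json.dumps(
                {"module_of": results.module_of, "quality": results.quality,
                 "seed": results.seed, "n_restarts": results.n_restarts}, indent=1))
        else:
            rows.to_csv(path, sep="\t", index=False)
        if graph is not None:
            edges = graph.module_edge_list(results)
            edges.to_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t",
                         index=False, float_format="%.6g")
        return

    df = _results_frame(results)
    if format == "json":
        path.write_text(df.to_json(orient="records", double_precision=6, indent=1) or "[]")
    else:
        if df.empty and results is not None:
            # header-only file for an empty list: use canonical contrast columns
            df = pd.DataFrame(
                columns=["target", "contrast", "log2fc", "se", "df", "t", "p", "p_adjust"]
            )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
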