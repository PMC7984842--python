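"""Peptide table → analysis-ready protein matrix.

Implements the multi-mixture isobaric-label normalization stack: contaminant
removal, within-mixture sample-loading (SL) normalization, pooled-QC (SPQC)
outlier-peptide filtering, k-nearest-neighbour imputation, unique-peptide
protein summarization, cross-mixture SL, internal reference scaling (IRS),
reproducibility filters and protein-level outlier detection.

The stage order is fixed — contaminants → SL (within mixture) → SPQC peptide
filter → kNN impute → summarize → SL (across mixtures) → IRS → protein
filters → protein outlier filter — and recorded in the pipeline log; SL and
IRS do not commute, so the order is part of the method.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .io import DataError, PeptideTable, ProteinMatrix, SampleDesign

__all__ = [
    "remove_contaminants",
    "sample_loading_normalize",
    "filter_spqc_outlier_peptides",
    "impute_knn",
    "summarize_proteins",
    "irs_normalize",
    "filter_proteins",
    "filter_protein_outliers",
    "preprocess_pipeline",
]

PIPELINE_ORDER = (
    "remove_contaminants",
    "sample_loading_within_mixture",
    "filter_spqc_outlier_peptides",
    "impute_knn",
    "summarize_proteins",
    "sample_loading_across_mixtures",
    "irs_normalize",
    "filter_proteins",
    "filter_protein_outliers",
)


def remove_contaminants(table: PeptideTable, contaminant_accessions: set) -> tuple[PeptideTable, list]:
    """Drop peptides whose accession list intersects the contaminant set."""
    if not contaminant_accessions:
        return table, []
    contaminants = set(contaminant_accessions)
    hit = table.data["accessions"].map(lambda accs: bool(contaminants.intersection(accs)))
    removed = list(table.data.loc[hit, "peptide_id"])
    return table.subset(~hit), removed


def sample_loading_normalize(
    values: pd.DataFrame, scope_groups: list[list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize column totals within each scope group.

    Each column is scaled so its total (ignoring missing values) equals the
    arithmetic mean of its group's pre-normalization totals, preserving the
    group's overall scale. Returns the scaled frame and per-sample factors.
    """
    out = values.copy()
    factors = pd.Series(1.0, index=values.columns, dtype=float)
    for group in scope_groups:
        if not group:
            raise DataError("empty sample-loading scope group")
        sub = values[group]
        n_obs = sub.notna().sum(axis=0)
        if (n_obs == 0).any():
            bad = n_obs.index[n_obs == 0][0]
            raise DataError(f"sample {bad!r} has no observed values; cannot normalize")
        totals = sub.sum(axis=0, skipna=True)
        target = totals.mean()
        fac = target / totals
        out.loc[:, group] = sub.mul(fac, axis=1).to_numpy()
        factors.loc[group] = fac
    return out, factors


def _pairwise_log_ratio(values: np.ndarray) -> float:
    """Mean signed log2 ratio over ordered replicate pairs (single pair for n=2)."""
    logs = np.log2(values)
    pairs = [logs[i] - logs[j] for i, j in combinations(range(len(logs)), 2)]
    return float(np.mean(pairs))


def _bin_outlier_mask(
    mean_intensity: np.ndarray, stat: np.ndarray, n_bins: int, sd_threshold: float
) -> np.ndarray:
    """Flag entries whose stat lies > sd_threshold bin-SDs from its bin mean.

    Bins are equal-count (quantile) on mean intensity. A bin with zero SD
    never fires (strict inequality).
    """
    n = len(stat)
    flagged = np.zeros(n, dtype=bool)
    if n == 0:
        return flagged
    n_bins = max(1, min(n_bins, n))
    order = np.argsort(mean_intensity, kind="stable")
    bins = np.array_split(order, n_bins)
    for idx in bins:
        if len(idx) < 2:
            continue
        s = stat[idx]
        mu, sd = s.mean(), s.std(ddof=1)
        # the 1e-9 absolute guard (log2 units) keeps float rounding in an
        # otherwise exactly-reproducible bin from firing the rule
        flagged[idx] = np.abs(s - mu) > sd_threshold * sd + 1e-9
    return flagged


def filter_spqc_outlier_peptides(
    table: PeptideTable, design: SampleDesign, n_bins: int = 5, sd_threshold: float = 4.0
) -> tuple[PeptideTable, pd.DataFrame]:
    """Remove irreproducible peptides based on within-mixture SPQC agreement.

    Per mixture: peptides with any missing SPQC value are removed outright;
    the rest are binned into ``n_bins`` equal-count intensity bins by mean
    SPQC intensity, and a peptide is removed when its SPQC log2 ratio lies
    more than ``sd_threshold`` bin standard deviations from its bin mean.
    """
    if n_bins < 1 or sd_threshold <= 0:
        raise ValueError("n_bins must be >= 1 and sd_threshold > 0")
    removed_rows = []
    drop = pd.Series(False, index=table.data.index)
    for mixture in design.mixtures:
        spqc_cols = [
            s for s in design.samples_of_mixture(mixture)
            if bool(design.table.set_index("sample_id").loc[s, "is_spqc"])
        ]
        if len(spqc_cols) < 2:
            raise DataError(f"mixture {mixture!r} has fewer than 2 SPQC samples")
        sub = table.data[spqc_cols]
        missing = sub.isna().any(axis=1)
        for i in table.data.index[missing]:
            removed_rows.append((table.data.loc[i, "peptide_id"], mixture, "missing_spqc"))
        drop |= missing

        ok = ~missing
        vals = sub.loc[ok].to_numpy(dtype=float)
        if len(vals):
            stat = np.apply_along_axis(_pairwise_log_ratio, 1, vals)
            flagged = _bin_outlier_mask(vals.mean(axis=1), stat, n_bins, sd_threshold)
            idx = table.data.index[ok][flagged]
            for i in idx:
                removed_rows.append((table.data.loc[i, "peptide_id"], mixture, "spqc_outlier"))
            drop.loc[idx] = True
    report = pd.DataFrame(removed_rows, columns=["peptide_id", "mixture", "reason"])
    return table.subset(~drop), report


def impute_knn(
    values: pd.DataFrame, k: int = 10, target_cols: list[str] | None = None
) -> pd.DataFrame:
    """Replace missing entries by the mean of the k nearest rows' values.

    Distance between rows is root-mean-square difference of log2 intensities
    over mutually observed columns; only rows observed in the target column
    are candidates. Columns outside ``target_cols`` (e.g. SPQC samples) are
    used for distances but never imputed. Observed values are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if target_cols is None:
        target_cols = list(values.columns)
    out = values.copy()
    mat = values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logm = np.log2(mat)
    obs = np.isfinite(logm)
    if (~obs).sum() == 0:
        return out
    all_missing = ~obs.any(axis=1)
    if all_missing.any():
        raise DataError(f"row {values.index[all_missing][0]!r} has no observed values; cannot impute")

    col_pos = {c: j for j, c in enumerate(values.columns)}
    target_idx = [col_pos[c] for c in target_cols]
    need = [
        (i, j) for i in range(mat.shape[0]) for j in target_idx if not obs[i, j]
    ]
    dist_cache: dict[int, np.ndarray] = {}
    for i, j in need:
        if i not in dist_cache:
            co = obs & obs[i]  # co-observed mask vs row i
            diff = np.where(co, logm - logm[i], 0.0)
            cnt = co.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.sqrt((diff**2).sum(axis=1) / cnt)
            d[cnt == 0] = np.inf
            d[i] = np.inf
            dist_cache[i] = d
        d = dist_cache[i].copy()
        d[~obs[:, j]] = np.inf  # candidates must be observed in the target column
        order = np.argsort(d, kind="stable")
        neigh = order[: k][np.isfinite(d[order[: k]])]
        if len(neigh) == 0:
            raise DataError(
                f"no neighbour with an observed value for row {values.index[i]!r}, "
                f"column {values.columns[j]!r}"
            )
        out.iloc[i, j] = float(mat[neigh, j].mean())
    return out


def summarize_proteins(table: PeptideTable) -> ProteinMatrix:
    """Sum unique-peptide intensities per protein accession.

    Only peptides mapping to exactly one accession contribute; shared
    peptides are discarded. A sample's sum is missing only when every
    contributing peptide is missing there.
    """
    unique = table.data[table.data["accessions"].map(len) == 1].copy()
    unique["accession"] = unique["accessions"].map(lambda a: a[0])
    grouped = unique.groupby("accession", sort=True)
    values = grouped[table.sample_ids].sum(min_count=1)
    n_pep = grouped.size().rename("n_peptides")
    return ProteinMatrix(values, n_pep)


def irs_normalize(
    matrix: ProteinMatrix, design: SampleDesign
) -> tuple[ProteinMatrix, pd.DataFrame, list[str]]:
    """Internal reference scaling across mixtures.

    For each protein, every sample of a mixture is multiplied by
    (geometric mean of the per-mixture SPQC geometric means) /
    (SPQC geometric mean within that mixture), equalizing SPQC levels across
    mixtures. Proteins with a missing or zero SPQC value are flagged and left
    unscaled. Returns (matrix, per-protein × mixture factors, flagged ids).
    """
    mixtures = design.mixtures
    spqc_by_mix = {
        m: [s for s in design.samples_of_mixture(m) if s in set(design.spqc["sample_id"])]
        for m in mixtures
    }
    out = matrix.values.copy()
    factors = pd.DataFrame(1.0, index=matrix.values.index, columns=mixtures)
    flagged: list[str] = []
    for prot in matrix.values.index:
        gms = {}
        bad = False
        for m in mixtures:
            v = matrix.values.loc[prot, spqc_by_mix[m]].to_numpy(dtype=float)
            if len(v) == 0 or np.isnan(v).any() or (v <= 0).any():
                bad = True
                break
            gms[m] = float(np.exp(np.mean(np.log(v))))
        if bad:
            flagged.append(prot)
            continue
        global_gm = float(np.exp(np.mean(np.log(list(gms.values())))))
        for m in mixtures:
            fac = global_gm / gms[m]
            factors.loc[prot, m] = fac
            cols = design.samples_of_mixture(m)
            out.loc[prot, cols] = out.loc[prot, cols] * fac
    return ProteinMatrix(out, matrix.n_peptides), factors, flagged


def filter_proteins(
    matrix: ProteinMatrix,
    design: SampleDesign,
    min_presence: float = 0.5,
    min_peptides: int = 2,
    require_complete_spqc: bool = True,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Remove irreproducibly quantified proteins.

    Rules: quantified in fewer than ``min_presence`` of biological samples;
    identified by fewer than ``min_peptides`` unique peptides; any missing
    SPQC value (when required). The report lists every rule that fired.
    """
    bio_cols = list(design.biological["sample_id"])
    spqc_cols = list(design.spqc["sample_id"])
    rows = []
    keep = []
    for prot in matrix.values.index:
        fired = []
        presence = matrix.values.loc[prot, bio_cols].notna().mean()
        if presence < min_presence:
            fired.append("low_presence")
        if matrix.n_peptides.loc[prot] < min_peptides:
            fired.append("single_peptide" if matrix.n_peptides.loc[prot] == 1 else "few_peptides")
        if require_complete_spqc and spqc_cols and matrix.values.loc[prot, spqc_cols].isna().any():
            fired.append("missing_spqc")
        if fired:
            rows.append((prot, ";".join(fired)))
        keep.append(not fired)
    report = pd.DataFrame(rows, columns=["accession", "rules"])
    kept = matrix.values.loc[keep]
    return ProteinMatrix(kept, matrix.n_peptides.loc[kept.index]), report


def filter_protein_outliers(
    matrix: ProteinMatrix, design: SampleDesign, n_bins: int = 5, sd_threshold: float = 4.0
) -> tuple[ProteinMatrix, list[str]]:
    """Remove proteins with an irreproducible measurement in any replicate group.

    Replicate groups are the genotype × fraction conditions (replicated
    across mixtures). Per group, each protein's mean pairwise log2 ratio is
    binned by mean intensity exactly as in the SPQC peptide filter and
    flagged beyond ``sd_threshold`` bin SDs.
    """
    bio = design.biological
    removed: set[str] = set()
    for (_, _), grp in bio.groupby(["genotype", "fraction"], sort=True):
        cols = list(grp["sample_id"])
        if len(cols) < 2:
            warnings.warn(f"replicate group {cols} has a single sample; skipped")
            continue
        vals = matrix.values[cols].to_numpy(dtype=float)
        ok = np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1)
        stat = np.apply_along_axis(_pairwise_log_ratio, 1, vals[ok])
        flagged = _bin_outlier_mask(vals[ok].mean(axis=1), stat, n_bins, sd_threshold)
        removed |= set(np.asarray(matrix.values.index)[ok][flagged])
    keep = [p for p in matrix.values.index if p not in removed]
    kept = matrix.values.loc[keep]
    return ProteinMatrix(kept, matrix.n_peptides.loc[keep]), sorted(removed)


def preprocess_pipeline(
    table: PeptideTable,
    design: SampleDesign,
    contaminants: set | None = None,
    n_bins: int = 5,
    sd_threshold: float = 4.0,
    knn_k: int = 10,
    min_presence: float = 0.5,
    min_peptides: int = 2,
) -> tuple[ProteinMatrix, dict]:
    """Run the full fixed-order stack; returns the matrix and a provenance log."""
    log: dict = {"order": list(PIPELINE_ORDER), "counts": {}}
    log["counts"]["input_peptides"] = len(table)

    table, contam = remove_contaminants(table, contaminants or set())
    log["counts"]["contaminant_peptides_removed"] = len(contam)

    mixture_groups = [design.samples_of_mixture(m) for m in design.mixtures]
    values, sl_factors = sample_loading_normalize(table.intensities, mixture_groups)
    table = table.with_intensities(values)
    log["sl_within_mixture_factors"] = sl_factors.to_dict()

    table, spqc_report = filter_spqc_outlier_peptides(table, design, n_bins, sd_threshold)
    log["counts"]["spqc_filtered_peptides"] = int(spqc_report["peptide_id"].nunique())
    log["spqc_filter_reasons"] = spqc_report["reason"].value_counts().to_dict()

    bio_cols = list(design.biological["sample_id"])
    imputed = impute_knn(table.intensities, k=knn_k, target_cols=bio_cols)
    log["counts"]["imputed_cells"] = int(
        (table.intensities[bio_cols].isna() & imputed[bio_cols].notna()).to_numpy().sum()
    )
    table = table.with_intensities(imputed)

    matrix = summarize_proteins(table)
    log["counts"]["summarized_proteins"] = len(matrix.accessions)

    values, sl2 = sample_loading_normalize(matrix.values, [list(matrix.values.columns)])
    matrix = ProteinMatrix(values, matrix.n_peptides)
    log["sl_across_mixtures_factors"] = sl2.to_dict()

    matrix, irs_factors, irs_flagged = irs_normalize(matrix, design)
    log["counts"]["irs_flagged_proteins"] = len(irs_flagged)

    matrix, filter_report = filter_proteins(matrix, design, min_presence, min_peptides)
    log["counts"]["proteins_after_filters"] = len(matrix.accessions)
    log["protein_filter_rules"] = (
        filter_report["rules"].value_counts().to_dict() if len(filter_report) else {}
    )

    matrix, outlier_removed = filter_protein_outliers(matrix, design, n_bins, sd_threshold)
    log["counts"]["protein_outliers_removed"] = len(outlier_removed)
    log["counts"]["final_proteins"] = len(matrix.accessions)
    return matrix, log
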