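"""Proximity-proteomics (iBioID) enrichment: probe vs. soluble control.

Label-free protein intensities from separate MS runs are sample-loading
normalized across runs, then pool-normalized per protein so the mean of the
biological replicates matches the mean of the pooled-QC (SPQC) replicates.
After presence and peptide-count filters and kNN imputation, each protein is
compared probe vs. control with a two-group fixed-effects linear model on
the log2 scale. A protein enters the interactome when its fold-change over
the control exceeds 4 and its Benjamini–Hochberg FDR is below 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import ContrastResult
from .io import DataError, ProteinMatrix, SampleDesign
from .preprocess import impute_knn, sample_loading_normalize

__all__ = ["normalize_bioid", "filter_and_impute_bioid", "bioid_enrichment"]


def normalize_bioid(
    matrix: ProteinMatrix, design: SampleDesign
) -> tuple[ProteinMatrix, list[str]]:
    """SL across runs, then per-protein pooling to the SPQC mean.

    After the step, each protein's mean over biological replicates equals
    its mean over SPQC replicates. Proteins with no SPQC measurement are
    flagged and excluded from pool normalization.
    """
    values, _ = sample_loading_normalize(matrix.values, [list(matrix.values.columns)])
    bio_cols = list(design.biological["sample_id"])
    spqc_cols = list(design.spqc["sample_id"])
    out = values.copy()
    flagged: list[str] = []
    for prot in values.index:
        spqc = values.loc[prot, spqc_cols].dropna()
        bio = values.loc[prot, bio_cols].dropna()
        if len(spqc) == 0 or len(bio) == 0:
            flagged.append(prot)
            continue
        factor = spqc.mean() / bio.mean()
        out.loc[prot, bio_cols] = values.loc[prot, bio_cols] * factor
    return ProteinMatrix(out, matrix.n_peptides), flagged


def filter_and_impute_bioid(
    matrix: ProteinMatrix,
    design: SampleDesign,
    min_presence: float = 0.5,
    min_peptides: int = 2,
    knn_k: int = 10,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Presence/peptide-count filters, then kNN imputation of the remainder.

    Missingness in these label-free runs is left-shifted (missing
    not-at-random), but imputation still uses the k-nearest-neighbour rule.
    """
    all_cols = list(matrix.values.columns)
    rows, keep = [], []
    for prot in matrix.values.index:
        fired = []
        if matrix.values.loc[prot, all_cols].notna().mean() < min_presence:
            fired.append("low_presence")
        if matrix.n_peptides.loc[prot] < min_peptides:
            fired.append("single_peptide")
        if fired:
            rows.append((prot, ";".join(fired)))
        keep.append(not fired)
    kept = matrix.values.loc[keep]
    imputed = impute_knn(kept, k=min(knn_k, max(1, len(kept) - 1)))
    report = pd.DataFrame(rows, columns=["accession", "rules"])
    return ProteinMatrix(imputed, matrix.n_peptides.loc[kept.index]), report


def bioid_enrichment(
    matrix: ProteinMatrix,
    design: SampleDesign,
    probe_group: str = "probe",
    control_group: str = "control",
    fc_threshold: float = 4.0,
    fdr: float = 0.05,
) -> tuple[list[ContrastResult], list[str]]:
    """Per-protein probe-vs-control comparison and thresholded interactome.

    The model is a two-group fixed-effects comparison on log2 intensities
    (pooled-variance t test, the OLS contrast for this design). Fold-change
    is 2^(difference of group log2 means). Returns (full statistics table,
    enriched accession list).
    """
    bio = design.biological
    probe_cols = list(bio.loc[bio["genotype"] == probe_group, "sample_id"])
    ctl_cols = list(bio.loc[bio["genotype"] == control_group, "sample_id"])
    if len(probe_cols) < 2 or len(ctl_cols) < 2:
        raise DataError("need >= 2 replicates per group")
    vals = matrix.values
    if vals[probe_cols + ctl_cols].isna().any().any():
        raise DataError("bioid_enrichment requires a complete matrix; impute first")
    results: list[ContrastResult] = []
    for prot in vals.index:
        a = np.log2(vals.loc[prot, probe_cols].to_numpy(dtype=float))
        b = np.log2(vals.loc[prot, ctl_cols].to_numpy(dtype=float))
        n1, n2 = len(a), len(b)
        est = float(a.mean() - b.mean())
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        flags = ""
        if sp2 <= 0:
            flags = "degenerate_variance"
            se, t, p = np.nan, np.nan, 1.0
        else:
            se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df))
        results.append(ContrastResult(
            target=prot, level="protein", contrast=f"{probe_group}-{control_group}",
            log2fc=est, se=se, df=float(df), t=t, p=p, flags=flags,
        ))
    padj = multipletests([r.p for r in results], method="fdr_bh")[1]
    enriched = []
    for r, q in zip(results, padj):
        r.p_adjust = float(q)
        r.method = "BH"
        if 2.0 ** r.log2fc > fc_threshold and r.p_adjust < fdr:
            enriched.append(r.target)
    return results, enriched
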