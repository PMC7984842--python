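"""Protein- and module-level differential abundance between genotypes.

Protein level: each protein's log2 intensities over the biological samples
are fit with a linear mixed model — condition (genotype × fraction) as a
fixed effect in cell-means form and TMT mixture as a random intercept —
by REML. Contrasts (per-fraction MUT − WT and the overall genotype effect,
equal weight 1/n_fractions per fraction) are tested with Satterthwaite
degrees of freedom; p-values are adjusted by Benjamini–Hochberg within each
contrast family across proteins.

Module level: protein intensities are first sum-normalized per protein
(relative intensity), log2-transformed, and all proteins of a module are fit
jointly with condition fixed and protein as a random intercept (mixture
omitted: after sample-loading and internal-reference scaling its variance
share is negligible). One overall genotype contrast per module is tested,
with Bonferroni adjustment over the number of modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import DataError, ProteinMatrix, SampleDesign
from .lmm import MixedFit, contrast, fit_random_intercept

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "ProteinModelFit",
    "ModuleModelFit",
    "fit_protein_model",
    "contrast_test",
    "overall_contrast",
    "fraction_contrast",
    "run_protein_contrasts",
    "relative_log2",
    "rescale_01",
    "fit_module_model",
    "run_module_contrasts",
    "adjust_pvalues",
]


@dataclass
class ContrastSpec:
    """Sum-to-zero coefficient vector over the ordered condition means."""

    l: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if abs(self.l.sum()) > 1e-12:
            raise ValueError(f"contrast {self.label!r} does not sum to zero")
        if not np.any(self.l != 0):
            raise ValueError(f"contrast {self.label!r} is identically zero")


@dataclass
class ContrastResult:
    target: str
    level: str  # "protein" | "module"
    contrast: str
    log2fc: float
    se: float
    df: float
    t: float
    p: float
    p_adjust: float = np.nan
    method: str = ""
    size: int = 1  # module size (1 for proteins)
    flags: str = ""


@dataclass
class _BaseFit:
    target: str
    conditions: list[str]
    fit: MixedFit
    y: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return self.fit.beta

    @property
    def vcov(self) -> np.ndarray:
        return self.fit.vcov

    @property
    def mu(self) -> float:
        return float(self.fit.beta.mean())

    @property
    def condition_effects(self) -> pd.Series:
        """Sum-to-zero condition effects (cell means minus the grand mean)."""
        return pd.Series(self.fit.beta - self.mu, index=self.conditions)

    @property
    def sigma2(self) -> float:
        return self.fit.sigma2

    @property
    def ols_fallback(self) -> bool:
        return self.fit.ols_fallback


@dataclass
class ProteinModelFit(_BaseFit):
    @property
    def sigma2_M(self) -> float:
        return self.fit.sigma2_g


@dataclass
class ModuleModelFit(_BaseFit):
    proteins: list[str] = field(default_factory=list)

    @property
    def sigma2_P(self) -> float:
        return self.fit.sigma2_g


def _condition_frame(design: SampleDesign) -> tuple[pd.DataFrame, list[str]]:
    bio = design.biological.copy()
    bio["condition"] = bio["genotype"] + "." + bio["fraction"]
    conditions = sorted(bio["condition"].unique())
    return bio, conditions


def _design_matrix(cond_labels: pd.Series, conditions: list[str]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(conditions)}
    X = np.zeros((len(cond_labels), len(conditions)))
    for i, c in enumerate(cond_labels):
        X[i, idx[c]] = 1.0
    return X


def _genotype_order(design: SampleDesign, control: str | None, mutant: str | None):
    seen = list(dict.fromkeys(design.biological["genotype"]))
    if control is None:
        control = "WT" if "WT" in seen else seen[0]
    if mutant is None:
        mutant = "MUT" if "MUT" in seen else [g for g in seen if g != control][0]
    return control, mutant


def fit_protein_model(values: pd.Series, design: SampleDesign) -> ProteinModelFit:
    """REML fit of one protein's log2 intensities (condition + (1|mixture))."""
    bio, conditions = _condition_frame(design)
    y_raw = values.loc[bio["sample_id"]].to_numpy(dtype=float)
    if np.isnan(y_raw).any() or (y_raw <= 0).any():
        raise DataError(f"protein {values.name!r} has missing/non-positive values; impute first")
    present = set(bio["condition"])
    absent = [c for c in conditions if c not in present]
    if absent:
        raise DataError(f"conditions with no samples: {absent}")
    y = np.log2(y_raw)
    X = _design_matrix(bio["condition"], conditions)
    groups = bio["mixture"].to_numpy()
    fit = fit_random_intercept(y, X, groups)
    return ProteinModelFit(str(values.name), conditions, fit, y)


def overall_contrast(
    conditions: list[str], control: str, mutant: str, label: str | None = None
) -> ContrastSpec:
    """Average genotype effect across fractions: mean(MUT_f) − mean(WT_f)."""
    mut = [c for c in conditions if c.startswith(mutant + ".")]
    ctl = [c for c in conditions if c.startswith(control + ".")]
    if not mut or not ctl:
        raise ValueError(f"genotypes {mutant!r}/{control!r} not found in conditions")
    l = np.zeros(len(conditions))
    for c in mut:
        l[conditions.index(c)] = 1.0 / len(mut)
    for c in ctl:
        l[conditions.index(c)] = -1.0 / len(ctl)
    return ContrastSpec(l, label or f"{mutant}-{control}")


def fraction_contrast(
    conditions: list[str], control: str, mutant: str, fraction: str
) -> ContrastSpec:
    l = np.zeros(len(conditions))
    mc, cc = f"{mutant}.{fraction}", f"{control}.{fraction}"
    if mc not in conditions or cc not in conditions:
        raise ValueError(f"fraction {fraction!r} lacks both genotypes")
    l[conditions.index(mc)] = 1.0
    l[conditions.index(cc)] = -1.0
    return ContrastSpec(l, f"{mutant}-{control}@{fraction}")


def contrast_test(
    fit: _BaseFit, spec: ContrastSpec, level: str = "protein", size: int = 1
) -> ContrastResult:
    if len(spec.l) != len(fit.conditions):
        raise ValueError("contrast dimension does not match condition count")
    out = contrast(fit.fit, spec.l, fit.y)
    return ContrastResult(
        target=fit.target, level=level, contrast=spec.label,
        log2fc=out.estimate, se=out.se, df=out.df, t=out.t, p=out.p,
        size=size, flags="ols_fallback" if fit.ols_fallback else "",
    )


def adjust_pvalues(results: list[ContrastResult], method: str = "BH", k: int | None = None) -> None:
    """In-place multiplicity adjustment over one family of results."""
    if not results:
        return
    p = np.array([r.p for r in results])
    if method.upper() == "BH":
        adj = multipletests(p, method="fdr_bh")[1]
    elif method.lower() == "bonferroni":
        adj = np.minimum(p * (k if k is not None else len(p)), 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    for r, a in zip(results, adj):
        r.p_adjust = float(a)
        r.method = method


def run_protein_contrasts(
    matrix: ProteinMatrix,
    design: SampleDesign,
    control: str | None = None,
    mutant: str | None = None,
) -> tuple[list[ContrastResult], list[str]]:
    """All per-fraction and overall genotype contrasts for every protein.

    BH adjustment is applied within each named contrast family across
    proteins. Returns (results, proteins whose fit failed).
    """
    control, mutant = _genotype_order(design, control, mutant)
    bio, conditions = _condition_frame(design)
    fractions = sorted(bio["fraction"].unique())
    specs = [overall_contrast(conditions, control, mutant)] + [
        fraction_contrast(conditions, control, mutant, f) for f in fractions
    ]
    families: dict[str, list[ContrastResult]] = {s.label: [] for s in specs}
    failed: list[str] = []
    for prot in matrix.values.index:
        try:
            fit = fit_protein_model(matrix.values.loc[prot], design)
            for spec in specs:
                families[spec.label].append(contrast_test(fit, spec, level="protein"))
        except (DataError, ValueError, np.linalg.LinAlgError):
            failed.append(prot)
    results: list[ContrastResult] = []
    for label in families:
        adjust_pvalues(families[label], method="BH")
        results.extend(families[label])
    return results, failed


# ---------------------------------------------------------------------------
# module level


def relative_log2(
    matrix: ProteinMatrix, design: SampleDesign, scope: str = "mixture"
) -> pd.DataFrame:
    """Per-protein sum-normalized log2 profiles over biological samples.

    Each protein's intensities are divided by that protein's total within the
    scope (``"mixture"``: the biological samples of each mixture separately;
    ``"global"``: all biological samples) and log2-transformed. SPQC samples
    are excluded. Scale-invariant by construction.
    """
    bio = design.biological
    cols = list(bio["sample_id"])
    vals = matrix.values[cols].astype(float)
    if vals.isna().any().any():
        raise DataError("relative_log2 requires a complete matrix; impute first")
    if scope == "global":
        groups = [cols]
    elif scope == "mixture":
        groups = [list(g["sample_id"]) for _, g in bio.groupby("mixture", sort=False)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = vals.copy()
    for g in groups:
        totals = vals[g].sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise DataError(f"protein {bad!r} has non-positive total in scope")
        out.loc[:, g] = vals[g].div(totals, axis=0).to_numpy()
    return np.log2(out)


def rescale_01(profiles: pd.DataFrame) -> pd.DataFrame:
    """Map each protein's log2 relative profile into [0, 1] (plotting only)."""
    lo = profiles.min(axis=1)
    rng = profiles.max(axis=1) - lo
    rng = rng.replace(0, 1.0)
    return profiles.sub(lo, axis=0).div(rng, axis=0)


def fit_module_model(
    profiles: pd.DataFrame, partition, module_id: str, design: SampleDesign
) -> ModuleModelFit:
    """Joint fit of a module's protein profiles (condition + (1|protein))."""
    members = [n for n in profiles.index if partition.module_of.get(n) == module_id]
    if not members:
        raise DataError(f"module {module_id!r} has no proteins in the matrix")
    bio, conditions = _condition_frame(design)
    cond = list(bio["condition"])
    ys, Xs, gs = [], [], []
    X1 = _design_matrix(bio["condition"], conditions)
    for prot in members:
        ys.append(profiles.loc[prot, bio["sample_id"]].to_numpy(dtype=float))
        Xs.append(X1)
        gs.append(np.full(len(cond), prot, dtype=object))
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    groups = np.concatenate(gs)
    fit = fit_random_intercept(y, X, groups)
    return ModuleModelFit(str(module_id), conditions, fit, y, proteins=members)


def run_module_contrasts(
    profiles: pd.DataFrame,
    partition,
    design: SampleDesign,
    control: str | None = None,
    mutant: str | None = None,
) -> list[ContrastResult]:
    """One overall genotype contrast per module, Bonferroni over modules."""
    control, mutant = _genotype_order(design, control, mutant)
    _, conditions = _condition_frame(design)
    spec = overall_contrast(conditions, control, mutant)
    module_ids = sorted(set(partition.module_of.values()), key=partition.sort_key)
    results = []
    for mod in module_ids:
        fit = fit_module_model(profiles, partition, mod, design)
        results.append(contrast_test(fit, spec, level="module", size=len(fit.proteins)))
    adjust_pvalues(results, method="bonferroni", k=len(module_ids))
    return results
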