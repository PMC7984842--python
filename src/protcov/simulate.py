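"""Synthetic multi-mixture isobaric-label datasets with known ground truth.

Emulates a three-mixture, 16-channel design: seven subcellular fractions ×
two genotypes plus two pooled-QC (SPQC) channels per mixture. Proteins belong
to covariation modules, each with its own relative-abundance profile across
fractions; selected modules carry a genotype effect. The generator plants
mixture batch effects, channel loading differences, intensity-dependent
missingness, and occasional gross SPQC outliers, so every downstream
normalization and filtering step has a known target.

Generative model (log2 scale) for protein p in module M, fraction f,
genotype g, mixture m, peptide t, observation:

    y = log2(grand_mean_p * profile_M[f]) + effect_M * 1[g = MUT]
        + mixture_effect_{p,m} + peptide_offset_t + N(0, sigma_peptide^2)

with mixture_effect ~ N(0, sigma_mixture^2) and peptide_offset ~ N(0, 1)
fixed per peptide. SPQC channels draw from the same latent protein mean
(pooled over fractions, no genotype effect). Reported intensity is
2^y × channel loading factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeptideTable, SampleDesign

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_profile_matrix"]

DEFAULT_FRACTIONS = [f"F{i}" for i in range(1, 8)]


class ConfigError(ValueError):
    """A SimulationConfig field violates its constraints."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 mixtures × 16 channels
    (7 fractions × 2 genotypes + 2 SPQC), log2-scale peptide noise of 0.25,
    mixture batch sd 0.10, ~2% missingness concentrated at low intensity,
    and rare (0.2%) gross SPQC outliers.
    """

    n_proteins: int = 300
    n_modules: int = 10
    peptides_per_protein: tuple[int, int] = (2, 6)
    n_mixtures: int = 3
    fractions: list[str] = field(default_factory=lambda: list(DEFAULT_FRACTIONS))
    genotypes: list[str] = field(default_factory=lambda: ["WT", "MUT"])
    spqc_per_mixture: int = 2
    module_profiles: np.ndarray | None = None  # (n_modules, n_fractions), rows sum to 1
    effect_map: dict[str, float] = field(default_factory=dict)  # module -> log2 MUT effect
    sigma_peptide: float = 0.25
    sigma_mixture: float = 0.10
    loading_factors: np.ndarray | None = None  # per channel, multiplicative
    missing_rate_at_floor: float = 0.10
    missing_decay: float = 1.0  # log2 units; ignored when mnar=False
    mnar: bool = True
    outlier_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 1 <= self.n_modules <= self.n_proteins:
            raise ConfigError("n_modules must be in [1, n_proteins]")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein must satisfy 1 <= min <= max")
        if self.n_mixtures < 1:
            raise ConfigError("n_mixtures must be >= 1")
        if self.spqc_per_mixture < 0:
            raise ConfigError("spqc_per_mixture must be >= 0")
        for name in ("sigma_peptide", "sigma_mixture"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_rate_at_floor", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.module_profiles is not None:
            prof = np.asarray(self.module_profiles, dtype=float)
            if prof.shape != (self.n_modules, len(self.fractions)):
                raise ConfigError("module_profiles must be (n_modules, n_fractions)")
            if (prof <= 0).any():
                raise ConfigError("module_profiles must be strictly positive")
            if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError("module_profiles rows must sum to 1")
        if self.loading_factors is not None:
            lf = np.asarray(self.loading_factors, dtype=float)
            if lf.shape != (self.n_channels,) or (lf <= 0).any():
                raise ConfigError("loading_factors must be positive, one per channel")

    @property
    def n_channels(self) -> int:
        return len(self.fractions) * len(self.genotypes) + self.spqc_per_mixture


@dataclass
class GroundTruth:
    """Planted truth for a simulated dataset."""

    module_of: dict[str, str]  # protein -> module id
    true_effect: dict[str, float]  # module -> log2FC (MUT - WT), 0 for null modules
    true_profiles: dict[str, list[float]]  # module -> fraction profile
    injected_missing: set  # {(peptide_id, sample_id)}
    injected_outliers: set  # {(peptide_id, sample_id)}

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "true_effect": self.true_effect,
            "true_profiles": self.true_profiles,
            "injected_missing": sorted(map(list, self.injected_missing)),
            "injected_outliers": sorted(map(list, self.injected_outliers)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _make_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for m in range(1, config.n_mixtures + 1):
        mixture = f"M{m}"
        ch = 0
        for g in config.genotypes:
            for f in config.fractions:
                ch += 1
                rows.append((f"{mixture}.{g}.{f}", mixture, f"C{ch:02d}", g, f, False))
        for s in range(1, config.spqc_per_mixture + 1):
            ch += 1
            rows.append((f"{mixture}.SPQC.{s}", mixture, f"C{ch:02d}", "", "", True))
    df = pd.DataFrame(
        rows, columns=["sample_id", "mixture", "channel", "genotype", "fraction", "is_spqc"]
    )
    return SampleDesign(df)


def simulate_dataset(config: SimulationConfig) -> tuple[PeptideTable, SampleDesign, GroundTruth]:
    """Draw one peptide-level dataset from the generative model.

    Returns the peptide table (NaN where missingness was injected), the
    sample design, and the planted ground truth. Identical config (including
    seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n_frac, n_geno = len(config.fractions), len(config.genotypes)

    modules = [f"M{i}" for i in range(1, config.n_modules + 1)]
    module_idx = rng.integers(0, config.n_modules, size=config.n_proteins)
    proteins = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    module_of = {p: modules[k] for p, k in zip(proteins, module_idx)}

    if config.module_profiles is not None:
        profiles = np.asarray(config.module_profiles, dtype=float)
    else:
        profiles = rng.dirichlet(np.full(n_frac, 1.5), size=config.n_modules)
        profiles = np.clip(profiles, 1e-3, None)
        profiles /= profiles.sum(axis=1, keepdims=True)

    unknown = set(config.effect_map) - set(modules)
    if unknown:
        raise ConfigError(f"effect_map names unknown modules: {sorted(unknown)}")
    effects = np.array([float(config.effect_map.get(mod, 0.0)) for mod in modules])

    if config.loading_factors is not None:
        loading = np.asarray(config.loading_factors, dtype=float)
    else:
        loading = 2.0 ** rng.normal(0.0, 0.2, size=config.n_channels)
    channel_of = dict(zip(design.table["sample_id"], design.table["channel"]))
    loading_of = {f"C{c + 1:02d}": loading[c] for c in range(config.n_channels)}

    # grand means: log2 ~ N(20, 2) gives realistic reporter-intensity spread
    log2_grand = rng.normal(20.0, 2.0, size=config.n_proteins)
    n_pep = rng.integers(
        config.peptides_per_protein[0], config.peptides_per_protein[1] + 1,
        size=config.n_proteins,
    )
    mix_effect = rng.normal(0.0, config.sigma_mixture, size=(config.n_proteins, config.n_mixtures))

    sample_ids = design.sample_ids
    bio = design.biological
    frac_idx = {f: i for i, f in enumerate(config.fractions)}
    mut_like = {g: (j > 0) for j, g in enumerate(config.genotypes)}  # first genotype is reference
    mix_of = {s: int(m[1:]) - 1 for s, m in zip(design.table["sample_id"], design.table["mixture"])}

    records, pep_ids, accs = [], [], []
    for pi, prot in enumerate(proteins):
        k = module_idx[pi]
        base_bio = {}
        for _, row in bio.iterrows():
            mu = (
                log2_grand[pi]
                + np.log2(profiles[k, frac_idx[row["fraction"]]])
                + (effects[k] if mut_like[row["genotype"]] else 0.0)
                + mix_effect[pi, mix_of[row["sample_id"]]]
            )
            base_bio[row["sample_id"]] = mu
        base_spqc = {}
        for _, row in design.spqc.iterrows():
            base_spqc[row["sample_id"]] = (
                log2_grand[pi] - np.log2(n_frac) + mix_effect[pi, mix_of[row["sample_id"]]]
            )
        offsets = rng.normal(0.0, 1.0, size=n_pep[pi])
        mu_row = np.array([base_bio.get(s, base_spqc.get(s)) for s in sample_ids])
        load_row = np.array([loading_of[channel_of[s]] for s in sample_ids])
        for t in range(n_pep[pi]):
            pep_ids.append(f"{prot}_pep{t + 1}")
            accs.append([prot])
            noise = rng.normal(0.0, config.sigma_peptide, size=len(sample_ids))
            records.append(2.0 ** (mu_row + offsets[t] + noise) * load_row)

    values = np.asarray(records)

    # gross SPQC outliers: one SPQC replicate of a peptide shifted by 2^±8
    injected_outliers: set = set()
    spqc_ids = list(design.spqc["sample_id"])
    if config.outlier_rate > 0 and spqc_ids:
        hit = rng.random(len(pep_ids)) < config.outlier_rate
        for i in np.flatnonzero(hit):
            s = spqc_ids[rng.integers(len(spqc_ids))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[i, sample_ids.index(s)] *= 2.0 ** (8.0 * sign)
            injected_outliers.add((pep_ids[i], s))

    # intensity-dependent missingness above a floor quantile
    injected_missing: set = set()
    if config.missing_rate_at_floor > 0:
        logv = np.log2(values)
        floor = np.quantile(logv, 0.05)
        if config.mnar:
            p = config.missing_rate_at_floor * 2.0 ** (
                -np.clip(logv - floor, 0.0, None) / config.missing_decay
            )
        else:
            p = np.full_like(logv, config.missing_rate_at_floor)
        drop = rng.random(values.shape) < p
        for i, j in zip(*np.nonzero(drop)):
            injected_missing.add((pep_ids[i], sample_ids[j]))
        values = np.where(drop, np.nan, values)

    data = pd.DataFrame(values, columns=sample_ids)
    data.insert(0, "accessions", accs)
    data.insert(0, "peptide_id", pep_ids)
    table = PeptideTable(data, sample_ids)

    truth = GroundTruth(
        module_of=module_of,
        true_effect={mod: float(e) for mod, e in zip(modules, effects)},
        true_profiles={mod: profiles[i].tolist() for i, mod in enumerate(modules)},
        injected_missing=injected_missing,
        injected_outliers=injected_outliers,
    )
    return table, design, truth


def simulate_profile_matrix(
    n_modules: int = 10,
    proteins_per_module: int = 30,
    design: SampleDesign | None = None,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Protein-level log2 matrix with planted covariation modules.

    Shortcut for clustering benchmarks: each module has its own log2-scale
    abundance profile over the genotype × fraction conditions (mutually
    orthogonal unit-variance vectors, so between-module correlation is near
    zero), and each member protein is profile + N(0, sigma) noise. The
    default sigma of 0.5 gives within-module correlations near
    1/(1 + sigma^2) ≈ 0.8. Returns (log2 matrix over biological samples,
    protein -> module map).
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = _make_design(SimulationConfig())
    bio = design.biological
    conds = list(dict.fromkeys(bio["genotype"] + "." + bio["fraction"]))
    if n_modules >= len(conds):
        raise ValueError("n_modules must be below the number of conditions")
    cond_of = (bio["genotype"] + "." + bio["fraction"]).tolist()
    cond_idx = {c: i for i, c in enumerate(conds)}

    # orthonormal columns of a random centered Gaussian -> profiles with
    # near-zero pairwise correlation, scaled to unit variance
    G = rng.normal(0.0, 1.0, (len(conds), n_modules))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    profiles = [(q - q.mean()) / q.std() for q in Q.T]

    rows, names, truth = [], [], {}
    for k in range(n_modules):
        for j in range(proteins_per_module):
            name = f"M{k + 1}_P{j + 1}"
            names.append(name)
            truth[name] = f"M{k + 1}"
            mu = rng.normal(20.0, 1.0)
            vals = [
                mu + profiles[k][cond_idx[c]] + rng.normal(0.0, sigma)
                for c in cond_of
            ]
            rows.append(vals)
    mat = pd.DataFrame(rows, index=names, columns=list(bio["sample_id"]))
    return mat, truth
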