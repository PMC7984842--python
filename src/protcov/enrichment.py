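"""Hypergeometric gene-set enrichment of network modules.

For each (module, gene set) pair, the upper-tail hypergeometric probability
P(X >= overlap) is computed against a background defined as the union of all
clustered proteins and all set members, with Bonferroni correction over
every test performed (zero-overlap pairs included, so the correction
denominator is the full modules × sets grid and is recorded per row).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_enrich", "hypergeom_pvalue"]


@dataclass
class EnrichmentResult:
    module: str
    set_name: str
    overlap: int
    module_size: int
    set_size: int
    background_size: int
    n_tests: int
    p: float
    p_adjust: float


def hypergeom_pvalue(overlap: int, module_size: int, set_size: int, background: int) -> float:
    """Upper-tail hypergeometric p: P(X >= overlap).

    X counts set members in a random draw of ``module_size`` from a
    background of ``background`` containing ``set_size`` members.
    """
    if not 0 <= overlap <= min(module_size, set_size):
        raise ValueError("overlap exceeds module or set size")
    if background < max(module_size, set_size):
        raise ValueError("background smaller than module or set")
    # sf(k-1) = P(X >= k); overlap 0 gives exactly 1
    p = float(stats.hypergeom.sf(overlap - 1, background, set_size, module_size))
    return min(max(p, 5e-324), 1.0)


def hypergeom_enrich(
    partition, sets: GeneSetCollection, id_map: dict[str, str] | None = None
) -> list[EnrichmentResult]:
    """Test every module against every gene set.

    ``id_map`` optionally translates set-member identifiers (e.g. gene
    symbols) to the partition's accession namespace before testing.
    """
    clustered = set(partition.module_of)
    mapped_sets = {}
    for name, members in sets.sets.items():
        if id_map is not None:
            members = {id_map.get(m, m) for m in members}
        mapped_sets[name] = members
    background = clustered.union(*mapped_sets.values()) if mapped_sets else clustered
    if not background:
        raise ValueError("empty background universe")
    module_ids = sorted(set(partition.module_of.values()), key=partition.sort_key)
    n_tests = len(module_ids) * len(mapped_sets)
    results = []
    for mod in module_ids:
        members = set(partition.members(mod))
        for name, gene_set in mapped_sets.items():
            gs = gene_set & background
            overlap = len(members & gs)
            p = hypergeom_pvalue(overlap, len(members), len(gs), len(background))
            results.append(EnrichmentResult(
                module=mod, set_name=name, overlap=overlap,
                module_size=len(members), set_size=len(gs),
                background_size=len(background), n_tests=n_tests,
                p=p, p_adjust=min(1.0, p * n_tests),
            ))
    return results
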