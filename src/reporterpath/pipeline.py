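"""End-to-end orchestration: gene stats -> mapping -> metabolites -> pathways.

One seed drives the whole run; the per-stage background seeds are derived
from it by fixed offsets so that a run is reproducible from its manifest
while the stages use distinct random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genestats import map_genes_to_reactions
from .network import MetabolicNetwork, PathwayIndex, build_pathway_index
from .reporter import (
    DEFAULT_N_SAMPLES,
    MetaboliteScores,
    combine_reports,
    directional_analysis,
    reporter_metabolites,
    reporter_pathways_metabolite_centric,
    reporter_pathways_reaction_centric,
)

# fixed seed offsets per random stage (metabolite bg, RPA^m bg, RPA^r bg, up, down)
_SEED_OFFSETS = {"metabolite": 0, "rpam": 1, "rpar": 2, "up": 3, "down": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Derived seed for one random stage (kept below 2**31)."""
    return (int(seed) + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class AnalysisResult:
    """All tables produced by one reporter pathway run."""

    network: MetabolicNetwork
    pathway_index: PathwayIndex
    gene_stats: pd.DataFrame
    reaction_stats: pd.DataFrame
    metabolite_scores: MetaboliteScores
    rpam: pd.DataFrame
    rpar: pd.DataFrame
    combined: pd.DataFrame
    directional: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_analysis(
    network: MetabolicNetwork,
    gene_stats: pd.DataFrame,
    *,
    min_reactions: int = 3,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    background: str = "permutation",
    directions: tuple[str, ...] = (),
) -> AnalysisResult:
    """Run the full scoring pipeline on a parsed network and gene table.

    ``directions`` may contain "up" and/or "down" to append directional
    metabolite-centric runs (always read together with the undirected one).
    """
    pathway_index = build_pathway_index(network, min_reactions=min_reactions)
    reaction_stats = map_genes_to_reactions(network, gene_stats)
    metabolite_scores = reporter_metabolites(
        network,
        reaction_stats,
        gene_stats=gene_stats,
        n_samples=n_samples,
        seed=stage_seed(seed, "metabolite"),
    )
    rpam = reporter_pathways_metabolite_centric(
        network,
        pathway_index,
        metabolite_scores,
        n_samples=n_samples,
        seed=stage_seed(seed, "rpam"),
        background=background,
    )
    rpar = reporter_pathways_reaction_centric(
        network,
        pathway_index,
        reaction_stats,
        n_samples=n_samples,
        seed=stage_seed(seed, "rpar"),
    )
    directional = {}
    for direction in directions:
        directional[direction] = directional_analysis(
            network,
            pathway_index,
            gene_stats,
            direction,
            n_samples=n_samples,
            seed=stage_seed(seed, direction),
            background=background,
        )
    return AnalysisResult(
        network=network,
        pathway_index=pathway_index,
        gene_stats=gene_stats,
        reaction_stats=reaction_stats,
        metabolite_scores=metabolite_scores,
        rpam=rpam,
        rpar=rpar,
        combined=combine_reports(rpam, rpar),
        directional=directional,
    )
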